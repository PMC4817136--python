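import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from intronmark.genotype_stats import (
    allele_stats,
    expected_heterozygosity,
    nei_li_distance,
    nj_tree,
    pic_from_frequencies,
    relative_expression,
    segregation_chi2,
)
from intronmark.synthetic_data import simulate_genotypes


@pytest.mark.parametrize(
    "freqs, expected",
    [
        ([1.0], 0.0),
        ([0.5, 0.5], 0.375),
        ([0.25] * 4, 0.703125),
    ],
)
def test_pic_closed_forms(freqs, expected):
    assert pic_from_frequencies(freqs) == pytest.approx(expected, abs=1e-12)


@given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
def test_pic_bounds_and_permutation_invariance(weights):
    freqs = np.asarray(weights) / np.sum(weights)
    pic = pic_from_frequencies(freqs)
    assert 0.0 <= pic < 1.0
    assert pic == pytest.approx(pic_from_frequencies(sorted(freqs)), abs=1e-12)
    assert pic <= expected_heterozygosity(freqs) + 1e-12


def test_allele_stats_relabeling_and_missing():
    gm = pd.DataFrame(
        {
            "a1": ["1", "1/2", "-", "3"],
            "a2": ["1", "2", "-", "3"],
            "a3": ["2", "1/2", "-", "3"],
        },
        index=["m1", "m2", "m3", "m4"],
    )
    table, summary = allele_stats(gm)
    relabeled = gm.replace({"1": "7", "2": "9", "1/2": "7/9"})
    table2, summary2 = allele_stats(relabeled)
    pd.testing.assert_series_equal(table["pic"], table2["pic"])
    assert table.loc["m3"].isna()["pic"]  # fully missing marker -> NA
    assert summary["n_scored"] == 3
    assert not table.loc["m4", "polymorphic"]
    assert table.loc["m4", "pic"] == 0.0


def test_nei_li_hand_cases():
    gm = pd.DataFrame({"x": ["1/2"], "y": ["2/3"]}, index=["m1"])
    d = nei_li_distance(gm)
    assert d.loc["x", "y"] == pytest.approx(0.5)  # S = 2*1/(2+2)
    same = pd.DataFrame({"x": ["1", "2/3"], "y": ["1", "2/3"]}, index=["m1", "m2"])
    assert nei_li_distance(same).loc["x", "y"] == 0.0
    disjoint = pd.DataFrame({"x": ["1"], "y": ["2"]}, index=["m1"])
    assert nei_li_distance(disjoint).loc["x", "y"] == 1.0


def test_nei_li_symmetry_zero_diagonal_and_missing_error():
    gm, _ = simulate_genotypes(60, {"A": 4, "B": 4}, divergence=0.2, seed=5)
    d = nei_li_distance(gm)
    assert np.allclose(d.values, d.values.T)
    assert np.allclose(np.diag(d.values), 0.0)
    assert ((d.values >= 0) & (d.values <= 1)).all()
    broken = pd.DataFrame({"x": ["1", "-"], "y": ["-", "2"]}, index=["m1", "m2"])
    with pytest.raises(ValueError, match="jointly scored"):
        nei_li_distance(broken)


def _tip_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(taxa[i], taxa[j])
    return out, [t.label for t in taxa]


def test_nj_three_taxon_closed_form():
    dm = pd.DataFrame(
        [[0, 2, 4], [2, 0, 4], [4, 4, 0]], index=list("ABC"), columns=list("ABC"),
        dtype=float,
    )
    tree = nj_tree(dm)
    lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def test_nj_recovers_additive_four_taxon_tree():
    # ((A,B),(C,D)) with internal edge 5 and leaf edges 1,2,3,4
    dm = pd.DataFrame(
        [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float,
    )
    tree = nj_tree(dm)
    dist, labels = _tip_distances(tree)
    assert np.allclose(dist, dm.loc[labels, labels].values)
    bip = {
        frozenset(l.taxon.label for l in e.head_node.leaf_iter())
        for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node and not e.head_node.is_leaf()
    }
    assert frozenset("AB") in bip or frozenset("CD") in bip


def _random_additive_tree(n, rng):
    """Random binary tree with positive branch lengths; returns (dm, labels)."""
    labels = [chr(ord("A") + i) for i in range(n)]
    ns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(lab)
        node.edge.length = float(rng.uniform(0.5, 5.0))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.5, 5.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(ns, key=lambda t: t.label)
    dm = pd.DataFrame(
        [[0.0 if i == j else pdm.distance(taxa[i], taxa[j]) for j in range(n)]
         for i in range(n)],
        index=labels, columns=labels,
    )
    return dm


@pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
def test_nj_exact_on_random_additive_matrices(n):
    rng = np.random.default_rng(n)
    for _ in range(3):
        dm = _random_additive_tree(n, rng)
        tree = nj_tree(dm)
        dist, labels = _tip_distances(tree)
        assert np.allclose(dist, dm.loc[labels, labels].values, atol=1e-9)


def test_nj_topology_agrees_with_dendropy_reference():
    """Cross-check our agglomeration against dendropy's own NJ."""
    gm, _ = simulate_genotypes(80, {"A": 3, "B": 3, "C": 2}, divergence=0.3, seed=9)
    dm = nei_li_distance(gm)
    ours = nj_tree(dm)

    csv = "," + ",".join(dm.columns) + "\n" + "\n".join(
        f"{idx}," + ",".join(str(v) for v in row) for idx, row in dm.iterrows()
    )
    import io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO(csv), taxon_namespace=ours.taxon_namespace
    )
    ref = pdm.nj_tree()

    def bipartitions(tree):
        tree.encode_bipartitions()
        return {
            e.bipartition.split_bitmask
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node and not e.head_node.is_leaf()
        }

    assert bipartitions(ours) == bipartitions(ref)


def test_bootstrap_support_100_when_markers_identical():
    gm = pd.DataFrame(
        {"A": ["1"] * 6, "B": ["1"] * 6, "C": ["2"] * 6, "D": ["2"] * 6},
        index=[f"m{i}" for i in range(6)],
    )
    tree = nj_tree(nei_li_distance(gm), gm, n_bootstrap=25, seed=0)
    supports = [
        float(n.label)
        for n in tree.preorder_node_iter()
        if not n.is_leaf() and n is not tree.seed_node and n.label
    ]
    assert supports and all(s == 100.0 for s in supports)


def test_two_planted_clusters_fully_supported():
    """Strong between-group divergence vs weak within: the group split gets
    100% bootstrap support."""
    gm, labels = simulate_genotypes(
        200, {"grpA": 5, "grpB": 5}, divergence=0.3, within_divergence=0.05, seed=17
    )
    tree = nj_tree(nei_li_distance(gm), gm, n_bootstrap=50, seed=17)
    group_a = frozenset(acc for acc, g in labels.items() if g == "grpA")
    group_b = frozenset(acc for acc, g in labels.items() if g == "grpB")
    found = None
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if clade in (group_a, group_b):
            found = float(node.label)
    assert found == 100.0


def test_nj_input_validation():
    dm2 = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(dm2)
    dm3 = pd.DataFrame(
        [[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]],
        index=list("ABC"), columns=list("ABC"),
    )
    with pytest.raises(ValueError, match="non-finite"):
        nj_tree(dm3)


@pytest.mark.parametrize(
    "observed, ratio, chi2, p",
    [
        ([75, 75], [1, 1], 0.0, 1.0),
        ([60, 40], [1, 1], 4.0, 0.0455),
        ([30, 10], [3, 1], 0.0, 1.0),
    ],
)
def test_segregation_chi2_hand_cases(observed, ratio, chi2, p):
    got_chi2, df, got_p = segregation_chi2(observed, ratio)
    assert got_chi2 == pytest.approx(chi2, abs=1e-12)
    assert df == 1
    assert got_p == pytest.approx(p, abs=5e-4)


def test_segregation_chi2_errors():
    with pytest.raises(ValueError):
        segregation_chi2([0, 0], [1, 1])
    with pytest.raises(ValueError):
        segregation_chi2([5, 5], [1, 0])


@pytest.mark.parametrize(
    "args, expected",
    [
        ((20, 18, 22, 20), 1.0),  # ddCt = 0
        ((19, 18, 20, 18), 2.0),  # ddCt = -1
        ((20, 18, 25, 18), 32.0),  # ddCt = 2 - 7 = -5
    ],
)
def test_comparative_ct_fold_changes(args, expected):
    assert relative_expression(*args) == pytest.approx(expected)


def test_comparative_ct_requires_finite():
    with pytest.raises(ValueError):
        relative_expression(float("nan"), 18, 20, 18)
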