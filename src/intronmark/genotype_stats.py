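"""Marker-genotype analytics: PIC, Nei-Li distance, NJ trees, segregation, ddCt.

The genotype matrix is a pandas DataFrame with markers as rows and
accessions as columns; each cell is an allele call "a", "a/b" (co-dominant
heterozygote) or "-" (missing). Allele codes are arbitrary positive
integers - every statistic here is invariant to relabeling.

PIC uses the Botstein (1980) formula (PowerMarker's definition)
    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2,
with expected heterozygosity (1 - sum p_i^2) emitted alongside. Band
presence for the Nei-Li similarity treats every observed allele of every
marker as one gel band; heterozygotes contribute both bands. Distances use
pairwise-complete missing handling. The neighbor-joining agglomeration is
Saitou-Nei with deterministic lowest-index tie-breaks; bootstrap resamples
markers (columns of the band profile) with replacement.
"""

from __future__ import annotations

import math
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

MISSING = "-"


def parse_call(cell: str) -> tuple[int, ...] | None:
    """Allele pair from a cell; None when missing. "a" means homozygous."""
    cell = str(cell).strip()
    if cell in (MISSING, "", "nan", "None"):
        return None
    parts = cell.split("/")
    if len(parts) == 1:
        a = int(parts[0])
        return (a, a)
    a, b = int(parts[0]), int(parts[1])
    return (a, b) if a <= b else (b, a)


def format_call(call: tuple[int, ...] | None) -> str:
    if call is None:
        return MISSING
    a, b = call
    return str(a) if a == b else f"{a}/{b}"


def pic_from_frequencies(freqs: Sequence[float]) -> float:
    """Botstein polymorphism information content from allele frequencies."""
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        return float("nan")
    if not math.isclose(p.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("allele frequencies must sum to 1")
    sum_sq = float((p**2).sum())
    cross = float(sum(2 * p[i] ** 2 * p[j] ** 2
                      for i in range(len(p)) for j in range(i + 1, len(p))))
    return 1.0 - sum_sq - cross


def expected_heterozygosity(freqs: Sequence[float]) -> float:
    p = np.asarray(freqs, dtype=float)
    return 1.0 - float((p**2).sum())


def allele_stats(gm: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-marker allele number, polymorphism flag, PIC and He; panel means.

    Frequencies come from non-missing calls only (two allele copies per
    scored cell). Fully missing markers get NA stats and are excluded from
    the panel means.
    """
    if gm.shape[1] < 2:
        raise ValueError("allele_stats needs at least two accessions")
    rows = []
    for marker_id, row in gm.iterrows():
        counts: dict[int, int] = {}
        for cell in row:
            call = parse_call(cell)
            if call is None:
                continue
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            rows.append(
                {"marker_id": marker_id, "n_alleles": 0, "polymorphic": np.nan,
                 "pic": np.nan, "he": np.nan}
            )
            continue
        total = sum(counts.values())
        freqs = [c / total for c in sorted(counts.values(), reverse=True)]
        rows.append(
            {
                "marker_id": marker_id,
                "n_alleles": len(counts),
                "polymorphic": len(counts) >= 2,
                "pic": pic_from_frequencies(freqs),
                "he": expected_heterozygosity(freqs),
            }
        )
    table = pd.DataFrame(rows).set_index("marker_id")
    scored = table.dropna(subset=["pic"])
    summary = {
        "n_markers": len(table),
        "n_scored": len(scored),
        "mean_alleles": float(scored["n_alleles"].mean()) if len(scored) else float("nan"),
        "pct_polymorphic": (
            100.0 * float(scored["polymorphic"].mean()) if len(scored) else float("nan")
        ),
        "mean_pic": float(scored["pic"].mean()) if len(scored) else float("nan"),
    }
    return table, summary


def _band_profiles(gm: pd.DataFrame) -> dict[str, dict[int, frozenset[int]]]:
    """Per accession: marker row index -> set of alleles (bands); missing omitted."""
    profiles: dict[str, dict[int, frozenset[int]]] = {}
    for acc in gm.columns:
        bands: dict[int, frozenset[int]] = {}
        for idx, cell in enumerate(gm[acc]):
            call = parse_call(cell)
            if call is not None:
                bands[idx] = frozenset(call)
        profiles[acc] = bands
    return profiles


def nei_li_distance(gm: pd.DataFrame) -> pd.DataFrame:
    """Accession x accession distance D = 1 - 2*n_shared/(n_x + n_y).

    Band counts are restricted to markers scored in both accessions
    (pairwise deletion). A pair with zero jointly scored bands raises an
    error naming the pair.
    """
    profiles = _band_profiles(gm)
    accs = list(gm.columns)
    n = len(accs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            bx, by = profiles[accs[i]], profiles[accs[j]]
            joint = bx.keys() & by.keys()
            nx = sum(len(bx[m]) for m in joint)
            ny = sum(len(by[m]) for m in joint)
            if nx + ny == 0:
                raise ValueError(
                    f"no jointly scored bands for pair ({accs[i]}, {accs[j]})"
                )
            shared = sum(len(bx[m] & by[m]) for m in joint)
            D[i, j] = D[j, i] = 1.0 - 2.0 * shared / (nx + ny)
    return pd.DataFrame(D, index=accs, columns=accs)


def _nj_agglomerate(
    D: np.ndarray, labels: Sequence[str], taxon_namespace: dendropy.TaxonNamespace
) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; deterministic lowest-index tie-break.

    Ends in an unrooted tree (trifurcating seed node for >= 3 taxa); on any
    additive distance matrix the generating topology and branch lengths are
    recovered exactly.
    """
    n0 = len(labels)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxon_namespace.require_taxon(label=lab)
        nodes.append(node)
    size = 2 * n0
    dist = np.zeros((size, size))
    dist[:n0, :n0] = D
    active = list(range(n0))
    nxt = n0
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            dku = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
            dist[nxt, k] = dist[k, nxt] = dku
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    root = dendropy.Node()
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
        lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
        lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
        for idx, ln in ((a, la), (b, lb), (c, lc)):
            nodes[idx].edge.length = ln
            root.add_child(nodes[idx])
    elif len(active) == 2:
        a, b = active
        for idx in (a, b):
            nodes[idx].edge.length = dist[a, b] / 2.0
            root.add_child(nodes[idx])
    else:
        root = nodes[active[0]]
    tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=root)
    tree.is_rooted = False
    return tree


def _internal_bitmasks(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    masks = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        masks.add(edge.bipartition.split_bitmask)
    return masks


def nj_tree(
    dm: pd.DataFrame,
    gm: pd.DataFrame | None = None,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix, optional marker bootstrap.

    With ``gm`` and ``n_bootstrap`` > 0, markers (rows of the genotype
    matrix) are resampled with replacement, the Nei-Li distance and NJ tree
    rebuilt per replicate, and each internal edge of the base tree labeled
    with the percentage of replicates recovering its bipartition.
    Deterministic given ``seed``.
    """
    if len(dm) < 3:
        raise ValueError("nj_tree needs at least 3 accessions")
    values = dm.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("distance matrix contains non-finite values")
    labels = [str(x) for x in dm.index]
    ns = dendropy.TaxonNamespace(labels)
    tree = _nj_agglomerate(values, labels, ns)
    if n_bootstrap and gm is not None:
        rng = np.random.default_rng(seed)
        tree.encode_bipartitions()
        counts: dict[int, int] = {}
        base_masks = _internal_bitmasks(tree)
        for mask in base_masks:
            counts[mask] = 0
        n_markers = len(gm)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n_markers, size=n_markers)
            rep_gm = gm.iloc[idx]
            rep_dm = nei_li_distance(rep_gm)
            rep_tree = _nj_agglomerate(
                rep_dm.to_numpy(dtype=float), labels, ns
            )
            rep_masks = _internal_bitmasks(rep_tree)
            for mask in base_masks & rep_masks:
                counts[mask] += 1
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
                continue
            support = 100.0 * counts[edge.bipartition.split_bitmask] / n_bootstrap
            edge.head_node.label = f"{support:.0f}"
    return tree


def bootstrap_support(tree: dendropy.Tree) -> dict[str, float]:
    """Internal-node label -> support (%) mapping for a bootstrapped tree."""
    out = {}
    for i, node in enumerate(
        n for n in tree.preorder_node_iter()
        if not n.is_leaf() and n is not tree.seed_node
    ):
        if node.label is not None:
            out[f"edge{i}"] = float(node.label)
    return out


def segregation_chi2(
    observed: Sequence[float], ratio: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit to a segregation ratio.

    No continuity correction; df = classes - 1; p from the upper tail.
    Used to screen markers for Mendelian 1:1 segregation in a mapping
    population (p < 0.05 rejects).
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.shape != rat.shape:
        raise ValueError("observed and ratio must have the same length")
    if (rat <= 0).any():
        raise ValueError("ratio terms must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed counts sum to zero")
    expected = rat / rat.sum() * total
    if (expected == 0).any():
        raise ValueError("expected count of zero")
    chi2, p = stats.chisquare(obs, expected)
    return float(chi2), len(obs) - 1, float(p)


def relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Comparative-Ct (2^-ddCt) fold change of a target gene.

    dCt = Ct(target) - Ct(reference gene) per condition; ddCt is the sample
    dCt minus the calibrator dCt, so the calibrator's own fold change is 1.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)


def read_genotype_csv(path) -> pd.DataFrame:
    """Genotype CSV: rows = markers, columns = accessions, cells 'a/b' or '-'."""
    return pd.read_csv(path, index_col=0, dtype=str).fillna(MISSING)


def write_genotype_csv(gm: pd.DataFrame, path) -> None:
    gm.to_csv(path)
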