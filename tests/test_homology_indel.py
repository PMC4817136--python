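import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronmark.genome_io import Genome, GenomeSequence, revcomp
from intronmark.homology_indel import (
    AlignScoring,
    HomologyConfig,
    KmerIndex,
    align_and_call_indels,
    alignment_score,
    anchored_call_indels,
    bit_score,
    call_intron_indels,
    e_value,
    map_intron_to_query,
)
from oracles import enumerate_alignment_score, gotoh_score

SIM_GATES = HomologyConfig(min_bit_score=50.0, max_evalue=1e-6)


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------- k-mer index


def test_kmer_index_counts_and_self_consistency():
    seq = _random_seq(1000, 0)
    genome = Genome(c=GenomeSequence("c", seq))
    index = KmerIndex(genome, k=13)
    assert len(index) == 1000 - 13 + 1 == 988
    for kmer, positions in list(index._index.items())[:200]:
        for seq_id, pos in positions:
            assert genome[seq_id].residues[pos : pos + 13] == kmer


def test_kmer_index_skips_n_and_validates_k():
    seq = "ACGTACGTACGTA" + "N" + "ACGTACGTACGTA"
    index = KmerIndex(Genome(c=GenomeSequence("c", seq)), k=13)
    assert all("N" not in kmer for kmer in index._index)
    with pytest.raises(ValueError):
        KmerIndex(Genome(c=GenomeSequence("c", seq)), k=7)


# -------------------------------------------------- Karlin-Altschul gating


def test_bit_score_closed_form_passes_gate():
    """A perfectly conserved 1 kb intron at +1/match scoring: raw 1000."""
    expected = (1.28 * 1000 - math.log(0.46)) / math.log(2.0)
    assert bit_score(1000) == pytest.approx(expected)
    assert bit_score(1000) == pytest.approx(1848, abs=1)
    assert bit_score(1000) >= 500
    assert e_value(1000, 1000, 4_000_000) < 1e-300


def test_random_intron_finds_no_match():
    query = Genome(c=GenomeSequence("c", _random_seq(50_000, 1)))
    index = KmerIndex(query, 13)
    foreign = _random_seq(400, 2)
    assert map_intron_to_query(foreign, index, SIM_GATES) is None


def test_planted_homolog_interval_recovered_exactly(small_sim):
    """On an indel-only pair the returned interval equals the truth interval."""
    from intronmark.synthetic_data import SimConfig, simulate_genome_pair

    sim = simulate_genome_pair(
        SimConfig(n_genes=6, n_chromosomes=1, intron_snp_rate=0.0, seed=21)
    )
    index = KmerIndex(sim.query_genome, 13)
    truth = sim.truth_introns.set_index(["gene_id", "intron_ordinal"])
    from intronmark.genome_io import extract_introns

    n_checked = n_opposite = 0
    for gene in sim.gene_models:
        for intron in extract_introns(gene, sim.ref_genome):
            match = map_intron_to_query(intron.sequence, index, SIM_GATES)
            assert match is not None and not match.ambiguous
            row = truth.loc[(gene.gene_id, intron.ordinal)]
            assert (match.query_seq_id, match.query_start, match.query_end) == (
                row["seq_id"], row["query_start"], row["query_end"]
            )
            expected_strand = "same" if gene.strand == "+" else "opposite"
            assert match.strand_rel == expected_strand
            n_opposite += match.strand_rel == "opposite"
            n_checked += 1
    assert n_checked >= 10 and n_opposite >= 1


def test_duplicated_locus_flagged_ambiguous():
    intron = _random_seq(400, 3)
    chrom = _random_seq(500, 4) + intron + _random_seq(500, 5) + intron + _random_seq(500, 6)
    index = KmerIndex(Genome(c=GenomeSequence("c", chrom)), 13)
    match = map_intron_to_query(intron, index, SIM_GATES)
    assert match is not None and match.ambiguous


# ------------------------------------------------------------ indel calling


def test_identical_sequences_call_nothing():
    seq = _random_seq(200, 7)
    _aln, calls = align_and_call_indels(seq, seq)
    assert calls == []


def test_single_deletion_matches_exhaustive_oracle():
    ref, query = "ACGTACGT", "ACGACGT"
    assert alignment_score(ref, query) == enumerate_alignment_score(ref, query)
    _aln, calls = align_and_call_indels(ref, query)
    assert len(calls) == 1
    call = calls[0]
    assert (call.kind, call.length) == ("deletion", 1)
    # left-normalized: deleting T at offset 3 and at offset 7 both yield the
    # query; the smallest offset is reported
    assert call.ref_pos == 3
    assert ref[: call.ref_pos] + ref[call.ref_pos + 1 :] == query


def test_left_normalization_shifts_through_homopolymer():
    ref = "GGTTTTTTACC"
    query = "GGTTTTACC"  # two T deleted somewhere in the run
    _aln, calls = align_and_call_indels(ref, query)
    assert [(c.kind, c.length, c.ref_pos) for c in calls] == [("deletion", 2, 2)]
    ins_ref = "GGTTACC"
    ins_query = "GGTTTTACC"
    _aln, calls = align_and_call_indels(ins_ref, ins_query)
    assert [(c.kind, c.length, c.ref_pos) for c in calls] == [("insertion", 2, 2)]
    assert calls[0].allele_query == "TT"


@given(st.data())
@settings(max_examples=150)
def test_signed_length_conservation(data):
    """Sum of signed indel lengths == query length - ref length."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    bases = np.array(list("ACGT"))
    ref = "".join(bases[rng.integers(0, 4, int(rng.integers(40, 200)))])
    out = list(ref)
    for _ in range(int(rng.integers(0, 4))):
        pos = int(rng.integers(5, len(out) - 10))
        length = int(rng.integers(1, 8))
        if rng.random() < 0.5:
            del out[pos : pos + length]
        else:
            out[pos:pos] = list(bases[rng.integers(0, 4, length)])
    query = "".join(out)
    _aln, calls = align_and_call_indels(ref, query)
    assert sum(c.signed_length for c in calls) == len(query) - len(ref)
    positions = [(c.ref_pos, c.ref_pos + (c.length if c.kind == "deletion" else 0))
                 for c in calls]
    assert positions == sorted(positions)  # non-overlapping, ordered


def test_affine_score_equals_gotoh_dp_for_short_pairs():
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    for _ in range(60):
        a = "".join(bases[rng.integers(0, 4, int(rng.integers(1, 13)))])
        b = "".join(bases[rng.integers(0, 4, int(rng.integers(1, 13)))])
        assert alignment_score(a, b) == gotoh_score(a, b)


def test_gotoh_oracle_agrees_with_full_enumeration():
    """Validates the DP oracle itself on exhaustively enumerable sizes."""
    rng = np.random.default_rng(13)
    bases = np.array(list("ACGT"))
    for _ in range(25):
        a = "".join(bases[rng.integers(0, 4, int(rng.integers(1, 7)))])
        b = "".join(bases[rng.integers(0, 4, int(rng.integers(1, 7)))])
        assert gotoh_score(a, b) == enumerate_alignment_score(a, b)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_and_call_indels("", "ACGT")


# ----------------------------------------------- anchored intron realignment


def test_anchored_call_interior_deletion_and_signed_sum():
    ref = _random_seq(300, 17)
    query_homolog = ref[:140] + ref[158:]  # 18-base interior deletion
    window = _random_seq(60, 18) + query_homolog + _random_seq(60, 19)
    q0, q1, calls = anchored_call_indels(ref, window)
    assert (q0, q1) == (60, 60 + len(query_homolog))
    assert [(c.kind, c.length) for c in calls] == [("deletion", 18)]
    assert sum(c.signed_length for c in calls) == (q1 - q0) - len(ref)


def test_exon_anchors_rescue_near_terminal_deletion():
    """A large deletion near the intron end is mis-scored without anchors:
    trading the gap for overhang mismatches is cheaper. Conserved exon
    anchors pin the boundary and recover the planted event."""
    ref = _random_seq(300, 17)
    left, right = _random_seq(80, 31), _random_seq(80, 32)
    query_homolog = ref[:278] + ref[296:]  # deletion ending 4 bases from the end
    inner = query_homolog + right[:40] + _random_seq(20, 19)
    window_unanchored = _random_seq(60, 18) + inner
    _q0, q1_plain, calls_plain = anchored_call_indels(ref, window_unanchored)
    assert sum(c.signed_length for c in calls_plain) != -18  # the failure mode
    window = _random_seq(20, 18) + left[-40:] + inner
    q0, q1, calls = call_intron_indels(ref, left[-40:], right[:40], window)
    assert (q0, q1) == (60, 60 + len(query_homolog))
    assert [(c.kind, c.length) for c in calls] == [("deletion", 18)]
    assert sum(c.signed_length for c in calls) == (q1 - q0) - len(ref)


def test_call_intron_indels_uses_exon_anchors():
    intron = _random_seq(300, 20)
    left, right = _random_seq(80, 21), _random_seq(80, 22)
    query_homolog = intron[:100] + intron[103:]  # 3-base deletion
    window = _random_seq(30, 23) + left[-40:] + query_homolog + right[:40] + _random_seq(30, 24)
    q0, q1, calls = call_intron_indels(intron, left[-40:], right[:40], window)
    assert (q0, q1) == (70, 70 + len(query_homolog))
    assert [(c.kind, c.length) for c in calls] == [("deletion", 3)]
    assert sum(c.signed_length for c in calls) == (q1 - q0) - len(intron)
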