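"""Intron homology search in a query genome, InDel calling, ILP conversion.

Each reference intron is located in the query genome by exact k-mer seeding
followed by local alignment (seed-and-extend, affine gaps); candidates are
gated on Karlin-Altschul bit score and E-value, mirroring a BLASTN-style
search. The surviving homolog is then globally aligned to the reference
intron, gaps are merged into InDel calls and left-normalized (the variant
convention: every indel is shifted to the smallest reference offset that
preserves the alignment), and the parent intron-spanning marker is converted
into an intron-length-polymorphism (ILP) marker whose predicted
fragment-length polymorphism (FLP) comes from in-silico PCR of the same
primer pair on both genomes.

Net FLP (|reference - query| amplicon) is the primary statistic - it is what
a gel resolves - with gross FLP (sum of |indel| lengths) reported alongside.
Markers whose indels balance out to net 0 are excluded from ILP conversion
and surfaced separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .genome_io import Genome, GenomeSequence, revcomp
from .ispcr import predict_amplicons
from .primer_design import IsmMarker

log = logging.getLogger(__name__)

#: net FLP (bp) resolvable on a 2.5% agarose gel; smaller differences need
#: amplicon sequencing.
GEL_FLP_THRESHOLD = 10


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scoring; a gap of length L costs gap_open + gap_extend*L."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = mode
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        # Biopython charges open_gap_score on the first gap column and
        # extend_gap_score on each subsequent one: open+extend on column 1
        # reproduces the open + extend-per-base convention above.
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al


@dataclass(frozen=True)
class HomologyConfig:
    """Thresholds for the seed-and-extend homology search.

    Defaults carry the BLASTN-like Karlin-Altschul parameters for +1/-2
    scoring (lambda=1.28, K=0.46) and the rice-genome-scale gates
    (bit >= 500, E <= 1e-50; an "E-value of 0" printed by BLAST is an
    underflow, so a finite cap is used). On small simulated genomes the
    gates should be scaled to the search space (see docs).
    """

    k: int = 13
    min_bit_score: float = 500.0
    max_evalue: float = 1e-50
    ambiguity_margin: float = 0.95
    ka_lambda: float = 1.28
    ka_kappa: float = 0.46
    seed_step: int = 3
    max_clusters: int = 5
    window_pad: int = 60
    diag_tolerance: int = 40
    scoring: AlignScoring = field(default_factory=AlignScoring)

    def __post_init__(self) -> None:
        if not 8 <= self.k <= 32:
            raise ValueError("k must be in [8, 32]")


@dataclass(frozen=True)
class HomologyMatch:
    intron_ref: tuple[str, int]  # (gene_id, ordinal)
    query_seq_id: str
    query_start: int
    query_end: int
    strand_rel: str  # {'same', 'opposite'}
    raw_score: float
    bit_score: float
    e_value: float
    identity_pct: float
    ambiguous: bool = False


@dataclass(frozen=True)
class IndelCall:
    """One insertion/deletion relative to the reference intron.

    ref_pos is the 0-based offset within the (gene-strand) intron sequence:
    for a deletion, the first deleted base; for an insertion, the number of
    reference bases preceding the inserted material.
    """

    ref_pos: int
    kind: str  # {'insertion', 'deletion'}
    length: int
    allele_ref: str
    allele_query: str

    @property
    def signed_length(self) -> int:
        return self.length if self.kind == "insertion" else -self.length


@dataclass
class IlpMarker:
    marker_id: str
    parent_ism_id: str
    gene_id: str
    seq_id: str
    indels: list[IndelCall]
    ref_amplicon_len: int
    query_amplicon_len: int
    flp_net: int
    flp_gross: int
    assay_tier: str  # {'gel', 'sequencing'}
    match: HomologyMatch | None = None


def bit_score(raw_score: float, ka_lambda: float = 1.28, ka_kappa: float = 0.46) -> float:
    """Karlin-Altschul normalized score: (lambda*S - ln K) / ln 2."""
    return (ka_lambda * raw_score - math.log(ka_kappa)) / math.log(2.0)


def e_value(raw_score: float, m: int, n: int,
            ka_lambda: float = 1.28, ka_kappa: float = 0.46) -> float:
    """Expected chance alignments: K*m*n*exp(-lambda*S), search space m*n."""
    return ka_kappa * m * n * math.exp(-ka_lambda * raw_score)


class KmerIndex:
    """Exact k-mer position index of a query genome (forward strand).

    Opposite-strand homology is found by seeding with the reverse
    complement of the probe, so a forward index covers both strands.
    K-mers containing N are not indexed.
    """

    def __init__(self, genome: Genome | Mapping[str, GenomeSequence], k: int = 13):
        if not 8 <= k <= 32:
            raise ValueError("k must be in [8, 32]")
        self.k = k
        self.genome = genome
        self.total_length = sum(
            len(g.residues if isinstance(g, GenomeSequence) else g)
            for g in genome.values()
        )
        self._index: dict[str, list[tuple[str, int]]] = {}
        for seq_id, gs in genome.items():
            seq = gs.residues if isinstance(gs, GenomeSequence) else str(gs)
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((seq_id, i))

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._index.values())

    def fetch(self, seq_id: str, start: int, end: int) -> str:
        gs = self.genome[seq_id]
        seq = gs.residues if isinstance(gs, GenomeSequence) else str(gs)
        return seq[max(0, start) : end]

    def seq_length(self, seq_id: str) -> int:
        gs = self.genome[seq_id]
        return len(gs.residues if isinstance(gs, GenomeSequence) else gs)


def _seed_clusters(oriented_seq: str, index: KmerIndex, cfg: HomologyConfig):
    """Group seed hits into (seq_id, diagonal-band) clusters."""
    k = index.k
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for i in range(0, len(oriented_seq) - k + 1, cfg.seed_step):
        kmer = oriented_seq[i : i + k]
        if "N" in kmer:
            continue
        for seq_id, pos in index.hits(kmer):
            by_seq.setdefault(seq_id, []).append((pos - i, i))
    clusters = []
    for seq_id, diags in by_seq.items():
        diags.sort()
        group: list[tuple[int, int]] = []
        for d, i in diags:
            if group and d - group[-1][0] > cfg.diag_tolerance:
                clusters.append((seq_id, group))
                group = []
            group.append((d, i))
        if group:
            clusters.append((seq_id, group))
    # Largest clusters first; deterministic tie-break on locus.
    clusters.sort(key=lambda c: (-len(c[1]), c[0], c[1][0][0]))
    return clusters[: cfg.max_clusters]


def _alignment_blocks(alignment, len_t: int, len_q: int):
    """Aligned blocks plus virtual (0,0)/(end,end) anchors for gap walking."""
    t_blocks, q_blocks = alignment.aligned
    blocks = [((int(t0), int(t1)), (int(q0), int(q1)))
              for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks)]
    return blocks


def _identity_pct(alignment, target: str, query: str) -> float:
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(*(alignment.aligned)):
        if prev_t is not None:
            columns += (t0 - prev_t) + (q0 - prev_q)  # gap columns
        sub_t = target[t0:t1]
        sub_q = query[q0:q1]
        matches += sum(a == b for a, b in zip(sub_t, sub_q))
        columns += t1 - t0
        prev_t, prev_q = t1, q1
    return 100.0 * matches / columns if columns else 0.0


def map_intron_to_query(
    intron_seq: str,
    index: KmerIndex,
    cfg: HomologyConfig = HomologyConfig(),
    intron_ref: tuple[str, int] = ("", 0),
) -> HomologyMatch | None:
    """Best query-genome locus for a reference intron, or None.

    Seed k-mers (both orientations) are clustered by diagonal; the top
    clusters are locally aligned and scored. Candidates failing the bit
    score / E-value gates are discarded. If the runner-up at a distinct
    locus scores within ``ambiguity_margin`` of the best, the match is
    flagged ambiguous (and excluded from ILP conversion downstream).
    """
    if len(intron_seq) < index.k:
        return None
    local = cfg.scoring.aligner("local")
    m = len(intron_seq)
    n = index.total_length
    candidates: list[HomologyMatch] = []
    for strand_rel, oriented in (("same", intron_seq), ("opposite", revcomp(intron_seq))):
        for seq_id, group in _seed_clusters(oriented, index, cfg):
            d_lo = group[0][0]
            d_hi = group[-1][0]
            wstart = max(0, d_lo - cfg.window_pad)
            wend = min(index.seq_length(seq_id), d_hi + len(oriented) + cfg.window_pad)
            window = index.fetch(seq_id, wstart, wend)
            if not window:
                continue
            alignments = local.align(oriented, window)
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            raw = aln.score
            blocks = _alignment_blocks(aln, len(oriented), len(window))
            if not blocks:
                continue
            (t0, _), (q0, _) = blocks[0]
            (_, t1), (_, q1) = blocks[-1]
            # Extend to cover unaligned intron overhangs so the interval
            # approximates the full homolog, clamped to the chromosome.
            qs = max(0, wstart + q0 - t0)
            qe = min(index.seq_length(seq_id), wstart + q1 + (len(oriented) - t1))
            candidates.append(
                HomologyMatch(
                    intron_ref=intron_ref,
                    query_seq_id=seq_id,
                    query_start=qs,
                    query_end=qe,
                    strand_rel=strand_rel,
                    raw_score=raw,
                    bit_score=bit_score(raw, cfg.ka_lambda, cfg.ka_kappa),
                    e_value=e_value(raw, m, n, cfg.ka_lambda, cfg.ka_kappa),
                    identity_pct=round(_identity_pct(aln, oriented, window), 2),
                )
            )
    candidates = [
        c for c in candidates
        if c.bit_score >= cfg.min_bit_score and c.e_value <= cfg.max_evalue
    ]
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c.bit_score, c.query_seq_id, c.query_start))
    best = candidates[0]
    for other in candidates[1:]:
        same_locus = (
            other.query_seq_id == best.query_seq_id
            and other.query_start < best.query_end
            and best.query_start < other.query_end
        )
        if not same_locus and other.bit_score >= cfg.ambiguity_margin * best.bit_score:
            return replace(best, ambiguous=True)
    return best


def _left_normalize(call: IndelCall, ref: str, floor: int = 0) -> IndelCall:
    """Shift an indel to the smallest ref offset preserving the alignment."""
    if call.kind == "deletion":
        pos = call.ref_pos
        L = call.length
        while pos > floor and ref[pos - 1] == ref[pos + L - 1]:
            pos -= 1
        if pos == call.ref_pos:
            return call
        return IndelCall(pos, "deletion", L, ref[pos : pos + L], "")
    pos = call.ref_pos
    ins = call.allele_query
    while pos > floor and ins[-1] == ref[pos - 1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    if pos == call.ref_pos:
        return call
    return IndelCall(pos, "insertion", call.length, "", ins)


def align_and_call_indels(
    ref_seq: str,
    query_seq: str,
    scoring: AlignScoring = AlignScoring(),
) -> tuple[object, list[IndelCall]]:
    """Global affine-gap alignment and merged, left-normalized InDel calls.

    Adjacent gap columns of the same kind merge into one call; the signed
    lengths always sum to len(query) - len(ref).
    """
    if not ref_seq or not query_seq:
        raise ValueError("align_and_call_indels requires non-empty sequences")
    aligner = scoring.aligner("global")
    aln = aligner.align(ref_seq, query_seq)[0]
    blocks = _alignment_blocks(aln, len(ref_seq), len(query_seq))
    anchored = [((0, 0), (0, 0))] + blocks + [
        ((len(ref_seq), len(ref_seq)), (len(query_seq), len(query_seq)))
    ]
    calls: list[IndelCall] = []
    for ((_, te), (_, qe)), ((ts, _), (qs, _)) in zip(anchored, anchored[1:]):
        if ts > te:  # reference bases absent from query: deletion
            calls.append(IndelCall(te, "deletion", ts - te, ref_seq[te:ts], ""))
        if qs > qe:  # query bases absent from reference: insertion
            calls.append(IndelCall(ts if ts > te else te, "insertion",
                                   qs - qe, "", query_seq[qe:qs]))
    normalized: list[IndelCall] = []
    floor = 0
    for call in sorted(calls, key=lambda c: c.ref_pos):
        norm = _left_normalize(call, ref_seq, floor)
        normalized.append(norm)
        floor = norm.ref_pos + (norm.length if norm.kind == "deletion" else 0)
    return aln, normalized


def alignment_score(a: str, b: str, scoring: AlignScoring = AlignScoring()) -> float:
    """Optimal global affine-gap alignment score (end gaps penalized)."""
    return scoring.aligner("global").score(a, b)


def _semi_global_calls(
    ref_seq: str, window_seq: str, scoring: AlignScoring
) -> tuple[list, list[IndelCall]]:
    """Blocks and raw (unnormalized) calls of a window-overhang-free alignment.

    The window overhangs beyond the reference are free (end insertions score
    0), internal gaps keep full affine cost, and reference bases left
    unaligned at either end surface as terminal deletions.
    """
    if not ref_seq or not window_seq:
        raise ValueError("semi-global alignment requires non-empty sequences")
    aligner = scoring.aligner("global")
    aligner.end_insertion_score = 0.0  # free window overhang
    aln = aligner.align(ref_seq, window_seq)[0]
    blocks = _alignment_blocks(aln, len(ref_seq), len(window_seq))
    if not blocks:
        raise ValueError("anchored alignment produced no aligned blocks")
    (t_first, _), _ = blocks[0]
    (_, t_last), _ = blocks[-1]
    calls: list[IndelCall] = []
    if t_first > 0:  # terminal deletion at the reference start
        calls.append(IndelCall(0, "deletion", t_first, ref_seq[:t_first], ""))
    for ((_, te), (_, qe)), ((ts, _), (qs, _)) in zip(blocks, blocks[1:]):
        if ts > te:
            calls.append(IndelCall(te, "deletion", ts - te, ref_seq[te:ts], ""))
        if qs > qe:
            calls.append(IndelCall(ts if ts > te else te, "insertion",
                                   qs - qe, "", window_seq[qe:qs]))
    if t_last < len(ref_seq):  # terminal deletion at the reference end
        calls.append(IndelCall(t_last, "deletion", len(ref_seq) - t_last,
                               ref_seq[t_last:], ""))
    return blocks, sorted(calls, key=lambda c: c.ref_pos)


def _normalize_calls(calls: list[IndelCall], ref_seq: str) -> list[IndelCall]:
    normalized: list[IndelCall] = []
    floor = 0
    for call in calls:
        norm = _left_normalize(call, ref_seq, floor)
        normalized.append(norm)
        floor = norm.ref_pos + (norm.length if norm.kind == "deletion" else 0)
    return normalized


def anchored_call_indels(
    ref_seq: str,
    window_seq: str,
    scoring: AlignScoring = AlignScoring(),
) -> tuple[int, int, list[IndelCall]]:
    """Anchor a full reference sequence inside a longer query window.

    Returns ``(q_start, q_end, indels)``: window offsets of the homolog and
    left-normalized InDel calls. By construction the signed indel lengths
    sum to (q_end - q_start) - len(ref_seq).
    """
    blocks, calls = _semi_global_calls(ref_seq, window_seq, scoring)
    q_first = blocks[0][1][0]
    q_last = blocks[-1][1][1]
    return q_first, q_last, _normalize_calls(calls, ref_seq)


def _query_pos_of(blocks, ref_pos: int) -> int:
    """Window offset aligned to a reference offset.

    Positions inside a deletion map to the gap's (single) query coordinate;
    a position at the start of a block following an insertion maps AFTER
    the inserted bases.
    """
    prev_q = blocks[0][1][0]
    for (t0, t1), (q0, q1) in blocks:
        if ref_pos < t0:  # inside a deletion gap
            return q0
        if t0 <= ref_pos < t1:
            return q0 + (ref_pos - t0)
        prev_q = q1
    return prev_q


def call_intron_indels(
    intron_seq: str,
    left_anchor: str,
    right_anchor: str,
    window_seq: str,
    scoring: AlignScoring = AlignScoring(),
) -> tuple[int, int, list[IndelCall]]:
    """InDel calls for one intron, anchored by its conserved exon flanks.

    The composite left_anchor + intron + right_anchor is aligned to the
    query window semi-globally; the exact-matching exon anchors pin the
    intron boundaries, which keeps large indels near an intron end from
    being traded for spurious matches in flanking sequence. Calls are
    reported in intron-local offsets, left-normalized within the intron;
    insertions landing exactly on the upstream boundary are assigned to the
    flank (excluded), those on the downstream boundary to the intron, and
    boundary-straddling deletions are clipped to the intron, so the signed
    call lengths always equal (q_end - q_start) - len(intron_seq) for the
    returned window offsets of the intron homolog.
    """
    la = len(left_anchor)
    L = len(intron_seq)
    composite = left_anchor + intron_seq + right_anchor
    blocks, raw_calls = _semi_global_calls(composite, window_seq, scoring)
    q_start = _query_pos_of(blocks, la)
    q_end = _query_pos_of(blocks, la + L)
    intron_calls: list[IndelCall] = []
    for call in raw_calls:
        if call.kind == "insertion":
            if la < call.ref_pos <= la + L:
                intron_calls.append(replace(call, ref_pos=call.ref_pos - la))
            continue
        # Deletion: clip to the intron interval.
        d0 = max(call.ref_pos, la)
        d1 = min(call.ref_pos + call.length, la + L)
        if d1 <= d0:
            continue
        intron_calls.append(
            IndelCall(d0 - la, "deletion", d1 - d0, intron_seq[d0 - la : d1 - la], "")
        )
    return q_start, q_end, _normalize_calls(intron_calls, intron_seq)


def convert_to_ilp(
    ism: IsmMarker,
    match: HomologyMatch,
    indels: Sequence[IndelCall],
    ref_genome: Genome,
    query_genome: Genome,
    max_product: int = 3000,
) -> tuple[IlpMarker | None, str]:
    """Convert an ISM into an ILP marker, reusing the ISM primers verbatim.

    Returns (marker, reason); marker is None when conversion is refused.
    Amplicon lengths on both genomes come from in-silico PCR; conversion
    requires a single product on each genome. Balanced indels (net 0) are
    refused with reason 'balanced_indels' for the caller's side table.
    """
    if not indels:
        return None, "no_indels"
    if match.ambiguous:
        return None, "ambiguous_homology"
    pp = ism.primer_pair
    ref_amps = predict_amplicons(pp.fwd_seq, pp.rev_seq, ref_genome, max_product)
    if len(ref_amps) != 1:
        return None, "nonunique_ref_binding"
    query_amps = predict_amplicons(pp.fwd_seq, pp.rev_seq, query_genome, max_product)
    if len(query_amps) == 0:
        return None, "no_query_amplicon"
    if len(query_amps) > 1:
        return None, "nonunique_query_binding"
    ref_len = ref_amps[0].length
    query_len = query_amps[0].length
    flp_net = abs(ref_len - query_len)
    flp_gross = sum(c.length for c in indels)
    if flp_net == 0:
        return None, "balanced_indels"
    marker = IlpMarker(
        marker_id="",
        parent_ism_id=ism.marker_id,
        gene_id=ism.gene_id,
        seq_id=ism.seq_id,
        indels=list(indels),
        ref_amplicon_len=ref_len,
        query_amplicon_len=query_len,
        flp_net=flp_net,
        flp_gross=flp_gross,
        assay_tier="gel" if flp_net >= GEL_FLP_THRESHOLD else "sequencing",
        match=match,
    )
    return marker, "converted"


def ilp_table(markers: Iterable[IlpMarker]) -> pd.DataFrame:
    rows = [
        {
            "marker_id": m.marker_id,
            "parent_ism_id": m.parent_ism_id,
            "gene_id": m.gene_id,
            "seq_id": m.seq_id,
            "ref_amp_len": m.ref_amplicon_len,
            "query_amp_len": m.query_amplicon_len,
            "flp_net": m.flp_net,
            "flp_gross": m.flp_gross,
            "n_indels": len(m.indels),
            "assay_tier": m.assay_tier,
        }
        for m in markers
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id",
            "parent_ism_id",
            "gene_id",
            "seq_id",
            "ref_amp_len",
            "query_amp_len",
            "flp_net",
            "flp_gross",
            "n_indels",
            "assay_tier",
        ],
    )


def indels_table(markers: Iterable[IlpMarker], introns_by_key: Mapping) -> pd.DataFrame:
    """Minimal VCF-like indel table (CHROM, POS_1based, REF, ALT, marker_id).

    Positions are anchored one base left of the event within the intron's
    gene-strand sequence, translated to chromosome coordinates where the
    intron lies on the plus strand; for minus-strand genes the offset refers
    to the gene-strand intron sequence and the chromosome is still named.
    """
    rows = []
    for m in markers:
        intron = introns_by_key.get((m.gene_id, _ordinal_of(m)), None)
        for c in m.indels:
            if intron is not None and intron.strand == "+":
                pos_1 = intron.start + c.ref_pos  # anchor base before event
                anchor = intron.sequence[c.ref_pos - 1] if c.ref_pos > 0 else "."
            elif intron is not None:
                pos_1 = intron.end - c.ref_pos
                anchor = intron.sequence[c.ref_pos - 1] if c.ref_pos > 0 else "."
            else:
                pos_1, anchor = c.ref_pos, "."
            if c.kind == "deletion":
                ref_allele, alt_allele = anchor + c.allele_ref, anchor
            else:
                ref_allele, alt_allele = anchor, anchor + c.allele_query
            rows.append(
                {
                    "CHROM": m.seq_id,
                    "POS_1based": pos_1,
                    "REF": ref_allele,
                    "ALT": alt_allele,
                    "marker_id": m.marker_id,
                }
            )
    return pd.DataFrame(rows, columns=["CHROM", "POS_1based", "REF", "ALT", "marker_id"])


def _ordinal_of(marker: IlpMarker) -> int:
    if marker.match is not None:
        return marker.match.intron_ref[1]
    return 0
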