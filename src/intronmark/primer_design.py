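"""ISM primer design inside the exonic windows flanking each intron.

The forward primer is a window of the left (upstream-exon) flank and the
reverse primer the reverse complement of a window of the right
(downstream-exon) flank, both in transcript orientation, so every accepted
pair amplifies across the target intron. A separate expression-assay mode
additionally constrains the spliced (cDNA) product to a short window so that
genomic and cDNA amplicons are distinguishable on a gel.

Melting temperatures come from the unified SantaLucia (1998) nearest-neighbor
thermodynamic table with the entropic salt correction
dS' = dS + 0.368*(N-1)*ln[Na+]; duplex concentration enters as R*ln(C/4)
(primer in excess over a non-self-complementary template). Candidate pairs
are ranked by an additive penalty; no attempt is made to reproduce Primer3's
objective to the decimal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import Intron, revcomp

log = logging.getLogger(__name__)

R_GAS = 1.987  # cal / (K mol)

# Unified nearest-neighbor parameters, SantaLucia (1998):
# dH in kcal/mol, dS in cal/(mol K), per propagation step 5'-XY-3'.
NN_DH_DS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# The table is complete under reverse complement: dG(XY) == dG(rc(XY)).
for _k in list(NN_DH_DS):
    NN_DH_DS.setdefault(revcomp(_k), NN_DH_DS[_k])

# Duplex initiation terms: terminal G·C vs terminal A·T.
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)


def wallace_tm(seq: str) -> float:
    """Wallace rule 2(A+T)+4(G+C) — short-oligo sanity formula only."""
    seq = seq.upper()
    return 2 * (seq.count("A") + seq.count("T")) + 4 * (seq.count("G") + seq.count("C"))


def melting_temperature(
    seq: str, salt_mM: float = 50.0, primer_uM: float = 0.25
) -> float:
    """Nearest-neighbor melting temperature (deg C) of a primer.

    Deterministic closed form: Tm = 1000*dH / (dS' + R ln(C/4)) - 273.15
    with dS' salt-corrected as in the module docstring. Sequences must be
    >= 8 bases of pure {A,C,G,T}.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("melting_temperature needs >= 8 bases")
    if set(seq) - set("ACGT"):
        raise ValueError(f"melting_temperature: non-ACGT residue in {seq!r}")
    dh = 0.0
    ds = 0.0
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_AT if terminal in "AT" else INIT_GC
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = NN_DH_DS[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    c_molar = primer_uM * 1e-6
    return 1000.0 * dh / (ds + R_GAS * math.log(c_molar / 4.0)) - 273.15


def gc_percent(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def three_prime_homopolymer(seq: str) -> int:
    run = 1
    for i in range(len(seq) - 1, 0, -1):
        if seq[i - 1] == seq[i]:
            run += 1
        else:
            break
    return run


def has_self_complementarity(seq: str, min_stem: int = 8) -> bool:
    """True if the primer contains a perfect inverted repeat >= min_stem.

    Two k-mers (possibly the same palindromic one) that are reverse
    complements of each other can fold into a hairpin stem or drive a
    self-dimer; such primers are rejected outright.
    """
    if len(seq) < min_stem:
        return False
    kmers = {seq[i : i + min_stem] for i in range(len(seq) - min_stem + 1)}
    return any(revcomp(k) in kmers for k in kmers)


@dataclass(frozen=True)
class PenaltyWeights:
    tm: float = 1.0
    length: float = 0.5
    gc: float = 0.5
    tm_diff: float = 1.0
    end_homopolymer: float = 0.5


@dataclass(frozen=True)
class DesignConstraints:
    """Hard constraints and targets for primer-pair design.

    Defaults: primers 18/20/27 bases, Tm 57/60/63 degC, GC 40-60%,
    homopolymers <= 4, genomic product 100-1000 bp (bracketing the ~464 bp
    products typical of intron-spanning assays), expression-mode cDNA
    product 60-100 bp, 100-base flank windows, 50 mM Na+, 0.25 uM primer.
    """

    primer_len: tuple[int, int, int] = (18, 20, 27)
    tm_c: tuple[float, float, float] = (57.0, 60.0, 63.0)
    gc_pct: tuple[float, float] = (40.0, 60.0)
    max_homopolymer: int = 4
    genomic_product: tuple[int, int] = (100, 1000)
    cdna_product: tuple[int, int] = (60, 100)
    flank_window: int = 100
    salt_mM: float = 50.0
    primer_uM: float = 0.25
    min_self_complement_stem: int = 8
    max_candidates_per_side: int = 40
    weights: PenaltyWeights = field(default_factory=PenaltyWeights)

    def __post_init__(self) -> None:
        for lo, opt, hi in (self.primer_len, self.tm_c):
            if not lo <= opt <= hi:
                raise ValueError("constraint triple must satisfy min <= opt <= max")
        if self.flank_window < self.primer_len[0]:
            raise ValueError("flank_window must be >= minimum primer length")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair spanning one intron.

    fwd_pos / rev_pos are 0-based chromosome coordinates of each primer's
    5' end; genomic_amplicon_len - cdna_amplicon_len equals the enclosed
    intron length.
    """

    fwd_seq: str
    rev_seq: str
    fwd_pos: int
    rev_pos: int
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    genomic_amplicon_len: int
    cdna_amplicon_len: int
    penalty: float


@dataclass(frozen=True)
class IsmMarker:
    marker_id: str
    gene_id: str
    intron_ordinal: int
    seq_id: str
    primer_pair: PrimerPair
    target_intron_len: int


@dataclass(frozen=True)
class _Candidate:
    offset: int  # window start within the flank (transcript orientation)
    length: int
    seq: str  # primer sequence 5'->3'
    tm: float
    gc: float
    penalty: float


def primer_penalty(
    tm: float,
    length: int,
    gc: float,
    seq: str,
    constraints: DesignConstraints,
) -> float:
    """Additive single-primer penalty; strictly monotone in each deviation."""
    w = constraints.weights
    lo_gc, hi_gc = constraints.gc_pct
    gc_out = max(0.0, lo_gc - gc, gc - hi_gc)
    return (
        w.tm * abs(tm - constraints.tm_c[1])
        + w.length * abs(length - constraints.primer_len[1])
        + w.gc * gc_out
        + w.end_homopolymer * max(0, three_prime_homopolymer(seq) - 2)
    )


def pair_penalty(fwd: _Candidate, rev: _Candidate, constraints: DesignConstraints) -> float:
    return fwd.penalty + rev.penalty + constraints.weights.tm_diff * abs(fwd.tm - rev.tm)


def _enumerate_side(
    flank: str, constraints: DesignConstraints, reverse: bool
) -> list[_Candidate]:
    """All windows of one flank passing the hard single-primer filters.

    For the reverse side the primer is the reverse complement of the window.
    The list is truncated to the best ``max_candidates_per_side`` by
    (penalty, offset, length) so pairing stays tractable and deterministic.
    """
    lo, _opt, hi = constraints.primer_len
    out: list[_Candidate] = []
    for length in range(lo, hi + 1):
        for off in range(0, len(flank) - length + 1):
            window = flank[off : off + length]
            primer = revcomp(window) if reverse else window
            gc = gc_percent(primer)
            if not constraints.gc_pct[0] <= gc <= constraints.gc_pct[1]:
                continue
            if max_homopolymer(primer) > constraints.max_homopolymer:
                continue
            if has_self_complementarity(primer, constraints.min_self_complement_stem):
                continue
            tm = melting_temperature(primer, constraints.salt_mM, constraints.primer_uM)
            if not constraints.tm_c[0] <= tm <= constraints.tm_c[2]:
                continue
            out.append(
                _Candidate(off, length, primer, tm, gc,
                           primer_penalty(tm, length, gc, primer, constraints))
            )
    out.sort(key=lambda c: (c.penalty, c.offset, c.length))
    return out[: constraints.max_candidates_per_side]


def _chromosome_positions(
    intron: Intron, fwd: _Candidate, rev: _Candidate, lf: int
) -> tuple[int, int]:
    """0-based chromosome coordinates of the two primer 5' ends."""
    fwd_tail = lf - fwd.offset  # bases from fwd 5' end to intron start
    rev_head = rev.offset + rev.length  # bases from intron end to rev 5' end
    if intron.strand == "+":
        return intron.start - fwd_tail, intron.end + rev_head - 1
    return intron.end + fwd_tail - 1, intron.start - rev_head


def design_ism_primers(
    intron: Intron,
    constraints: DesignConstraints = DesignConstraints(),
    expression_mode: bool = False,
) -> list[PrimerPair]:
    """Design ranked primer pairs spanning ``intron``.

    Returns an empty list (never an error) when no candidate satisfies the
    hard constraints; flanks shorter than the minimum primer length or
    containing N are refused with a logged reason. In ``expression_mode``
    the spliced (cDNA) product must also fall within ``cdna_product``.
    """
    lo = constraints.primer_len[0]
    for side, flank in (("left", intron.left_flank), ("right", intron.right_flank)):
        if len(flank) < lo:
            log.debug("%s intron %d: flank_too_short (%s)", intron.gene_id, intron.ordinal, side)
            return []
        if "N" in flank:
            log.debug("%s intron %d: flank_contains_N (%s)", intron.gene_id, intron.ordinal, side)
            return []
    fwd_cands = _enumerate_side(intron.left_flank, constraints, reverse=False)
    rev_cands = _enumerate_side(intron.right_flank, constraints, reverse=True)
    lf = len(intron.left_flank)
    pairs: list[PrimerPair] = []
    for f in fwd_cands:
        fwd_tail = lf - f.offset
        for r in rev_cands:
            rev_head = r.offset + r.length
            cdna_len = fwd_tail + rev_head
            genomic_len = cdna_len + intron.length
            if not constraints.genomic_product[0] <= genomic_len <= constraints.genomic_product[1]:
                continue
            if expression_mode and not (
                constraints.cdna_product[0] <= cdna_len <= constraints.cdna_product[1]
            ):
                continue
            fpos, rpos = _chromosome_positions(intron, f, r, lf)
            pairs.append(
                PrimerPair(
                    fwd_seq=f.seq,
                    rev_seq=r.seq,
                    fwd_pos=fpos,
                    rev_pos=rpos,
                    fwd_tm=f.tm,
                    rev_tm=r.tm,
                    fwd_gc=f.gc,
                    rev_gc=r.gc,
                    genomic_amplicon_len=genomic_len,
                    cdna_amplicon_len=cdna_len,
                    penalty=pair_penalty(f, r, constraints),
                )
            )
    pairs.sort(key=lambda p: (p.penalty, p.fwd_pos, p.rev_pos))
    return pairs


def design_expression_primers(
    intron: Intron,
    constraints: DesignConstraints = DesignConstraints(),
) -> list[PrimerPair]:
    """Expression-assay mode: cDNA product constrained to ``cdna_product``."""
    return design_ism_primers(intron, constraints, expression_mode=True)


def select_markers_per_gene(
    candidates: Mapping[str, Sequence[tuple[Intron, PrimerPair]]],
    k: int = 4,
    id_prefix: str = "OsISM",
) -> list[IsmMarker]:
    """Pick at most ``k`` markers per gene, preferring distinct introns.

    Within a gene the best (lowest-penalty) pair of each intron competes
    first; only if fewer than ``k`` introns have candidates are additional
    pairs from already-used introns admitted, again by penalty. Marker ids
    are assigned genome-wide in chromosome-then-position order.
    """
    selected: list[tuple[Intron, PrimerPair]] = []
    for gene_id in sorted(candidates):
        cands = sorted(
            candidates[gene_id],
            key=lambda ip: (ip[1].penalty, ip[0].ordinal, ip[1].fwd_pos),
        )
        best_per_intron: dict[int, tuple[Intron, PrimerPair]] = {}
        rest: list[tuple[Intron, PrimerPair]] = []
        for intron, pair in cands:
            if intron.ordinal not in best_per_intron:
                best_per_intron[intron.ordinal] = (intron, pair)
            else:
                rest.append((intron, pair))
        primary = sorted(
            best_per_intron.values(), key=lambda ip: (ip[1].penalty, ip[0].ordinal)
        )
        chosen = primary[:k]
        if len(chosen) < k:
            chosen.extend(rest[: k - len(chosen)])
        selected.extend(chosen)
    selected.sort(
        key=lambda ip: (ip[0].seq_id, min(ip[1].fwd_pos, ip[1].rev_pos), ip[0].gene_id)
    )
    return [
        IsmMarker(
            marker_id=f"{id_prefix}{n:05d}",
            gene_id=intron.gene_id,
            intron_ordinal=intron.ordinal,
            seq_id=intron.seq_id,
            primer_pair=pair,
            target_intron_len=intron.length,
        )
        for n, (intron, pair) in enumerate(selected, start=1)
    ]


def markers_table(markers: Iterable[IsmMarker]) -> pd.DataFrame:
    """Marker table with 1-based primer 5'-end coordinates."""
    rows = []
    for m in markers:
        p = m.primer_pair
        rows.append(
            {
                "marker_id": m.marker_id,
                "gene_id": m.gene_id,
                "intron_ordinal": m.intron_ordinal,
                "seq_id": m.seq_id,
                "fwd_seq": p.fwd_seq,
                "rev_seq": p.rev_seq,
                "fwd_start_1based": p.fwd_pos + 1,
                "rev_start_1based": p.rev_pos + 1,
                "fwd_tm": round(p.fwd_tm, 2),
                "rev_tm": round(p.rev_tm, 2),
                "genomic_amplicon_len": p.genomic_amplicon_len,
                "cdna_amplicon_len": p.cdna_amplicon_len,
                "penalty": round(p.penalty, 3),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id",
            "gene_id",
            "intron_ordinal",
            "seq_id",
            "fwd_seq",
            "rev_seq",
            "fwd_start_1based",
            "rev_start_1based",
            "fwd_tm",
            "rev_tm",
            "genomic_amplicon_len",
            "cdna_amplicon_len",
            "penalty",
        ],
    )
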