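"""In-silico PCR: mismatch-tolerant primer binding sites and amplicon prediction.

This module is the pipeline's independent oracle for amplicon lengths and
primer uniqueness: it knows nothing about introns or flanks, it just scans
template sequences. Binding tolerates a bounded number of internal
mismatches but requires the 3'-terminal trinucleotide to match exactly
(polymerase extension is blocked by a mismatched 3' end). Uniqueness is
judged at the amplicon level: two binding sites that cannot form a
convergent product within ``max_product`` do not threaten specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .genome_io import GeneModel, Genome, GenomeSequence, revcomp


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing site; ``pos5`` is the template (+)-strand
    coordinate of the primer's 5' end."""

    seq_id: str
    strand: str  # '+': primer extends rightward; '-': leftward
    pos5: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """Predicted product: [start, end) spans the forward primer 5' end
    through the reverse primer 5' end on the template."""

    seq_id: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan(template: np.ndarray, probe: str, max_mismatch: int,
          exact_3prime_slice: slice | None) -> list[tuple[int, int]]:
    """(start, mismatches) of every window of ``template`` matching ``probe``."""
    m = len(probe)
    if len(template) < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template, m)
    mism = (windows != _as_bytes(probe)).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatch)
    if exact_3prime_slice is not None and hits.size:
        exact = (windows[hits, exact_3prime_slice] ==
                 _as_bytes(probe)[exact_3prime_slice]).all(axis=1)
        hits = hits[exact]
    return [(int(h), int(mism[h])) for h in hits]


def find_binding_sites(
    primer: str,
    sequence: GenomeSequence | str,
    max_mismatch: int = 2,
    require_3prime_exact: bool = True,
    seq_id: str = "",
) -> list[BindingSite]:
    """Locate annealing sites of ``primer`` on both strands of ``sequence``.

    On the '+' strand the primer itself appears in the template and extends
    rightward; on the '-' strand its reverse complement appears and the
    primer extends leftward. N in the template never matches.
    """
    if len(primer) < 15:
        raise ValueError("find_binding_sites requires primer length >= 15")
    if isinstance(sequence, GenomeSequence):
        seq_id = sequence.seq_id
        sequence = sequence.residues
    template = _as_bytes(sequence)
    m = len(primer)
    sites: list[BindingSite] = []
    # '+' strand: primer as-is, 3' end is the window's last 3 bases.
    tail = slice(m - 3, m) if require_3prime_exact else None
    for start, mism in _scan(template, primer, max_mismatch, tail):
        sites.append(BindingSite(seq_id, "+", start, mism))
    # '-' strand: revcomp(primer) in template; primer 3' end maps to the
    # window's FIRST 3 bases, primer 5' end to the window's last base.
    rc = revcomp(primer)
    head = slice(0, 3) if require_3prime_exact else None
    for start, mism in _scan(template, rc, max_mismatch, head):
        sites.append(BindingSite(seq_id, "-", start + m - 1, mism))
    sites.sort(key=lambda s: (s.pos5, s.strand))
    return sites


def predict_amplicons(
    fwd_seq: str,
    rev_seq: str,
    sequences: Genome | Mapping[str, GenomeSequence] | Mapping[str, str],
    max_product: int = 3000,
    max_mismatch: int = 2,
    require_3prime_exact: bool = True,
) -> list[Amplicon]:
    """All convergent products of a primer pair over a sequence collection.

    Both primer-to-strand assignments are considered (the pair amplifies the
    same product from either strand of a duplex template), so the predicted
    length set is invariant under reverse-complementing the template.
    Products shorter than the two primer footprints are impossible and
    discarded; results are sorted by (seq_id, length, start).
    """
    out: list[Amplicon] = []
    min_len = len(fwd_seq) + len(rev_seq)
    for seq_id, gs in sequences.items():
        template = gs.residues if isinstance(gs, GenomeSequence) else str(gs)
        f_sites = find_binding_sites(fwd_seq, template, max_mismatch,
                                     require_3prime_exact, seq_id)
        r_sites = find_binding_sites(rev_seq, template, max_mismatch,
                                     require_3prime_exact, seq_id)
        for left, right, lmm_is_fwd in (
            (f_sites, r_sites, True),   # forward rightward, reverse leftward
            (r_sites, f_sites, False),  # reverse rightward, forward leftward
        ):
            for a in left:
                if a.strand != "+":
                    continue
                for b in right:
                    if b.strand != "-":
                        continue
                    length = b.pos5 + 1 - a.pos5
                    if min_len <= length <= max_product:
                        fm, rm = (a.mismatches, b.mismatches) if lmm_is_fwd \
                            else (b.mismatches, a.mismatches)
                        out.append(Amplicon(seq_id, a.pos5, b.pos5 + 1, fm, rm))
    # De-duplicate products found under both primer assignments (palindromic
    # corner cases) and sort deterministically.
    seen: dict[tuple, Amplicon] = {}
    for amp in out:
        seen.setdefault((amp.seq_id, amp.start, amp.end), amp)
    return sorted(seen.values(), key=lambda a: (a.seq_id, a.length, a.start))


def primer_uniqueness(
    fwd_seq: str,
    rev_seq: str,
    genome: Genome | Mapping[str, str],
    max_product: int = 3000,
    max_mismatch: int = 2,
) -> str:
    """'unique' iff exactly one amplicon genome-wide, else 'multi'/'none'."""
    n = len(predict_amplicons(fwd_seq, rev_seq, genome, max_product, max_mismatch))
    if n == 0:
        return "none"
    return "unique" if n == 1 else "multi"


def splice_cdna(gene: GeneModel, genome: Genome) -> str:
    """Spliced transcript: exons concatenated in transcription order, coding strand."""
    chrom = genome[gene.seq_id].residues
    seq = "".join(chrom[a:b] for a, b in gene.exons)
    return seq if gene.strand == "+" else revcomp(seq)
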