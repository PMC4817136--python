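"""Genome and annotation I/O: FASTA reading, gene-model assembly, intron extraction.

Internal coordinates are 0-based half-open throughout the package; every
emitted table uses 1-based inclusive coordinates (the GFF3 convention).
All intron and flank sequences are reported 5'->3' on the gene (coding)
strand, so downstream primer design never has to think about strand again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_VALID_RESIDUES = set("ACGTNU")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-pairs)."""
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: uppercase DNA over {A,C,G,T,N}."""

    seq_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


class Genome(dict):
    """Mapping seq_id -> GenomeSequence with convenience slicing."""

    def fetch(self, seq_id: str, start: int, end: int) -> str:
        return self[seq_id].residues[start:end]

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.values())


@dataclass
class GeneModel:
    """A gene locus reduced to one transcript's exon chain.

    exons are 0-based half-open [start, end) intervals, sorted ascending by
    start regardless of strand; transcription order is derived from strand.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    te_class: str = "non-TE"
    note: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs at least one exon")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"{self.gene_id}: empty exon interval [{a},{b})")
        for (a0, b0), (a1, b1) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class Intron:
    """An intron plus its up-to-100-base exonic flank windows.

    ``sequence``, ``left_flank`` and ``right_flank`` read 5'->3' on the gene
    strand: left_flank is the 3' end of the upstream exon, right_flank the
    5' start of the downstream exon (transcript orientation).
    """

    gene_id: str
    ordinal: int
    seq_id: str
    start: int
    end: int
    strand: str
    sequence: str
    left_flank: str
    right_flank: str
    has_n: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-record) FASTA file into a :class:`Genome`.

    Residues are uppercased and U is mapped to T; anything outside
    {A,C,G,T,N,U} is rejected. Duplicate ids and empty records are errors;
    an empty file yields an empty genome with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome = Genome()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace("U", "T")
        if not residues:
            raise ValueError(f"{path}: empty record '{rec.id}'")
        bad = set(residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{path}: record '{rec.id}' has illegal residues {sorted(bad)}"
            )
        if rec.id in genome:
            raise ValueError(f"{path}: duplicate sequence id '{rec.id}'")
        genome[rec.id] = GenomeSequence(rec.id, residues)
    if not genome:
        log.warning("FASTA file %s contains no records", path)
    return genome


def write_fasta(genome: Genome | dict, path: str | Path, width: int = 60) -> None:
    """Write a genome to FASTA (fixed line wrap, insertion order)."""
    records = []
    for seq_id, gs in genome.items():
        residues = gs.residues if isinstance(gs, GenomeSequence) else str(gs)
        records.append(SeqRecord(Seq(residues), id=seq_id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


_TE_WORDS = ("retrotransposon", "transposon")


def _te_class_from_attrs(*features) -> str:
    for feat in features:
        for key in ("Note", "Name", "note", "name", "product"):
            for val in feat.attributes.get(key, []):
                low = val.lower()
                if any(w in low for w in _TE_WORDS):
                    return "TE"
    return "non-TE"


def _transcript_key(db, mrna) -> tuple[int, int]:
    """Sort key: (total CDS length, total span) — larger wins."""
    cds_len = sum(c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS"))
    return cds_len, mrna.end - mrna.start + 1


def parse_gene_models(gff3_path: str | Path, genome: Genome) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon features into :class:`GeneModel` objects.

    One transcript is kept per gene: the mRNA with the longest summed CDS,
    falling back to the longest span. GFF3 1-based inclusive coordinates are
    converted to 0-based half-open. Genes on unknown chromosomes or with
    exons beyond chromosome bounds are skipped with a logged reason.
    """
    gff3_path = Path(gff3_path)
    if not gff3_path.exists():
        raise FileNotFoundError(gff3_path)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid not in genome:
            log.warning("gene %s on unknown sequence %s: skipped", gene.id, gene.seqid)
            continue
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            chosen = max(mrnas, key=lambda m: _transcript_key(db, m))
            exon_feats = list(db.children(chosen, featuretype="exon"))
            te = _te_class_from_attrs(gene, chosen)
        else:
            chosen = gene
            exon_feats = list(db.children(gene, featuretype="exon"))
            te = _te_class_from_attrs(gene)
        if not exon_feats:
            # Feature without exon children: treat the whole span as one exon.
            exon_feats = [chosen]
        exons = sorted((f.start - 1, f.end) for f in exon_feats)
        chrom_len = genome[gene.seqid].length
        if exons[0][0] < 0 or exons[-1][1] > chrom_len:
            log.warning("gene %s exceeds chromosome bounds: rejected", gene.id)
            continue
        note = ";".join(gene.attributes.get("Note", []))
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons,
                te_class=te,
                note=note,
            )
        )
    return models


def extract_introns(
    gene: GeneModel, genome: Genome, flank_window: int = 100
) -> list[Intron]:
    """Extract the introns of one gene with their exonic flank windows.

    Intron i occupies the genomic gap [exon_i.end, exon_{i+1}.start).
    Ordinals follow transcription order, so for minus-strand genes the
    genomically rightmost gap is ordinal 1 and all sequences are
    reverse-complemented onto the coding strand. Flank windows never extend
    past the adjacent exon: flank length = min(flank_window, exon length).
    Zero-length gaps (abutting exons) are skipped with a warning.
    """
    chrom = genome[gene.seq_id].residues
    gaps = []
    for k, ((a0, b0), (a1, b1)) in enumerate(zip(gene.exons, gene.exons[1:])):
        if b0 == a1:
            log.warning("gene %s: zero-length gap after exon %d skipped", gene.gene_id, k + 1)
            continue
        lf_start = max(a0, b0 - flank_window)
        rf_end = min(b1, a1 + flank_window)
        gaps.append((k, b0, a1, chrom[lf_start:b0], chrom[a1:rf_end]))
    n = len(gaps)
    introns: list[Intron] = []
    for idx, (k, g_start, g_end, left_genomic, right_genomic) in enumerate(gaps):
        seq = chrom[g_start:g_end]
        if gene.strand == "+":
            ordinal = idx + 1
            sequence, left, right = seq, left_genomic, right_genomic
        else:
            ordinal = n - idx
            sequence = revcomp(seq)
            left, right = revcomp(right_genomic), revcomp(left_genomic)
        introns.append(
            Intron(
                gene_id=gene.gene_id,
                ordinal=ordinal,
                seq_id=gene.seq_id,
                start=g_start,
                end=g_end,
                strand=gene.strand,
                sequence=sequence,
                left_flank=left,
                right_flank=right,
                has_n="N" in sequence or "N" in left or "N" in right,
            )
        )
    introns.sort(key=lambda i: i.ordinal)
    return introns


def extract_all_introns(
    genes: Iterable[GeneModel], genome: Genome, flank_window: int = 100
) -> list[Intron]:
    out: list[Intron] = []
    for gene in genes:
        out.extend(extract_introns(gene, genome, flank_window))
    return out


def introns_table(introns: Iterable[Intron]) -> pd.DataFrame:
    """Tabulate introns with 1-based inclusive coordinates."""
    rows = [
        {
            "gene_id": i.gene_id,
            "intron_ordinal": i.ordinal,
            "seq_id": i.seq_id,
            "start_1based": i.start + 1,
            "end_1based": i.end,
            "strand": i.strand,
            "intron_len": i.length,
            "left_flank_len": len(i.left_flank),
            "right_flank_len": len(i.right_flank),
        }
        for i in introns
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "intron_ordinal",
            "seq_id",
            "start_1based",
            "end_1based",
            "strand",
            "intron_len",
            "left_flank_len",
            "right_flank_len",
        ],
    )
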