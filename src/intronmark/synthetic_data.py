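"""Synthetic genome pairs with planted intronic variation, plus genotype panels.

The generator emulates the study design this package targets: a fully
annotated reference genome (the "Nipponbare-like" accession) and a diverged
query genome (the "Kasalath-like" accession) that differs from it only by
planted intronic SNPs and InDels, so exonic primer flanks stay conserved.
Every planted variant is recorded in machine-readable truth tables, making
the whole marker pipeline testable offline: recovery of the planted InDels
is the pipeline's ground-truth oracle.

Defaults mirror the regime the markers are designed for: exons 80-400 bp,
introns 60-2000 bp, 2-8 exons per gene, InDel lengths geometric with mean
~4.8 bp truncated to 1-101 bp, ~30% transposable-element-associated genes,
and random intergenic spacers (200-1000 bp) that keep primers single-copy
unless gene duplications are planted deliberately. All randomness flows
from one seeded generator; runs are byte-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_io import GeneModel, Genome, GenomeSequence, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated reference/query genome pair."""

    n_chromosomes: int = 2
    n_genes: int = 50
    exon_len: tuple[int, int] = (80, 400)
    intron_len: tuple[int, int] = (60, 2000)
    exons_per_gene: tuple[int, int] = (2, 8)
    intron_snp_rate: float = 0.01
    intron_indel_rate: float = 0.4  # expected InDels per intron (Poisson)
    indel_len_mean: float = 4.8  # geometric, truncated to [1, indel_len_max]
    indel_len_max: int = 101
    exon_mutation_rate: float = 0.0
    fraction_te_genes: float = 0.3
    duplication_rate: float = 0.0
    spacer_len: tuple[int, int] = (200, 1000)
    chrom_len_limit: int | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        for rate in (self.intron_snp_rate, self.intron_indel_rate / 100.0,
                     self.exon_mutation_rate, self.fraction_te_genes,
                     self.duplication_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        for lo, hi in (self.exon_len, self.intron_len, self.exons_per_gene,
                       self.spacer_len):
            if lo <= 0 or hi < lo:
                raise ValueError("length distributions must be positive ranges")


@dataclass
class SimulatedPair:
    """A reference genome + annotation, a derived query genome, and truth."""

    config: SimConfig
    ref_genome: Genome
    gene_models: list[GeneModel]
    query_genome: Genome
    truth_indels: pd.DataFrame
    truth_introns: pd.DataFrame
    truth_genes: pd.DataFrame


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _geometric_len(rng: np.random.Generator, mean: float, cap: int) -> int:
    return int(min(rng.geometric(1.0 / mean), cap))


def _mutate_intron(
    seq: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, list[dict]]:
    """Apply planted SNPs and InDels to one intron (plus-strand genomic).

    Returns the mutated sequence and truth records with 0-based offsets into
    the reference intron. Events keep a >= 3-base margin from the intron
    edges and never overlap each other.
    """
    L = len(seq)
    margin = 3
    events: list[dict] = []
    occupied: list[tuple[int, int]] = []
    n_indels = rng.poisson(cfg.intron_indel_rate)
    for _ in range(n_indels):
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        length = _geometric_len(rng, cfg.indel_len_mean, cfg.indel_len_max)
        if kind == "deletion":
            length = min(length, max(1, (L - 2 * margin) // 2))
        span = length if kind == "deletion" else 0
        placed = False
        for _try in range(25):
            if L - margin - span <= margin:
                break
            pos = int(rng.integers(margin, L - margin - span + 1))
            if all(pos + span <= a or pos >= b for a, b in occupied):
                placed = True
                break
        if not placed:
            continue
        occupied.append((pos, pos + max(span, 1)))
        if kind == "deletion":
            events.append(
                {"kind": kind, "ref_pos": pos, "length": length,
                 "allele_ref": seq[pos : pos + length], "allele_query": ""}
            )
        else:
            events.append(
                {"kind": kind, "ref_pos": pos, "length": length,
                 "allele_ref": "", "allele_query": _random_seq(rng, length)}
            )
    # SNPs outside indel footprints.
    deleted = np.zeros(L, dtype=bool)
    for e in events:
        if e["kind"] == "deletion":
            deleted[e["ref_pos"] : e["ref_pos"] + e["length"]] = True
    snp_mask = (rng.random(L) < cfg.intron_snp_rate) & ~deleted
    out = list(seq)
    for pos in np.flatnonzero(snp_mask):
        choices = [b for b in "ACGT" if b != seq[pos]]
        out[pos] = choices[int(rng.integers(0, 3))]
    for e in sorted(events, key=lambda x: -x["ref_pos"]):
        p, l = e["ref_pos"], e["length"]
        if e["kind"] == "deletion":
            del out[p : p + l]
        else:
            out[p:p] = list(e["allele_query"])
    return "".join(out), events


def simulate_genome_pair(cfg: SimConfig) -> SimulatedPair:
    """Generate a reference genome + GFF3-ready models and a mutated query.

    Deterministic given ``cfg.seed``. With all mutation rates at zero the
    query genome is byte-identical to the reference. Raises before building
    anything if the packed genes would exceed ``chrom_len_limit``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes_per_chrom = [
        cfg.n_genes // cfg.n_chromosomes + (1 if c < cfg.n_genes % cfg.n_chromosomes else 0)
        for c in range(cfg.n_chromosomes)
    ]
    # Draw all structures first so packing can be validated up front.
    structures = []
    for c, n_genes in enumerate(genes_per_chrom):
        chrom_structs = []
        for _ in range(n_genes):
            n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            exon_lens = [int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
                         for _ in range(n_ex)]
            intron_lens = [int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
                           for _ in range(n_ex - 1)]
            strand = "+" if rng.random() < 0.5 else "-"
            te = rng.random() < cfg.fraction_te_genes
            spacer = int(rng.integers(cfg.spacer_len[0], cfg.spacer_len[1] + 1))
            chrom_structs.append((spacer, exon_lens, intron_lens, strand, te))
        structures.append(chrom_structs)
        if cfg.chrom_len_limit is not None:
            need = sum(sp + sum(e) + sum(i) for sp, e, i, *_ in chrom_structs)
            if need > cfg.chrom_len_limit:
                raise ValueError(
                    f"chr{c + 1}: packed genes need {need} bases > limit "
                    f"{cfg.chrom_len_limit}"
                )
    ref_genome = Genome()
    query_genome = Genome()
    gene_models: list[GeneModel] = []
    indel_rows: list[dict] = []
    intron_rows: list[dict] = []
    gene_rows: list[dict] = []
    gene_no = 0
    for c, chrom_structs in enumerate(structures):
        seq_id = f"chr{c + 1}"
        ref_parts: list[str] = []
        query_parts: list[str] = []
        rpos = qpos = 0

        def emit(ref_seq: str, query_seq: str | None = None):
            nonlocal rpos, qpos
            query_seq = ref_seq if query_seq is None else query_seq
            ref_parts.append(ref_seq)
            query_parts.append(query_seq)
            rpos += len(ref_seq)
            qpos += len(query_seq)

        duplicated_spans: list[tuple[str, str]] = []
        for spacer, exon_lens, intron_lens, strand, te in chrom_structs:
            gene_no += 1
            gene_id = f"gene{gene_no:04d}"
            emit(_random_seq(rng, spacer))
            g_ref_start, g_q_start = rpos, qpos
            exons: list[tuple[int, int]] = []
            n_introns = len(intron_lens)
            ref_gene_parts: list[str] = []
            for i, elen in enumerate(exon_lens):
                eseq = _random_seq(rng, elen)
                exons.append((rpos, rpos + elen))
                emit(eseq)
                ref_gene_parts.append(eseq)
                if i < n_introns:
                    iseq = _random_seq(rng, intron_lens[i])
                    i_ref_start, i_q_start = rpos, qpos
                    mutated, events = _mutate_intron(iseq, cfg, rng)
                    emit(iseq, mutated)
                    ref_gene_parts.append(iseq)
                    genomic_gap = i + 1  # ascending-coordinate gap index
                    ordinal = genomic_gap if strand == "+" else n_introns - i
                    for e in events:
                        indel_rows.append(
                            {"gene_id": gene_id, "intron_ordinal": ordinal,
                             "seq_id": seq_id, "kind": e["kind"],
                             "length": e["length"], "ref_pos": e["ref_pos"],
                             "allele_ref": e["allele_ref"],
                             "allele_query": e["allele_query"]}
                        )
                    net = sum(
                        e["length"] if e["kind"] == "insertion" else -e["length"]
                        for e in events
                    )
                    intron_rows.append(
                        {"gene_id": gene_id, "intron_ordinal": ordinal,
                         "seq_id": seq_id,
                         "ref_start": i_ref_start, "ref_end": i_ref_start + len(iseq),
                         "query_start": i_q_start, "query_end": i_q_start + len(mutated),
                         "ref_len": len(iseq), "query_len": len(mutated),
                         "n_indels": len(events), "net": net,
                         "gross": sum(e["length"] for e in events),
                         "strand": strand}
                    )
            note = ("retrotransposon protein, putative" if te
                    else "expressed protein")
            model = GeneModel(gene_id=gene_id, seq_id=seq_id, strand=strand,
                              exons=exons, te_class="TE" if te else "non-TE",
                              note=note)
            gene_models.append(model)
            gene_rows.append(
                {"gene_id": gene_id, "seq_id": seq_id, "strand": strand,
                 "te_class": model.te_class,
                 "ref_start": g_ref_start, "ref_end": rpos,
                 "query_start": g_q_start, "query_end": qpos,
                 "duplicated": False}
            )
            if rng.random() < cfg.duplication_rate:
                duplicated_spans.append((gene_id, "".join(ref_gene_parts)))
                gene_rows[-1]["duplicated"] = True
        emit(_random_seq(rng, int(rng.integers(*cfg.spacer_len))))
        for _gene_id, span_seq in duplicated_spans:
            emit(_random_seq(rng, int(rng.integers(*cfg.spacer_len))))
            emit(span_seq)  # verbatim copy in both genomes
        ref_genome[seq_id] = GenomeSequence(seq_id, "".join(ref_parts))
        query_genome[seq_id] = GenomeSequence(seq_id, "".join(query_parts))
    return SimulatedPair(
        config=cfg,
        ref_genome=ref_genome,
        gene_models=gene_models,
        query_genome=query_genome,
        truth_indels=pd.DataFrame(
            indel_rows,
            columns=["gene_id", "intron_ordinal", "seq_id", "kind", "length",
                     "ref_pos", "allele_ref", "allele_query"],
        ),
        truth_introns=pd.DataFrame(
            intron_rows,
            columns=["gene_id", "intron_ordinal", "seq_id", "ref_start",
                     "ref_end", "query_start", "query_end", "ref_len",
                     "query_len", "n_indels", "net", "gross", "strand"],
        ),
        truth_genes=pd.DataFrame(
            gene_rows,
            columns=["gene_id", "seq_id", "strand", "te_class", "ref_start",
                     "ref_end", "query_start", "query_end", "duplicated"],
        ),
    )


def write_gff3(gene_models, path: str | Path) -> None:
    """Write gene/mRNA/exon features (1-based inclusive, GFF3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            start, end = g.span
            attrs = f"ID={g.gene_id}"
            if g.note:
                attrs += f";Note={g.note}"
            fh.write(
                f"{g.seq_id}\tsim\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.seq_id}\tsim\tmRNA\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.seq_id}\tsim\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
                fh.write(
                    f"{g.seq_id}\tsim\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def write_simulated_pair(sim: SimulatedPair, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a simulated pair: ref.fa, ref.gff3, query.fa, truth TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ref_fasta": out_dir / "ref.fa",
        "ref_gff3": out_dir / "ref.gff3",
        "query_fasta": out_dir / "query.fa",
        "truth_indels": out_dir / "truth_indels.tsv",
        "truth_introns": out_dir / "truth_introns.tsv",
        "truth_genes": out_dir / "truth_genes.tsv",
    }
    write_fasta(sim.ref_genome, paths["ref_fasta"])
    write_fasta(sim.query_genome, paths["query_fasta"])
    write_gff3(sim.gene_models, paths["ref_gff3"])
    sim.truth_indels.to_csv(paths["truth_indels"], sep="\t", index=False)
    sim.truth_introns.to_csv(paths["truth_introns"], sep="\t", index=False)
    sim.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    return paths


def simulate_genotypes(
    n_markers: int,
    groups: Mapping[str, int],
    divergence: float = 0.3,
    within_divergence: float = 0.0,
    missing_rate: float = 0.0,
    allele_range: tuple[int, int] = (2, 4),
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Group-structured genotype panel with known truth labels.

    Each marker gets a base allele-frequency vector; every group perturbs it
    by a Balding-Nichols-style Dirichlet draw with concentration
    (1 - divergence)/divergence, so divergence 0 means identical group
    frequencies and divergence near 1 means nearly fixed group-private
    alleles. Accessions are diploid draws from their group's frequencies;
    cells go missing independently at ``missing_rate``. Deterministic given
    ``seed``. Returns (genotype matrix, accession -> group labels).
    """
    rng = np.random.default_rng(seed)
    acc_ids: list[str] = []
    labels: dict[str, str] = {}
    for group, count in groups.items():
        for i in range(count):
            acc = f"{group}_{i + 1}"
            acc_ids.append(acc)
            labels[acc] = group
    data: dict[str, list[str]] = {acc: [] for acc in acc_ids}
    marker_ids = [f"M{i + 1:04d}" for i in range(n_markers)]
    for _ in range(n_markers):
        n_alleles = int(rng.integers(allele_range[0], allele_range[1] + 1))
        base = rng.dirichlet(np.ones(n_alleles))
        group_freqs: dict[str, np.ndarray] = {}
        for group in groups:
            if divergence <= 0:
                gf = base
            else:
                conc = base * (1.0 - divergence) / divergence
                gf = rng.dirichlet(np.maximum(conc, 1e-6))
            if within_divergence > 0:
                conc = gf * (1.0 - within_divergence) / within_divergence
                gf = rng.dirichlet(np.maximum(conc, 1e-6))
            group_freqs[group] = gf
        for acc in acc_ids:
            gf = group_freqs[labels[acc]]
            if missing_rate > 0 and rng.random() < missing_rate:
                data[acc].append("-")
                continue
            a, b = sorted(rng.choice(len(gf), size=2, p=gf) + 1)
            data[acc].append(str(a) if a == b else f"{a}/{b}")
    gm = pd.DataFrame(data, index=marker_ids)
    return gm, labels
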