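"""End-to-end marker pipeline: introns -> ISM design -> homology -> ILP.

Chains the per-module operations the way the marker-design workflow runs in
practice: extract introns with exonic flanks, design and rank intron-spanning
primer pairs, enforce genome-wide primer uniqueness by in-silico PCR, locate
each marker's intron in the query genome, call intronic InDels, and convert
markers with InDels into ILP markers with predicted fragment-length
polymorphism. Everything is deterministic: no RNG is used anywhere in the
design path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .genome_io import (
    GeneModel,
    Genome,
    Intron,
    extract_introns,
    introns_table,
    parse_gene_models,
    read_fasta,
    revcomp,
)
from .homology_indel import (
    HomologyConfig,
    HomologyMatch,
    IlpMarker,
    IndelCall,
    KmerIndex,
    call_intron_indels,
    convert_to_ilp,
    ilp_table,
    indels_table,
    map_intron_to_query,
)
from .ispcr import primer_uniqueness
from .primer_design import (
    DesignConstraints,
    IsmMarker,
    design_ism_primers,
    markers_table,
    select_markers_per_gene,
)

log = logging.getLogger(__name__)


@dataclass
class DesignResult:
    markers: list[IsmMarker]
    introns_by_key: dict[tuple[str, int], Intron]
    dropped_nonunique: list[str]  # marker ids removed by the uniqueness screen


@dataclass
class ConversionResult:
    ilp_markers: list[IlpMarker]
    balanced: list[IlpMarker]  # net-0 markers, kept in a side table only
    refusals: list[tuple[str, str]]  # (ism marker_id, reason)
    matches: dict[str, HomologyMatch]
    indel_calls: dict[str, list[IndelCall]]


def design_ism(
    ref_genome: Genome,
    gene_models: Sequence[GeneModel],
    constraints: DesignConstraints = DesignConstraints(),
    per_gene: int = 4,
    expression_mode: bool = False,
    check_uniqueness: bool = True,
    max_product: int = 3000,
) -> DesignResult:
    """Design up to ``per_gene`` intron-spanning markers per gene.

    Selected markers whose primer pair is not single-copy on the reference
    genome (in-silico PCR finds != 1 product) are dropped, and marker ids
    are reassigned so numbering stays dense in chromosome-position order.
    """
    candidates: dict[str, list[tuple[Intron, object]]] = {}
    introns_by_key: dict[tuple[str, int], Intron] = {}
    for gene in gene_models:
        introns = extract_introns(gene, ref_genome, constraints.flank_window)
        for intron in introns:
            introns_by_key[(gene.gene_id, intron.ordinal)] = intron
            pairs = design_ism_primers(intron, constraints, expression_mode)
            if pairs:
                candidates.setdefault(gene.gene_id, []).append((intron, pairs[0]))
    markers = select_markers_per_gene(candidates, k=per_gene)
    dropped: list[str] = []
    if check_uniqueness:
        kept = []
        for m in markers:
            status = primer_uniqueness(
                m.primer_pair.fwd_seq, m.primer_pair.rev_seq, ref_genome, max_product
            )
            if status == "unique":
                kept.append(m)
            else:
                dropped.append(m.marker_id)
                log.info("marker %s dropped: %s binding on reference", m.marker_id, status)
        markers = [replace(m, marker_id=f"OsISM{n:05d}")
                   for n, m in enumerate(kept, start=1)]
    return DesignResult(markers, introns_by_key, dropped)


def convert_markers(
    design: DesignResult,
    ref_genome: Genome,
    query_genome: Genome,
    homology: HomologyConfig = HomologyConfig(),
    max_product: int = 3000,
) -> ConversionResult:
    """Map each marker's intron to the query genome and convert to ILP.

    For opposite-strand homologs the query slice is reverse-complemented
    before indel calling, so InDel offsets always refer to the gene-strand
    intron sequence. Conversion refusals (no homolog, ambiguity, balanced
    indels, non-unique binding) are recorded per marker.
    """
    index = KmerIndex(query_genome, homology.k)
    ilp: list[IlpMarker] = []
    balanced: list[IlpMarker] = []
    refusals: list[tuple[str, str]] = []
    matches: dict[str, HomologyMatch] = {}
    indel_calls: dict[str, list[IndelCall]] = {}
    for ism in design.markers:
        intron = design.introns_by_key[(ism.gene_id, ism.intron_ordinal)]
        match = map_intron_to_query(
            intron.sequence, index, homology, intron_ref=(ism.gene_id, ism.intron_ordinal)
        )
        if match is None:
            refusals.append((ism.marker_id, "no_homolog"))
            continue
        matches[ism.marker_id] = match
        if match.ambiguous:
            refusals.append((ism.marker_id, "ambiguous_homology"))
            continue
        # Re-anchor the full intron in a padded window: the local-alignment
        # interval can over/undershoot when an indel sits near an intron end.
        pad = 100 + abs((match.query_end - match.query_start) - intron.length)
        chrom_len = query_genome[match.query_seq_id].length
        wstart = max(0, match.query_start - pad)
        wend = min(chrom_len, match.query_end + pad)
        window = query_genome.fetch(match.query_seq_id, wstart, wend)
        if not window:
            refusals.append((ism.marker_id, "empty_query_interval"))
            continue
        if match.strand_rel == "opposite":
            window = revcomp(window)
        # Conserved exon flanks anchor the intron boundaries during indel
        # calling, so indels near an intron end cannot be traded away for
        # spurious matches in flanking sequence.
        anchor = 40
        q0, q1, indels = call_intron_indels(
            intron.sequence,
            intron.left_flank[-anchor:],
            intron.right_flank[:anchor],
            window,
            homology.scoring,
        )
        if match.strand_rel == "same":
            refined_start, refined_end = wstart + q0, wstart + q1
        else:
            refined_start = wstart + len(window) - q1
            refined_end = wstart + len(window) - q0
        match = replace(match, query_start=refined_start, query_end=refined_end)
        matches[ism.marker_id] = match
        indel_calls[ism.marker_id] = indels
        marker, reason = convert_to_ilp(
            ism, match, indels, ref_genome, query_genome, max_product
        )
        if marker is not None:
            ilp.append(marker)
        elif reason == "balanced_indels":
            balanced.append(
                IlpMarker(
                    marker_id="",
                    parent_ism_id=ism.marker_id,
                    gene_id=ism.gene_id,
                    seq_id=ism.seq_id,
                    indels=indels,
                    ref_amplicon_len=ism.primer_pair.genomic_amplicon_len,
                    query_amplicon_len=ism.primer_pair.genomic_amplicon_len,
                    flp_net=0,
                    flp_gross=sum(c.length for c in indels),
                    assay_tier="sequencing",
                    match=match,
                )
            )
        else:
            refusals.append((ism.marker_id, reason))
    # Assign ILP ids in chromosome-then-position order of the parent marker.
    pos_of = {
        m.marker_id: (m.seq_id, min(m.primer_pair.fwd_pos, m.primer_pair.rev_pos))
        for m in design.markers
    }
    ilp.sort(key=lambda m: pos_of[m.parent_ism_id])
    for n, marker in enumerate(ilp, start=1):
        marker.marker_id = f"OsILP{n:05d}"
    for n, marker in enumerate(balanced, start=1):
        marker.marker_id = f"OsBAL{n:05d}"
    return ConversionResult(ilp, balanced, refusals, matches, indel_calls)


@dataclass
class PipelineResult:
    design: DesignResult
    conversion: ConversionResult


def run_pipeline(
    ref_genome: Genome,
    gene_models: Sequence[GeneModel],
    query_genome: Genome,
    constraints: DesignConstraints = DesignConstraints(),
    homology: HomologyConfig = HomologyConfig(),
    per_gene: int = 4,
    max_product: int = 3000,
) -> PipelineResult:
    """Full in-memory pipeline on already-loaded genomes and models."""
    design = design_ism(
        ref_genome, gene_models, constraints, per_gene, max_product=max_product
    )
    conversion = convert_markers(design, ref_genome, query_genome, homology, max_product)
    return PipelineResult(design, conversion)


def run_pipeline_files(
    ref_fasta: str | Path,
    ref_gff3: str | Path,
    query_fasta: str | Path,
    out_dir: str | Path,
    constraints: DesignConstraints = DesignConstraints(),
    homology: HomologyConfig = HomologyConfig(),
    per_gene: int = 4,
    max_product: int = 3000,
) -> PipelineResult:
    """File-based pipeline; writes introns/markers/ILP/indel TSVs to out_dir."""
    ref_genome = read_fasta(ref_fasta)
    query_genome = read_fasta(query_fasta)
    gene_models = parse_gene_models(ref_gff3, ref_genome)
    result = run_pipeline(
        ref_genome, gene_models, query_genome, constraints, homology,
        per_gene, max_product,
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_result_tables(result, out_dir)
    return result


def write_result_tables(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "introns": out_dir / "introns.tsv",
        "ism_markers": out_dir / "ism_markers.tsv",
        "ilp_markers": out_dir / "ilp_markers.tsv",
        "balanced_markers": out_dir / "balanced_markers.tsv",
        "indels": out_dir / "indels.tsv",
    }
    introns = sorted(
        result.design.introns_by_key.values(), key=lambda i: (i.seq_id, i.start)
    )
    introns_table(introns).to_csv(paths["introns"], sep="\t", index=False)
    markers_table(result.design.markers).to_csv(paths["ism_markers"], sep="\t", index=False)
    ilp_table(result.conversion.ilp_markers).to_csv(paths["ilp_markers"], sep="\t", index=False)
    ilp_table(result.conversion.balanced).to_csv(
        paths["balanced_markers"], sep="\t", index=False
    )
    ordinal_introns = {
        (m.gene_id, m.match.intron_ref[1]): result.design.introns_by_key.get(
            (m.gene_id, m.match.intron_ref[1])
        )
        for m in result.conversion.ilp_markers
        if m.match is not None
    }
    indels_table(result.conversion.ilp_markers, ordinal_introns).to_csv(
        paths["indels"], sep="\t", index=False
    )
    return paths
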