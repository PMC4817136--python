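"""Planted-variant recovery benchmark: the pipeline's ground-truth validation.

Runs the full design -> homology -> ILP pipeline on a simulated genome pair
and scores it against the simulator's truth tables. The benchmark conditions
are fixed study conditions, not tunables: 50 genes on 2 chromosomes
(~200 introns), 0.4 planted InDels per intron, 1% intronic SNPs, conserved
exon flanks. Primer product bounds (100-2500 bp) and in-silico PCR cap
(3000 bp) bracket the simulated 60-2000 bp intron range, and the homology
gates (bit >= 50, E <= 1e-6) are scaled to the ~10^5-base search space; see
docs/methods.md for the scaling argument.

Scored quantities: recall of planted InDel-bearing introns as ILP markers,
exactness of the predicted fragment-length polymorphism against the planted
net size, false ILP calls on variant-free introns, and the internal
consistency of the two FLP routes (indel-call arithmetic vs in-silico PCR).
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology_indel import HomologyConfig
from .pipeline import PipelineResult, run_pipeline
from .primer_design import DesignConstraints
from .synthetic_data import SimConfig, SimulatedPair, simulate_genome_pair

#: product-size window matching the simulated intron length range
BENCH_CONSTRAINTS = DesignConstraints(genomic_product=(100, 2500))
#: homology gates scaled to the simulated search space
BENCH_HOMOLOGY = HomologyConfig(min_bit_score=50.0, max_evalue=1e-6)
BENCH_MAX_PRODUCT = 3000
BENCH_PER_GENE = 8  # >= max introns/gene, so every designable intron competes


@dataclass
class RecoveryReport:
    """Truth-scored outcome of one benchmark run."""

    sim: SimulatedPair
    result: PipelineResult
    n_introns: int = 0
    n_ism: int = 0
    n_ilp: int = 0
    n_target_introns: int = 0  # planted net != 0, ISM designed
    n_recovered: int = 0  # ILP present with flp_net == |planted net|
    n_flp_exact: int = 0
    n_false_ilp: int = 0  # ILP on introns without planted indels
    n_balanced_truth: int = 0  # planted net == 0 with >= 1 indel, ISM designed
    n_balanced_called: int = 0
    n_flp_consistent: int = 0  # |sum signed indel calls| == flp_net
    mean_flp: float = float("nan")

    @property
    def recall_pct(self) -> float:
        if self.n_target_introns == 0:
            return float("nan")
        return 100.0 * self.n_recovered / self.n_target_introns

    @property
    def flp_exact_pct(self) -> float:
        if self.n_ilp == 0:
            return float("nan")
        return 100.0 * self.n_flp_exact / self.n_ilp

    @property
    def flp_consistent_pct(self) -> float:
        if self.n_ilp == 0:
            return float("nan")
        return 100.0 * self.n_flp_consistent / self.n_ilp


def score_against_truth(sim: SimulatedPair, result: PipelineResult) -> RecoveryReport:
    """Compare pipeline output with the simulator's planted-variant truth."""
    report = RecoveryReport(sim=sim, result=result)
    truth = sim.truth_introns.set_index(["gene_id", "intron_ordinal"])
    designed = {(m.gene_id, m.intron_ordinal) for m in result.design.markers}
    ilp_by_key = {
        (m.gene_id, m.match.intron_ref[1]): m
        for m in result.conversion.ilp_markers
        if m.match is not None
    }
    report.n_introns = len(truth)
    report.n_ism = len(result.design.markers)
    report.n_ilp = len(result.conversion.ilp_markers)
    for key, row in truth.iterrows():
        if key not in designed:
            continue
        planted_net = int(row["net"])
        has_indels = int(row["n_indels"]) > 0
        marker = ilp_by_key.get(key)
        if has_indels and planted_net != 0:
            report.n_target_introns += 1
            if marker is not None and marker.flp_net == abs(planted_net):
                report.n_recovered += 1
        elif has_indels and planted_net == 0:
            report.n_balanced_truth += 1
        elif not has_indels and marker is not None:
            report.n_false_ilp += 1
    report.n_balanced_called = len(result.conversion.balanced)
    flps = []
    for m in result.conversion.ilp_markers:
        key = (m.gene_id, m.match.intron_ref[1])
        if key in truth.index and m.flp_net == abs(int(truth.loc[key, "net"])):
            report.n_flp_exact += 1
        indel_net = sum(c.signed_length for c in m.indels)
        if abs(indel_net) == m.flp_net:
            report.n_flp_consistent += 1
        flps.append(m.flp_net)
    if flps:
        report.mean_flp = sum(flps) / len(flps)
    return report


def run_recovery_benchmark(
    seed: int = 42,
    n_genes: int = 50,
    n_chromosomes: int = 2,
    intron_indel_rate: float = 0.4,
    intron_snp_rate: float = 0.01,
    per_gene: int = BENCH_PER_GENE,
) -> RecoveryReport:
    """Simulate a genome pair, run the full pipeline, score against truth."""
    cfg = SimConfig(
        n_genes=n_genes,
        n_chromosomes=n_chromosomes,
        intron_indel_rate=intron_indel_rate,
        intron_snp_rate=intron_snp_rate,
        seed=seed,
    )
    sim = simulate_genome_pair(cfg)
    result = run_pipeline(
        sim.ref_genome,
        sim.gene_models,
        sim.query_genome,
        BENCH_CONSTRAINTS,
        BENCH_HOMOLOGY,
        per_gene=per_gene,
        max_product=BENCH_MAX_PRODUCT,
    )
    return score_against_truth(sim, result)


def run_null_benchmark(seed: int = 42, n_genes: int = 20) -> RecoveryReport:
    """Indel-free pair (SNPs only): any ILP marker is a false positive."""
    return run_recovery_benchmark(
        seed=seed, n_genes=n_genes, n_chromosomes=1, intron_indel_rate=0.0
    )
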