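import pytest
from hypothesis import HealthCheck, settings

from intronmark.benchmark import (
    BENCH_CONSTRAINTS,
    run_null_benchmark,
    run_recovery_benchmark,
)
from intronmark.pipeline import design_ism
from intronmark.synthetic_data import SimConfig, simulate_genome_pair

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bench():
    """Full pipeline run at the study conditions (50 genes, seed 42)."""
    return run_recovery_benchmark(seed=42)


@pytest.fixture(scope="session")
def null_bench():
    """Pipeline run on an InDel-free pair (SNPs only)."""
    return run_null_benchmark(seed=42, n_genes=10)


@pytest.fixture(scope="session")
def small_sim():
    """Small mixed-strand simulated pair for module-level tests."""
    return simulate_genome_pair(SimConfig(n_genes=8, n_chromosomes=2, seed=3))


@pytest.fixture(scope="session")
def small_design(small_sim):
    """ISM design over the small pair (uniqueness screen on)."""
    return design_ism(
        small_sim.ref_genome, small_sim.gene_models, BENCH_CONSTRAINTS, per_gene=8
    )
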