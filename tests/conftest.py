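import numpy as np
import pytest

from haplodnm.simulate import SimConfig, run_benchmarks, run_pipeline, simulate_pedigree

# a 1-Mb pedigree with the default-equivalent geometry, for fast unit tests
SMALL_KWARGS = dict(
    genome_length_bp=1_000_000,
    n_no_variant_intervals=6,
    no_variant_interval_length_bp=75_000,
    n_offspring=2,
    dnm_spike_per_offspring=30,
    pzm_spike_per_offspring=15,
    seed=11,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_pedigree(SimConfig(**SMALL_KWARGS))


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """(zygosity, thresholds, scores, similar_pairs, inheritance, mean_depths, callables)."""
    return run_pipeline(small_sim)


@pytest.fixture(scope="session")
def default_benchmark():
    """Full 5-Mb default-condition benchmark with retained artifacts."""
    artifacts: dict = {}
    report = run_benchmarks(SimConfig(seed=0), artifacts=artifacts)
    return report, artifacts


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
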