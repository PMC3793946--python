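import numpy as np
import pytest

from epimut.amplicon import run_pipeline
from epimut.array_screen import ScreenConfig
from epimut.simulate import (
    ArraySimConfig,
    ReadSimConfig,
    plant_epimutations,
    random_amplicon_spec,
    simulate_amplicon_reads,
    simulate_beta_matrix,
)


@pytest.fixture(scope="session")
def small_array_sim():
    """200-probe, 10-control matrix with 12 planted |delta beta| = 0.35 hits."""
    rng = np.random.default_rng(101)
    baselines = rng.uniform(0.1, 0.9, 200)
    planted = plant_epimutations(200, 12, 0.35, baselines, rng)
    cfg = ArraySimConfig(
        n_controls=10,
        n_probes=200,
        baselines=tuple(baselines),
        noise_sd=0.01,
        planted=planted,
        seed=102,
    )
    return simulate_beta_matrix(cfg)


@pytest.fixture(scope="session")
def small_screen_cfg(small_array_sim):
    return ScreenConfig(control_ids=small_array_sim.control_ids)


@pytest.fixture(scope="session")
def small_spec():
    """Short synthetic amplicon (5 CpGs, G/A SNP) for alignment-heavy tests."""
    return random_amplicon_spec(n_cpgs=5, n_spacer_tokens=70, seed=11)


@pytest.fixture(scope="session")
def small_read_sim(small_spec):
    """Imprinted-locus-like mixture: 40 high-meth G reads, 40 low-meth A reads."""
    cfg = ReadSimConfig(
        spec=small_spec,
        per_allele_meth={"G": [0.9] * 5, "A": [0.1] * 5},
        allele_read_counts={"G": 40, "A": 40},
        seed=12,
    )
    return cfg, simulate_amplicon_reads(cfg)


@pytest.fixture(scope="session")
def small_results(small_spec, small_read_sim):
    _, sim = small_read_sim
    return run_pipeline(sim.reads, small_spec, by_allele=True, min_reads=10)
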