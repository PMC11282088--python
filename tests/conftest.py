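import numpy as np
import pytest

from ctrich import simulate as sim


@pytest.fixture(scope="session")
def refs():
    return sim.make_reference_haplotypes()


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(n_samples=30, read_depth=30, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sim.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def clean_reads(small_cohort, refs, small_config):
    """Error-free, forward-only, chimera-free reads for 30 samples."""
    import dataclasses

    cfg = dataclasses.replace(
        small_config, error_rates=(0.0, 0.0, 0.0), reverse_fraction=0.0, chimera_fraction=0.0
    )
    return sim.simulate_reads(small_cohort, refs, cfg, np.random.default_rng(5))
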