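import math

import pytest
from hypothesis import settings

from circatime import SimulationConfig, generate_reference_timecourse

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_config():
    """One noiseless day, 12 genes all cycling with phases tiling the day."""
    return SimulationConfig(
        n_genes=12,
        cycler_fraction=1.0,
        amplitude_to_noise=math.inf,
        duration_hours=24.0,
        replicates=1,
    )


@pytest.fixture(scope="session")
def noiseless_reference(noiseless_config):
    return generate_reference_timecourse(noiseless_config)


@pytest.fixture(scope="session")
def noisy_reference():
    """Standard two-day triplicate design: 20 cyclers + 80 flat genes, ANR 4."""
    cfg = SimulationConfig(seed=11)
    return generate_reference_timecourse(cfg)
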