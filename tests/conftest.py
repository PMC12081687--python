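import numpy as np
import pytest

from bmrisk.grid import Grid
from bmrisk.phantom import SimulationConfig, build_phantom, simulate_cohort


@pytest.fixture(scope="session")
def phantom():
    return build_phantom(spacing_mm=2.0, shape=(96, 96, 96), seed=7)


@pytest.fixture(scope="session")
def dmap(phantom):
    return phantom.interface_dmap()


@pytest.fixture(scope="session")
def small_cohort(phantom):
    """50 patients under the interface/perfusion-biased defaults."""
    return simulate_cohort(phantom, SimulationConfig(seed=11, n_patients=50))


@pytest.fixture(scope="session")
def uniform_cohort_500(phantom):
    """500 patients seeded uniformly over parenchyma (tau -> inf, gamma = 0)."""
    cfg = SimulationConfig(
        seed=5, n_patients=500, interface_decay_tau_mm=None, perfusion_exponent_gamma=0.0
    )
    return simulate_cohort(phantom, cfg)


@pytest.fixture
def unit_grid():
    def make(shape, spacing=1.0):
        return Grid(shape=tuple(shape), spacing_mm=spacing)

    return make
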