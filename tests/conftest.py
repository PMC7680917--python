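import numpy as np
import pytest

from oscnet import (IntegratorConfig, NetworkSpec, OregonatorParams,
                    PeakConfig, load_preset, sample_flag)


@pytest.fixture(scope="session")
def params():
    return OregonatorParams()


@pytest.fixture(scope="session")
def optimized_genome():
    """The published optimum of the Japanese-flag network."""
    return load_preset("japan_optimized")


@pytest.fixture(scope="session")
def single_osc():
    """Uncoupled oscillator with the optimized decay rate."""
    return NetworkSpec(n_osc=1, alpha=0.849, beta=0.0)


@pytest.fixture(scope="session")
def peaks():
    return PeakConfig()


def fast_cfg(t_max: float, h: float = 1e-3) -> IntegratorConfig:
    """Coarse-step integrator for tests; maxima counts are step-invariant
    between 1e-4 and 1e-3 (verified by the refinement test)."""
    return IntegratorConfig(t_max=t_max, h=h, store_stride=round(0.01 / h))


@pytest.fixture(scope="session")
def flag_200():
    return sample_flag(200, seed=20200)
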