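import numpy as np
import pytest

from turingtherm.model import DiffusionConstants, Geometry, RateConstants
from turingtherm.presets import get_preset


@pytest.fixture(scope="session")
def accuracy():
    return get_preset("accuracy")


@pytest.fixture(scope="session")
def robustness():
    return get_preset("robustness")


@pytest.fixture(scope="session")
def equilibrium_rates():
    """Symmetric rate set with Gamma = Gamma' = 1 (detailed balance)."""
    return RateConstants(
        k12=0.5, k21=0.5, k23=0.0139, k32=0.0139, k31=0.0416, k13=0.0416,
        kt12=1.67e-5, kt21=1.67e-5,
    )


@pytest.fixture(scope="session")
def small_geometry():
    return Geometry(L=6.0, n_box=15)
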