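import numpy as np
import pytest

from forcespec import BondTruth, LoadingProtocol, ThermoConstants


@pytest.fixture(scope="session")
def tc():
    return ThermoConstants()


@pytest.fixture(scope="session")
def truth():
    """Default bond ground truth: F_eq=50 pN, f_beta=10 pN, k_off=1e3/s,
    k_eff=13.1 pN/nm, PEG-like 10 nm tether."""
    return BondTruth()


@pytest.fixture(scope="session")
def ramp_protocol():
    return LoadingProtocol(kind="linear_ramp", retract_velocity=1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
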