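import numpy as np
import pytest

from luxfer.equilibrium_model import DeviceParams, EquilibriumConstants, HyperbolicParams

# fitted transfer-curve parameters of the three characterized constructs
CHARACTERIZED = {
    "strong": HyperbolicParams(a1=3.6e4, a2=3.2e-10, a3=1.5e-8),
    "medium": HyperbolicParams(a1=4.0e4, a2=4.0e-10, a3=2.6e-8),
    "weak": HyperbolicParams(a1=4.1e4, a2=12.7e-10, a3=22.0e-8),
}

# simple-model simulation parameters (concentrations in uM for readability)
SIMPLE_SIM = dict(K1=0.2, K3=1.0, r_prime=100.0, V=100.0)

# manually fitted shared mechanistic parameters of the leaky model
SHARED_FIT = dict(V0=85.0, K2r=5.0, K3r=500.0, eps_R=10.0, eps_L=10.0, K1_inv=3e-6)


@pytest.fixture(scope="session")
def characterized():
    return CHARACTERIZED


@pytest.fixture(scope="session")
def simple_sim_device():
    return DeviceParams(phi=1.0, r_prime=SIMPLE_SIM["r_prime"], V=SIMPLE_SIM["V"])


@pytest.fixture(scope="session")
def shared_fit_constants():
    return EquilibriumConstants(K1=1.0 / SHARED_FIT["K1_inv"], K2=SHARED_FIT["K2r"], K3=SHARED_FIT["K3r"])


def shared_fit_device(phi: float) -> DeviceParams:
    return DeviceParams(phi=phi, r_prime=1.0, V0=SHARED_FIT["V0"], eps_R=SHARED_FIT["eps_R"], eps_L=SHARED_FIT["eps_L"])


@pytest.fixture(scope="session")
def dense_ligand_grid():
    """Zero plus 59 log-spaced inducer levels spanning 1e-11..1e-5 M."""
    return np.concatenate([[0.0], np.logspace(-11, -5, 59)])
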