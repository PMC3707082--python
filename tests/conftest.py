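import numpy as np
import pytest

import ptenkin as pk

SPHERE_R = 30.0
SPHERE_RG = np.sqrt(3.0 / 5.0) * SPHERE_R  # 23.2379 A


@pytest.fixture(scope="session")
def truth_params():
    """Reference interfacial truth used across round-trip tests."""
    return pk.InterfacialParams(kcat=3.0, iKm=2.0, Ks=40.0, ET=0.01)


@pytest.fixture(scope="session")
def q_grid():
    return np.linspace(0.006, 0.35, 240)


@pytest.fixture(scope="session")
def sphere_curve(q_grid):
    """Noise-free analytic sphere scattering curve, R = 30 A."""
    return pk.gen_scattering("sphere", q_grid, pk.quiet(1), R=SPHERE_R)
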