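import numpy as np
import pytest

from hydrotraits import CultivarPreset


def make_piecewise(x, theta1, theta2, b1, b2, b3, c1):
    """Evaluate a continuous 3-segment piecewise line (phase-I intercept c1)."""
    x = np.asarray(x, dtype=float)
    c2 = c1 + (b1 - b2) * theta1
    c3 = c2 + (b2 - b3) * theta2
    return np.where(x >= theta1, c1 + b1 * x,
                    np.where(x >= theta2, c2 + b2 * x, c3 + b3 * x))


@pytest.fixture
def ideal_preset():
    """Preset with analytically convenient PV and vulnerability parameters
    (pi_o=2, eps=10 => TLP at -2.5 MPa / 80% RWC; b=4, c=3 => |P50|=3.54)."""
    return CultivarPreset(
        label="ideal", gs_max=500.0, k_stomatal=1.0, a_max=12.0,
        e_per_gs=0.012, pi_o=2.0, epsilon=10.0,
        weibull_b=4.0, weibull_c=3.0,
        retention_a=1.0, retention_n=1.5, plant_conductance=4.0)
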