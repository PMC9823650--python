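import numpy as np
import pytest

import coflowmetry as cf


@pytest.fixture(scope="session")
def alpha():
    """Correction line calibrated on the reference device."""
    return cf.DEFAULT_ALPHA


@pytest.fixture(scope="session")
def geometry():
    return cf.DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def glycerin_run(alpha):
    """Noise-free 4-period glycerin simulation (trace + intensity)."""
    return cf.make_trace(cf.preset("glycerin30"), alpha=alpha)


@pytest.fixture(scope="session")
def glycerin_offphase(alpha):
    """One noise-free off-phase decay with the glycerin lambda(beta) line."""
    lam = cf.TimeConstantProfile(lam0=8.8902, slope_beta=-7.6899)
    t, b = cf.integrate_interface(
        0.7, 0.0, lam, alpha, duration=120.0, sampling_dt=0.5, internal_dt=0.01
    )
    return cf.InterfaceTrace(t, b, np.array(["off"] * len(t)))


@pytest.fixture(scope="session")
def logistic_trace():
    """Off-phase decay with unit correction and constant lambda = 5 s.

    Has the logistic closed form beta(t) = 1/(1 + ((1-b0)/b0) e^{t/lam}).
    """
    lam = cf.TimeConstantProfile(5.0)
    t, b = cf.integrate_interface(
        0.7, 0.0, lam, cf.UNIT_ALPHA, duration=60.0, sampling_dt=0.5
    )
    return cf.InterfaceTrace(t, b, np.array(["off"] * len(t)))
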