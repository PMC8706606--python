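import numpy as np
import pytest

from fatecycle import (
    CouplingSchedule,
    IntegratorSettings,
    find_boundaries,
    get_preset,
    integrate,
    perturbed_symmetric_state,
)


@pytest.fixture(scope="session")
def double_or():
    return get_preset("double-or")


@pytest.fixture(scope="session")
def double_or_boundaries(double_or):
    """Oscillatory window of the standard double repressilator (cached)."""
    return find_boundaries(double_or.spec, double_or.g_scan)


@pytest.fixture(scope="session")
def oscillating_trajectory(double_or):
    """A settled mid-window oscillation of the double repressilator."""
    rng = np.random.default_rng(11)
    x0 = perturbed_symmetric_state(double_or.spec, double_or.g_oscillatory, rng)
    return integrate(
        double_or.spec,
        CouplingSchedule(kind="constant", g_start=double_or.g_oscillatory),
        x0,
        (0.0, 600.0),
        settings=IntegratorSettings(n_points=3000),
    )
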