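import numpy as np
import pytest

from ringflow import model as fm
from ringflow import synthetic as syn


@pytest.fixture(scope="session")
def params() -> fm.ModelParams:
    """Reference model parameters with a 79 s accumulation timescale."""
    return fm.ModelParams.from_timescale(79.0)


@pytest.fixture(scope="session")
def spec() -> syn.EmbryoSpec:
    return syn.EmbryoSpec(seed=7)


@pytest.fixture(scope="session")
def ground_truth(spec) -> syn.GroundTruth:
    return syn.GroundTruth(spec, syn.default_model_params(spec))


@pytest.fixture(scope="session")
def small_population():
    """Ten synthetic embryos with default population variability."""
    return syn.make_population(10, seed=11)


def ode_ring_size(rbar_ini: float, tbar_end: float) -> float:
    """Independent oracle: integrate dRbar/dtbar = −ln(2 Rbar_ini) e^tbar Rbar
    from the half-closure state Rbar(0) = 1/2."""
    from scipy.integrate import solve_ivp

    k = np.log(2.0 * rbar_ini)

    def rhs(t, y):
        return [-k * np.exp(t) * y[0]]

    sol = solve_ivp(rhs, (0.0, tbar_end), [0.5], rtol=1e-10, atol=1e-12)
    return float(sol.y[0, -1])
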