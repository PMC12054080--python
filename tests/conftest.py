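import numpy as np
import pytest
from scipy.integrate import solve_ivp

from vancoauc.pk import PKParameters, Regimen


@pytest.fixture(scope="session")
def published_pop():
    from vancoauc.popmodel import PopulationModel

    return PopulationModel()


def ode_concentration(params: PKParameters, regimen: Regimen, times) -> np.ndarray:
    """Independent numerical oracle: integrate dA/dt = R_in(t) - k*A, C = A/V.

    Uses stiff-aware integration with tight tolerances and explicit
    breakpoints at every infusion start/stop so the piecewise-constant
    input is resolved exactly.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    k = params.k

    def rate_in(t):
        return sum(ev.rate for ev in regimen.events
                   if ev.start < t <= ev.start + ev.duration)

    def rhs(t, y):
        return [rate_in(t) - k * y[0]]

    breaks = sorted({ev.start for ev in regimen.events}
                    | {ev.start + ev.duration for ev in regimen.events})
    t_end = float(times.max()) if len(times) else 0.0
    sol = solve_ivp(
        rhs, (0.0, max(t_end, 1e-9)), [0.0], t_eval=np.sort(times),
        rtol=1e-10, atol=1e-12, max_step=0.05, method="LSODA",
    )
    order = np.argsort(times)
    out = np.empty_like(times)
    out[order] = sol.y[0] / params.v
    return out
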