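"""Independent oracles shared by the test suite.

These deliberately avoid the package's own closed-form solver so that
agreement between the two routes is a real check.
"""

import numpy as np


def ode_eaten(a: float, h: float, n0: float, t: float, n_pred: int = 1) -> float:
    """High-accuracy integration of dN/dt = -P a N / (1 + a h N)."""
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda _s, N: -n_pred * a * np.maximum(N, 0.0) / (1.0 + a * h * np.maximum(N, 0.0)),
        (0.0, t),
        [float(n0)],
        method="LSODA",
        rtol=1e-11,
        atol=1e-13,
    )
    assert sol.success
    return float(n0 - sol.y[0, -1])


def fixed_point_eaten(a: float, h: float, n0: float, t: float, n_iter: int = 200_000) -> float:
    """Damped fixed-point iteration of Ne = N0 (1 - exp(-a (t - h Ne)))."""
    ne = 0.0
    for _ in range(n_iter):
        nxt = 0.5 * ne + 0.5 * n0 * (1.0 - np.exp(-a * (t - h * ne)))
        if abs(nxt - ne) < 1e-13:
            return nxt
        ne = nxt
    return ne
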