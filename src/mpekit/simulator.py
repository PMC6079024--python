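"""In-silico predation trials.

Two generators: a deterministic one producing noiseless single-predator
trials from the random predator equation over a density gradient, and a
stochastic one that integrates the multi-predator depletion ODE with a
fixed-step RK4 scheme while redrawing each predator's attack rate and
handling time from normal distributions at every step (sd a fraction of
the mean), mimicking parameter uncertainty in real feeding experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .frmodels import FRParams, TrialRecord, rogers_eaten
from .nullmodels import PredatorAssemblage, round_half_away

__all__ = [
    "NoiseSpec",
    "SimulatedDataset",
    "default_density_grid",
    "simulate_deterministic",
    "simulate_stochastic",
]

_PARAM_FLOOR = 1e-6  # truncation floor for noisy parameter draws


@dataclass(frozen=True)
class NoiseSpec:
    """Per-step parameter noise: sd as a fraction of the mean value.

    ``redraw_dt`` is the fixed integration step at which parameters are
    redrawn; None means t/100 is chosen at simulation time.
    """

    sd_frac_a: float = 0.10
    sd_frac_h: float = 0.05
    redraw_dt: Optional[float] = None

    def __post_init__(self) -> None:
        for name, v in (("sd_frac_a", self.sd_frac_a), ("sd_frac_h", self.sd_frac_h)):
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.redraw_dt is not None and not (self.redraw_dt > 0):
            raise ValueError(f"redraw_dt must be > 0, got {self.redraw_dt}")


@dataclass
class SimulatedDataset:
    trials: list
    params: dict  # label -> FRParams of the generating predators
    grid: np.ndarray
    n_replicates: int
    seed: Optional[int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        counts = {}
        for tr in self.trials:
            counts[tr.n0] = counts.get(tr.n0, 0) + 1
        if any(c != self.n_replicates for c in counts.values()):
            raise ValueError("each density must carry exactly n_replicates trials")


def default_density_grid(lo: int = 1, hi: int = 800, n: int = 25) -> np.ndarray:
    """n distinct log-spaced integer prey densities spanning [lo, hi].

    Rounding collapses nearby low-density points, so candidates are added
    until n distinct integers remain (or the integer range is exhausted).
    """
    if hi - lo + 1 <= n:
        return np.arange(lo, hi + 1, dtype=int)
    m = n
    grid = np.unique(np.round(np.geomspace(lo, hi, m)).astype(int))
    while grid.size < n:
        m += 1
        grid = np.unique(np.round(np.geomspace(lo, hi, m)).astype(int))
    if grid.size > n:
        idx = np.round(np.linspace(0, grid.size - 1, n)).astype(int)
        grid = grid[np.unique(idx)]
    return grid


def simulate_deterministic(
    params: FRParams,
    grid: Optional[Sequence[int]] = None,
    t: float = 1.0,
    assemblage_id: str = "A",
) -> SimulatedDataset:
    """Noiseless single-predator trials: one rounded catch per density."""
    grid = default_density_grid() if grid is None else np.asarray(grid, dtype=int)
    eaten = round_half_away(rogers_eaten(params, grid.astype(float), t))
    trials = [
        TrialRecord(
            assemblage_id=assemblage_id,
            replicate_id=1,
            n0=int(n0),
            eaten=float(min(ne, n0)),
            duration=float(t),
        )
        for n0, ne in zip(grid, eaten)
    ]
    return SimulatedDataset(
        trials=trials,
        params={assemblage_id: params},
        grid=grid,
        n_replicates=1,
        seed=None,
        metadata={"generator": "deterministic", "t_days": float(t)},
    )


def _rk4_step(N, dt, a_list, h_list, P_list):
    def rhs(Ncur):
        Np = np.maximum(Ncur, 0.0)
        dN = np.zeros_like(Np)
        for a, h, P in zip(a_list, h_list, P_list):
            dN -= P * a * Np / (1.0 + a * h * Np)
        return dN

    k1 = rhs(N)
    k2 = rhs(N + 0.5 * dt * k1)
    k3 = rhs(N + 0.5 * dt * k2)
    k4 = rhs(N + dt * k3)
    return N + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_stochastic(
    assemblage: PredatorAssemblage,
    grid: Optional[Sequence[int]] = None,
    t: float = 1.0,
    noise: NoiseSpec = NoiseSpec(),
    n_replicates: int = 10,
    seed: Optional[int] = None,
) -> SimulatedDataset:
    """Stochastic multi-predator trials via fixed-step RK4 with noisy parameters.

    Each (density, replicate) trial is an independent integration of the
    depletion ODE; at every RK4 step each member's (a, h) are redrawn from
    normal distributions centred on the true values with sds
    ``sd_frac * mean``, truncated at a small positive floor.  The eaten
    count is ``round(N0 - N(t))`` clipped to [0, N0].

    A seed is mandatory: trial data are only publishable if regenerable.
    """
    if seed is None:
        raise ValueError("simulate_stochastic requires an explicit seed")
    grid = default_density_grid() if grid is None else np.asarray(grid, dtype=int)
    dt = noise.redraw_dt if noise.redraw_dt is not None else t / 100.0
    n_steps = int(round(t / dt))
    if n_steps < 10:
        raise ValueError(
            f"only {n_steps} redraw steps over the trial; need >= 10 for the noise model"
        )
    dt = t / n_steps

    rng = np.random.default_rng(seed)
    D, R = len(grid), n_replicates
    N0 = grid.astype(float)[:, None]  # (D, 1)
    N = np.broadcast_to(N0, (D, R)).copy()
    P_list = [float(m.density) for m in assemblage.members]
    mean_a = []
    for m in assemblage.members:
        a = np.asarray(m.params.attack_at(grid.astype(float)), dtype=float)
        mean_a.append(a.reshape(-1, 1) if a.ndim else np.full((D, 1), float(a)))
    mean_h = [m.params.handling_time for m in assemblage.members]

    for _ in range(n_steps):
        a_list, h_list = [], []
        for i in range(len(assemblage.members)):
            a_draw = rng.normal(mean_a[i], noise.sd_frac_a * mean_a[i], size=(D, R))
            h_draw = rng.normal(mean_h[i], noise.sd_frac_h * mean_h[i], size=(D, R))
            a_list.append(np.maximum(a_draw, _PARAM_FLOOR))
            h_list.append(np.maximum(h_draw, _PARAM_FLOOR) if mean_h[i] > 0 else np.zeros((D, R)))
        N = np.clip(_rk4_step(N, dt, a_list, h_list, P_list), 0.0, None)

    eaten = np.clip(round_half_away(N0 - N), 0.0, N0)
    label = assemblage.label
    trials = [
        TrialRecord(
            assemblage_id=label,
            replicate_id=r + 1,
            n0=int(grid[d]),
            eaten=float(eaten[d, r]),
            duration=float(t),
        )
        for d in range(D)
        for r in range(R)
    ]
    return SimulatedDataset(
        trials=trials,
        params={f"{m.label}[{i}]": m.params for i, m in enumerate(assemblage.members)},
        grid=grid,
        n_replicates=n_replicates,
        seed=seed,
        metadata={
            "generator": "stochastic-rk4",
            "t_days": float(t),
            "n_steps": n_steps,
            "redraw_dt": dt,
            "sd_frac_a": noise.sd_frac_a,
            "sd_frac_h": noise.sd_frac_h,
            "param_floor": _PARAM_FLOOR,
        },
    )
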