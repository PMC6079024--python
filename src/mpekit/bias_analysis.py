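"""Bias quantification: null-model predictions vs stochastic two-predator trials.

For every combination of trial duration, assemblage composition and varied
functional-response parameter, the sweep

1. generates deterministic single-predator trials over a density gradient,
2. builds the three null-model predictions from them (the population-
   dynamic model uses the generating parameters directly),
3. simulates stochastic two-predator trials under independence, and
4. records, per density, prediction minus replicate-mean eaten.

Negative differences mean the model predicts fewer prey eaten than the
simulated (independent) predators actually consume — i.e. the null model
underestimates predation and would misread independence as synergy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import fit_rogers
from .frmodels import FRParams
from .nullmodels import (
    AssemblageMember,
    PredatorAssemblage,
    multiplicative_risk,
    pair_replicates,
    popdyn_predict,
)
from .simulator import NoiseSpec, default_density_grid, simulate_deterministic, simulate_stochastic

logger = logging.getLogger(__name__)

__all__ = ["SweepConfig", "run_sweep", "summarize_extremes", "fig1_param_grid", "plot_bias"]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class SweepConfig:
    """Grid definition for the prediction-vs-simulation comparison.

    Defaults follow the simulation experiment: durations 1–24 h, handling
    time varied over 0.002–0.02 at a = 2, attack rate varied over 1–8 at
    h = 0.005; heterospecific assemblages fix member 1 at (2, 0.005).
    """

    durations_h: tuple = (1.0, 6.0, 12.0, 24.0)
    h_grid: tuple = tuple(np.round(np.linspace(0.002, 0.02, 10), 6))
    a_grid: tuple = tuple(float(a) for a in range(1, 9))
    fixed_a: float = 2.0
    fixed_h: float = 0.005
    modes: tuple = ("conspecific", "heterospecific")
    varied: tuple = ("h", "a")
    density_grid: tuple = tuple(int(n) for n in default_density_grid())
    n_replicates: int = 10
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.h_grid or not self.a_grid or not self.density_grid:
            raise ValueError("parameter and density grids must be non-empty")
        if any(not (1.0 <= T <= 24.0) for T in self.durations_h):
            raise ValueError("durations must lie within 1–24 hours")
        if any(m not in ("conspecific", "heterospecific") for m in self.modes):
            raise ValueError(f"unknown assemblage mode in {self.modes}")
        if any(v not in ("h", "a") for v in self.varied):
            raise ValueError(f"varied parameters must be 'h' or 'a', got {self.varied}")


def fig1_param_grid():
    """(a, h) combinations for the side-by-side prediction comparison figure.

    Same axes as the sweeps: handling time varied at a = 2, attack rate
    varied at h = 0.005, spanning values reported in feeding studies.
    """
    combos = [(2.0, h) for h in (0.002, 0.005, 0.01, 0.02)]
    combos += [(a, 0.005) for a in (1.0, 4.0, 8.0)]
    return combos


def _grid_point_rows(
    mode: str,
    varied: str,
    value: float,
    T_h: float,
    config: SweepConfig,
    seed_seq: np.random.SeedSequence,
) -> list:
    t = T_h / HOURS_PER_DAY
    grid = np.asarray(config.density_grid, dtype=int)
    if mode == "conspecific":
        a2 = value if varied == "a" else config.fixed_a
        h2 = value if varied == "h" else config.fixed_h
        a1, h1 = a2, h2
    else:
        a1, h1 = config.fixed_a, config.fixed_h
        a2 = value if varied == "a" else config.fixed_a
        h2 = value if varied == "h" else config.fixed_h
    p1, p2 = FRParams(a1, h1), FRParams(a2, h2)
    conspecific = mode == "conspecific"

    det1 = simulate_deterministic(p1, grid=grid, t=t, assemblage_id="A")
    det2 = det1 if conspecific else simulate_deterministic(p2, grid=grid, t=t, assemblage_id="B")

    # Multiplicative risk: per-density eaten probabilities from the trials.
    prob1 = {tr.n0: tr.eaten / tr.n0 for tr in det1.trials}
    prob2 = {tr.n0: tr.eaten / tr.n0 for tr in det2.trials}
    mult = np.array([multiplicative_risk(n0, prob1[n0], prob2[n0]) for n0 in grid])

    # Direct FR: fit the random predator equation to the paired expected data.
    seeds = seed_seq.spawn(2)
    pair_seed = int(seeds[0].generate_state(1)[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # expected pseudoreplication note
        paired = pair_replicates(det1.trials, det1.trials if conspecific else det2.trials, seed=pair_seed)
    fit = fit_rogers(paired, start=FRParams(a1 + a2, min(h1, h2) / 2 if min(h1, h2) > 0 else 1e-6))
    if not fit.converged:
        raise RuntimeError(f"direct FR fit failed: {fit.message}")
    direct = np.asarray(fit.predict(grid.astype(float), t))

    # Population-dynamic: generating parameters, depletion ODE.
    assemblage = PredatorAssemblage(
        (AssemblageMember("A", 1, p1), AssemblageMember("A" if conspecific else "B", 1, p2))
    )
    popdyn = np.asarray(popdyn_predict(assemblage, grid.astype(float), t))

    sim_seed = int(seeds[1].generate_state(1)[0])
    sim = simulate_stochastic(
        assemblage, grid=grid, t=t, noise=config.noise, n_replicates=config.n_replicates, seed=sim_seed
    )
    sim_mean = (
        pd.DataFrame({"n0": [tr.n0 for tr in sim.trials], "eaten": [tr.eaten for tr in sim.trials]})
        .groupby("n0")["eaten"]
        .mean()
        .reindex(grid)
        .to_numpy()
    )

    rows = []
    for model, pred in (("mult_risk", mult), ("direct_fr", direct), ("pop_dyn", popdyn)):
        for i, n0 in enumerate(grid):
            rows.append(
                {
                    "model": model,
                    "assemblage": mode,
                    "varied_param": varied,
                    "varied_value": value,
                    "duration_h": T_h,
                    "a1": a1,
                    "h1": h1,
                    "a2": a2,
                    "h2": h2,
                    "n0": int(n0),
                    "predicted": float(pred[i]),
                    "simulated_mean": float(sim_mean[i]),
                    "difference": float(pred[i] - sim_mean[i]),
                }
            )
    return rows


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run the full prediction-vs-simulation comparison.

    Returns a tidy table with one row per (model, mode, varied parameter,
    value, duration, density); ``difference = predicted - simulated_mean``.
    Individual grid-point failures are logged and skipped, never fatal.
    """
    root = np.random.SeedSequence(config.seed)
    rows: list = []
    failures: list = []
    tasks = [
        (mode, varied, float(value), float(T_h))
        for mode in config.modes
        for varied in config.varied
        for value in (config.h_grid if varied == "h" else config.a_grid)
        for T_h in config.durations_h
    ]
    children = root.spawn(len(tasks))
    for (mode, varied, value, T_h), child in zip(tasks, children):
        try:
            rows.extend(_grid_point_rows(mode, varied, value, T_h, config, child))
        except Exception as exc:  # noqa: BLE001 — sweep must survive point failures
            logger.warning("grid point failed (%s, %s=%s, T=%sh): %s", mode, varied, value, T_h, exc)
            failures.append({"mode": mode, "varied": varied, "value": value, "T_h": T_h, "error": str(exc)})
    table = pd.DataFrame(rows)
    table.attrs["failures"] = failures
    table.attrs["seed"] = config.seed
    return table


def summarize_extremes(
    table: pd.DataFrame,
    model: str,
    duration_h: float,
    n0: int,
    assemblage: Optional[str] = None,
    varied_param: Optional[str] = None,
):
    """(min, max) of prediction-minus-simulation over the varied parameter grid
    at one model, duration and density."""
    mask = (table["model"] == model) & (table["duration_h"] == duration_h) & (table["n0"] == n0)
    if assemblage is not None:
        mask &= table["assemblage"] == assemblage
    if varied_param is not None:
        mask &= table["varied_param"] == varied_param
    sl = table.loc[mask, "difference"]
    if sl.empty:
        raise ValueError("no rows match the requested slice")
    return float(sl.min()), float(sl.max())


def plot_bias(table: pd.DataFrame, model: str, assemblage: str, varied_param: str, ax=None):
    """One bias panel: difference vs density, one series per parameter value.

    Requires matplotlib (optional dependency).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sl = table[
        (table["model"] == model)
        & (table["assemblage"] == assemblage)
        & (table["varied_param"] == varied_param)
    ]
    for value, grp in sl.groupby("varied_value"):
        grp = grp.sort_values("n0")
        ax.plot(grp["n0"], grp["difference"], label=f"{varied_param}={value:g}")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("initial prey density")
    ax.set_ylabel("prediction − simulated mean (prey)")
    ax.set_title(f"{model}, {assemblage}")
    ax.legend(fontsize="small")
    return ax
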