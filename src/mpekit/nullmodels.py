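"""Null models for prey eaten by multiple predators acting independently.

Three predictors of the combined catch of a predator assemblage, all
assuming no emergent interactions:

* multiplicative risk — combines per-predator eaten probabilities as
  ``N0 (P_A + P_B - P_A P_B)``;
* direct FR — fits the random predator equation to multiplicative-risk
  expected data built from randomly paired single-predator replicates;
* population-dynamic — integrates the prey depletion ODE
  ``dN/dt = -Σ f_i(N) P_i`` with each predator's own functional response,
  with Latin-hypercube propagation of parameter uncertainty into a 95% CI.
"""

from __future__ import annotations

import enum
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import norm, qmc

from .fitting import BootstrapBand, FRFit, bootstrap_band, fit_rogers
from .frmodels import FRParams, TrialRecord, holling2_rate

__all__ = [
    "NullModel",
    "AssemblageMember",
    "PredatorAssemblage",
    "SurvivalProb",
    "PredictionResult",
    "multiplicative_risk",
    "round_half_away",
    "pair_replicates",
    "direct_fr_predict",
    "popdyn_predict",
    "popdyn_ci",
]


class NullModel(enum.Enum):
    MULT_RISK = "mult_risk"
    DIRECT_FR = "direct_fr"
    POP_DYN = "pop_dyn"


@dataclass(frozen=True)
class AssemblageMember:
    label: str
    density: int  # predators per arena
    params: FRParams

    def __post_init__(self) -> None:
        if self.density < 1 or int(self.density) != self.density:
            raise ValueError(f"predator density must be a positive integer, got {self.density}")


@dataclass(frozen=True)
class PredatorAssemblage:
    members: tuple

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("assemblage needs at least one member")
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def conspecific(self) -> bool:
        return len({m.label for m in self.members}) == 1

    @property
    def label(self) -> str:
        return "+".join(m.label for m in self.members for _ in range(m.density))


@dataclass(frozen=True)
class SurvivalProb:
    """Per-prey probability of being eaten over a trial."""

    p: float
    source: str = "measured"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"probability must be in [0, 1], got {self.p}")


@dataclass
class PredictionResult:
    model: NullModel
    n0: float
    t: float
    expected_eaten: float
    ci95: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.expected_eaten <= self.n0 + 1e-9):
            raise ValueError("expected_eaten must lie in [0, N0]")


def _prob(p) -> float:
    p = p.p if isinstance(p, SurvivalProb) else float(p)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must be in [0, 1], got {p}")
    return p


def multiplicative_risk(n0, p_a, p_b) -> float:
    """Expected eaten under independence: N0 (P_A + P_B - P_A P_B)."""
    pa, pb = _prob(p_a), _prob(p_b)
    return n0 * (pa + pb - pa * pb)


def round_half_away(x):
    """Round to nearest integer, ties away from zero (0.5 -> 1)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out if out.ndim else float(out)


def _by_density(trials: Sequence[TrialRecord]) -> dict:
    groups = defaultdict(list)
    for tr in trials:
        groups[tr.n0].append(tr)
    return dict(groups)


def pair_replicates(
    trials_a: Sequence[TrialRecord],
    trials_b: Sequence[TrialRecord],
    seed: Optional[int] = None,
    assemblage_id: Optional[str] = None,
) -> list:
    """Build expected two-predator trials by random replicate pairing.

    For each density, trials of A and B are randomly matched one-to-one
    (pairing is the random assignment of replicate numbers) and combined
    with the multiplicative risk rule using per-replicate eaten
    probabilities ``Ne/N0``; the expectation is rounded to the nearest
    integer so the result can feed a binomial-likelihood fit.

    A conspecific pair (same input list / same assemblage id) reuses each
    replicate twice, which is pseudoreplication; a warning is emitted and
    the output assemblage id gains a ``(pseudoreplicated)`` marker unless an
    explicit id is supplied.
    """
    trials_a, trials_b = list(trials_a), list(trials_b)
    conspecific = trials_a is trials_b or (
        trials_a == trials_b
        and {tr.assemblage_id for tr in trials_a} == {tr.assemblage_id for tr in trials_b}
    )
    ga, gb = _by_density(trials_a), _by_density(trials_b)
    if set(ga) != set(gb):
        raise ValueError(
            f"density grids differ: A has {sorted(set(ga) - set(gb))} extra, "
            f"B has {sorted(set(gb) - set(ga))} extra"
        )
    rng = np.random.default_rng(seed)
    label_a = trials_a[0].assemblage_id if trials_a else "A"
    label_b = trials_b[0].assemblage_id if trials_b else "B"
    out_id = assemblage_id or f"{label_a}+{label_b}"
    if conspecific:
        warnings.warn(
            "conspecific pairing reuses each replicate twice (pseudoreplication)",
            UserWarning,
            stacklevel=2,
        )
        if assemblage_id is None:
            out_id += " (pseudoreplicated)"

    paired = []
    rep = 1
    for n0 in sorted(ga):
        reps_a, reps_b = ga[n0], gb[n0]
        if len(reps_a) != len(reps_b):
            raise ValueError(f"replicate counts differ at N0={n0}: {len(reps_a)} vs {len(reps_b)}")
        order_a = rng.permutation(len(reps_a))
        order_b = order_a if conspecific else rng.permutation(len(reps_b))
        for ia, ib in zip(order_a, order_b):
            ta, tb = reps_a[ia], reps_b[ib]
            if not np.isclose(ta.duration, tb.duration):
                raise ValueError(f"paired trials must share a duration (N0={n0})")
            expected = multiplicative_risk(n0, ta.eaten / n0, tb.eaten / n0)
            paired.append(
                TrialRecord(
                    assemblage_id=out_id,
                    replicate_id=rep,
                    n0=n0,
                    eaten=min(round_half_away(expected), n0),
                    duration=ta.duration,
                )
            )
            rep += 1
    return paired


def direct_fr_predict(
    trials_a: Sequence[TrialRecord],
    trials_b: Sequence[TrialRecord],
    seed: Optional[int] = None,
    n_boot: int = 2000,
    grid: Optional[np.ndarray] = None,
    start: Optional[FRParams] = None,
):
    """Direct FR null model: fit the random predator equation to paired expected data.

    Returns ``(fit, predictions, band)`` — the ML fit, a list of
    PredictionResult over ``grid`` (default: trial densities), and the
    bootstrap band (None when ``n_boot`` is 0).  The same machinery applies
    unchanged to observed multi-predator trials for empirical tests.
    """
    paired = pair_replicates(trials_a, trials_b, seed=seed)
    fit = fit_rogers(paired, start=start)
    t = paired[0].duration
    if grid is None:
        grid = np.unique([tr.n0 for tr in paired]).astype(float)
    grid = np.asarray(grid, dtype=float)
    curve = np.asarray(fit.predict(grid, t))
    band = None
    if n_boot:
        band = bootstrap_band(paired, fit, n_boot=n_boot, seed=None if seed is None else seed + 1, grid=grid)
    preds = [
        PredictionResult(
            model=NullModel.DIRECT_FR,
            n0=float(g),
            t=float(t),
            expected_eaten=float(c),
            ci95=(float(band.lower95[i]), float(band.upper95[i])) if band is not None else None,
        )
        for i, (g, c) in enumerate(zip(grid, curve))
    ]
    return fit, preds, band


def _depletion_rhs(assemblage: PredatorAssemblage, n0_arr: np.ndarray):
    members = [(m.density, m.params, m.params.attack_at(n0_arr)) for m in assemblage.members]
    h_list = [m.params.handling_time for m in assemblage.members]

    def rhs(_t, N):
        Np = np.maximum(N, 0.0)
        dN = np.zeros_like(Np)
        for (P, _params, a), h in zip(members, h_list):
            dN -= P * a * Np / (1.0 + a * h * Np)
        return dN

    return rhs


def popdyn_predict(assemblage: PredatorAssemblage, n0, t: float, rtol: float = 1e-8, atol: float = 1e-10):
    """Population-dynamic null model: integrate prey depletion over the trial.

    Solves ``dN/dt = -Σ f_i(N) P_i`` from N(0)=N0 over [0, t] and returns
    the expected eaten ``N0 - N(t)``.  ``n0`` may be an array of densities;
    each is an independent arena so the system is integrated elementwise.
    """
    n0_arr = np.atleast_1d(np.asarray(n0, dtype=float))
    if np.any(n0_arr < 1):
        raise ValueError("n0 must be >= 1")
    if t <= 0:
        raise ValueError("t must be > 0")
    rhs = _depletion_rhs(assemblage, n0_arr)
    sol = solve_ivp(rhs, (0.0, t), n0_arr, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"depletion ODE integration failed: {sol.message}")
    n_final = np.clip(sol.y[:, -1], 0.0, n0_arr)
    eaten = n0_arr - n_final
    return eaten if np.ndim(n0) else float(eaten[0])


def _lhs_param_draws(fit: FRFit, u: np.ndarray, n_truncated: list) -> np.ndarray:
    """Map LHS uniforms (n, 2) to (a, h) draws honouring the fit's CIs and vcov."""
    a_hat, h_hat = fit.estimates.attack_rate, fit.estimates.handling_time
    sd_a = (fit.ci95_a[1] - fit.ci95_a[0]) / (2 * 1.959963984540054)
    sd_h = (fit.ci95_h[1] - fit.ci95_h[0]) / (2 * 1.959963984540054)
    z = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    if fit.vcov is not None and sd_a > 0 and sd_h > 0:
        denom = np.sqrt(fit.vcov[0, 0] * fit.vcov[1, 1])
        rho = float(np.clip(fit.vcov[0, 1] / denom, -0.999, 0.999)) if denom > 0 else 0.0
    else:
        rho = 0.0  # covariance assumed zero when unknown
    z_a = z[:, 0]
    z_h = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    a = a_hat + sd_a * z_a
    h = h_hat + sd_h * z_h
    bad = int(np.sum(a < 1e-6) + np.sum(h < 0.0))
    n_truncated[0] += bad
    return np.column_stack([np.maximum(a, 1e-6), np.maximum(h, 0.0)])


def popdyn_ci(
    assemblage_fits: Sequence[FRFit],
    densities: Sequence[int],
    n0: float,
    t: float,
    n_lhs: int = 1000,
    seed: Optional[int] = None,
):
    """95% CI of the population-dynamic prediction by Latin hypercube sampling.

    Draws ``n_lhs`` joint parameter sets over the fits' 95% CIs (Gaussian
    margins, correlation from each fit's vcov, zero covariance when
    unknown), integrates the depletion ODE per set, and returns the 2.5%
    and 97.5% quantiles of the expected eaten, plus the count of draws
    truncated at the positivity bounds.
    """
    if len(assemblage_fits) != len(densities):
        raise ValueError("one predator density per fit is required")
    m = len(assemblage_fits)
    sampler = qmc.LatinHypercube(d=2 * m, seed=seed)
    u = sampler.random(n_lhs)
    n_truncated = [0]
    draws = [_lhs_param_draws(fit, u[:, 2 * i : 2 * i + 2], n_truncated) for i, fit in enumerate(assemblage_fits)]

    P = np.asarray(densities, dtype=float)

    def rhs(_t, N):
        Np = np.maximum(N, 0.0)
        dN = np.zeros_like(Np)
        for i in range(m):
            a, h = draws[i][:, 0], draws[i][:, 1]
            dN -= P[i] * a * Np / (1.0 + a * h * Np)
        return dN

    y0 = np.full(n_lhs, float(n0))
    sol = solve_ivp(rhs, (0.0, t), y0, method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"LHS depletion integration failed: {sol.message}")
    eaten = np.clip(n0 - sol.y[:, -1], 0.0, n0)
    lo, hi = np.percentile(eaten, [2.5, 97.5])
    return (float(lo), float(hi)), n_truncated[0]
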