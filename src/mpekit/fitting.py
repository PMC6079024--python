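"""Maximum-likelihood estimation of functional-response parameters.

Trials are modelled as binomial draws: each of the N0 prey is eaten with
probability ``rogers_eaten(a, h, N0, t) / N0``, so depletion over the trial
is part of the likelihood rather than a constant-risk approximation.
Optimisation runs on log-transformed (a, h) to keep both positive without
boundary pathologies; confidence intervals are Wald intervals from the
inverse observed information, and non-parametric bootstrap bands are
available for curve-level comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binom

from .frmodels import FRParams, ResponseType, TrialRecord, rogers_eaten

__all__ = ["FRFit", "BootstrapBand", "OverlapResult", "fit_rogers", "bootstrap_band", "ci_overlap"]

_PCLIP = (1e-9, 1.0 - 1e-9)
_LOG_BOUNDS = ((-20.0, 10.0), (-20.0, 5.0))  # (log a, log h)


@dataclass
class FRFit:
    """Result of a binomial ML fit of the random predator equation."""

    estimates: FRParams
    log_likelihood: float
    ci95_a: tuple
    ci95_h: tuple
    vcov: Optional[np.ndarray]
    n_trials: int
    converged: bool
    message: str = ""

    def predict(self, n0, t):
        """Expected eaten at density n0 over t days (single predator)."""
        return rogers_eaten(self.estimates, n0, t)


@dataclass
class BootstrapBand:
    """Pointwise 95% envelope of bootstrap-refit expected-eaten curves."""

    grid: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    n_boot: int
    n_dropped: int = 0
    point_curve: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.lower95 = np.asarray(self.lower95, dtype=float)
        self.upper95 = np.asarray(self.upper95, dtype=float)
        if np.any(self.lower95 > self.upper95 + 1e-12):
            raise ValueError("lower95 must be <= upper95 pointwise")


@dataclass
class OverlapResult:
    """Per-density CI overlap verdict between two bands."""

    grid: np.ndarray
    overlap: np.ndarray  # bool per density
    significant: bool
    regions: list = field(default_factory=list)  # (density_lo, density_hi) of non-overlap


def _trial_arrays(trials: Sequence[TrialRecord]):
    n0 = np.array([tr.n0 for tr in trials], dtype=float)
    ne = np.array([tr.eaten for tr in trials], dtype=float)
    t = np.array([tr.duration for tr in trials], dtype=float)
    return n0, ne, t


def _nll(log_theta, n0, ne, t, response_type):
    a = math.exp(log_theta[0])
    h = math.exp(log_theta[1])
    try:
        params = FRParams(a, h, response_type)
        pred = rogers_eaten(params, n0, t)
    except (ValueError, RuntimeError, OverflowError):
        return 1e12
    p = np.clip(np.asarray(pred) / n0, *_PCLIP)
    ll = binom.logpmf(ne, n0, p)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(np.sum(ll))


def _default_start(n0, ne, t) -> np.ndarray:
    # Moment-ish guesses: slope at low density for a, inverse max rate for h.
    low = n0 <= np.quantile(n0, 0.3)
    rate_low = ne[low] / (n0[low] * t[low])
    a0 = float(np.clip(np.mean(rate_low) if rate_low.size else 0.5, 1e-3, 50.0))
    max_rate = float(np.max(ne / t)) if np.any(ne > 0) else 1.0
    h0 = float(np.clip(1.0 / max(max_rate, 1e-6), 1e-5, 10.0))
    return np.array([math.log(a0), math.log(h0)])


def _hessian_vcov(log_opt, n0, ne, t, response_type):
    """vcov over (a, h) via finite-difference Hessian on the natural scale."""
    a, h = math.exp(log_opt[0]), math.exp(log_opt[1])
    theta = np.array([a, h])
    steps = np.maximum(np.abs(theta) * 1e-4, 1e-9)

    def f(v):
        va, vh = max(v[0], 1e-12), max(v[1], 1e-12)
        return _nll([math.log(va), math.log(vh)], n0, ne, t, response_type)

    hess = np.empty((2, 2))
    f0 = f(theta)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * steps[i]
            ej = np.eye(2)[j] * steps[j]
            if i == j:
                hess[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / steps[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
        return None
    return vcov


def fit_rogers(
    trials: Sequence[TrialRecord],
    start: Optional[FRParams] = None,
    response_type: ResponseType = ResponseType.TYPE_II,
) -> FRFit:
    """Fit (a, h) of the random predator equation by binomial ML.

    Parameters
    ----------
    trials:
        Single-predator trials (or paired expected data); needs at least two
        distinct initial densities, and integer eaten counts.
    start:
        Optional starting parameters; a heuristic start is used otherwise.
    response_type:
        TYPE_II only; estimating a TYPE_III attack function is out of scope.

    Returns
    -------
    FRFit.  ``converged`` is False (never an exception) when the optimizer
    stalls; diagnostics go to ``message``.
    """
    if response_type is not ResponseType.TYPE_II:
        raise NotImplementedError("only TYPE_II parameter estimation is supported")
    trials = list(trials)
    n0, ne, t = _trial_arrays(trials)
    if np.unique(n0).size < 2:
        raise ValueError("fit requires trials at >= 2 distinct initial densities")
    if not np.all(ne == np.round(ne)):
        raise ValueError(
            "eaten counts must be integers for the binomial likelihood; "
            "round expected values to the nearest integer first (direct FR rounding rule)"
        )

    x0 = (
        np.array([math.log(start.attack_rate), math.log(max(start.handling_time, 1e-8))])
        if start is not None
        else _default_start(n0, ne, t)
    )
    x0 = np.clip(x0, [b[0] for b in _LOG_BOUNDS], [b[1] for b in _LOG_BOUNDS])
    args = (n0, ne, t, response_type)
    res = minimize(_nll, x0, args=args, method="L-BFGS-B", bounds=_LOG_BOUNDS)
    if not res.success:
        res2 = minimize(_nll, x0, args=args, method="Nelder-Mead",
                        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-8})
        if res2.fun <= res.fun:
            res = res2

    a_hat, h_hat = math.exp(res.x[0]), math.exp(res.x[1])
    ll = -res.fun
    converged = bool(np.isfinite(ll)) and res.fun < 1e11
    message = "" if res.success else f"optimizer: {res.message}"
    if not converged:
        message = message or "likelihood not finite at optimum"

    vcov = _hessian_vcov(res.x, *args) if converged else None
    if vcov is not None:
        se = np.sqrt(np.diag(vcov))
        ci_a = (a_hat - 1.96 * se[0], a_hat + 1.96 * se[0])
        ci_h = (max(h_hat - 1.96 * se[1], 0.0), h_hat + 1.96 * se[1])
    else:
        ci_a, ci_h = (a_hat, a_hat), (h_hat, h_hat)
        if converged:
            message = (message + "; " if message else "") + "singular information: degenerate Wald CIs"

    return FRFit(
        estimates=FRParams(a_hat, h_hat, response_type),
        log_likelihood=ll,
        ci95_a=ci_a,
        ci95_h=ci_h,
        vcov=vcov,
        n_trials=len(trials),
        converged=converged,
        message=message,
    )


def bootstrap_band(
    trials: Sequence[TrialRecord],
    fit: FRFit,
    n_boot: int = 2000,
    seed: Optional[int] = None,
    grid: Optional[np.ndarray] = None,
    max_drop_frac: float = 0.2,
) -> BootstrapBand:
    """Non-parametric bootstrap 95% band around the fitted expected-eaten curve.

    Trials are resampled with replacement ``n_boot`` times; each resample is
    refitted starting from ``fit.estimates`` and predicted over ``grid``
    (default: the sorted unique trial densities, at the common trial
    duration).  Replicates that fail to converge are dropped and counted; an
    error is raised if more than ``max_drop_frac`` are dropped.
    """
    if not fit.converged:
        raise ValueError("bootstrap_band requires a converged fit")
    trials = list(trials)
    n0, _, t = _trial_arrays(trials)
    if np.unique(n0).size < 2:
        raise ValueError("bootstrap requires >= 2 distinct initial densities")
    t_unique = np.unique(t)
    if t_unique.size > 1:
        raise ValueError("bootstrap band needs a single common trial duration")
    t_common = float(t_unique[0])
    if grid is None:
        grid = np.unique(n0)
    grid = np.asarray(grid, dtype=float)

    rng = np.random.default_rng(seed)
    idx_all = rng.integers(0, len(trials), size=(n_boot, len(trials)))
    curves = []
    n_dropped = 0
    for b in range(n_boot):
        sample = [trials[i] for i in idx_all[b]]
        if np.unique([tr.n0 for tr in sample]).size < 2:
            n_dropped += 1
            continue
        bfit = fit_rogers(sample, start=fit.estimates)
        if not bfit.converged:
            n_dropped += 1
            continue
        curves.append(rogers_eaten(bfit.estimates, grid, t_common))
    if n_dropped > max_drop_frac * n_boot:
        raise RuntimeError(
            f"{n_dropped}/{n_boot} bootstrap replicates failed to converge "
            f"(> {max_drop_frac:.0%} allowed)"
        )
    curves = np.asarray(curves)
    lower = np.percentile(curves, 2.5, axis=0)
    upper = np.percentile(curves, 97.5, axis=0)
    point = np.asarray(rogers_eaten(fit.estimates, grid, t_common))
    return BootstrapBand(
        grid=grid,
        lower95=np.clip(lower, 0.0, grid),
        upper95=np.clip(upper, 0.0, grid),
        n_boot=n_boot,
        n_dropped=n_dropped,
        point_curve=point,
    )


def ci_overlap(band_a: BootstrapBand, band_b: BootstrapBand) -> OverlapResult:
    """Classify two bands as significantly different where their CIs do not overlap.

    Returns a per-density overlap flag and a global verdict: significant
    when any contiguous run of densities is non-overlapping, with the run
    bounds reported.
    """
    if band_a.grid.shape != band_b.grid.shape or not np.allclose(band_a.grid, band_b.grid):
        raise ValueError("bands must share an identical density grid")
    overlap = (band_a.lower95 <= band_b.upper95) & (band_b.lower95 <= band_a.upper95)
    regions = []
    start = None
    for i, ok in enumerate(overlap):
        if not ok and start is None:
            start = i
        elif ok and start is not None:
            regions.append((float(band_a.grid[start]), float(band_a.grid[i - 1])))
            start = None
    if start is not None:
        regions.append((float(band_a.grid[start]), float(band_a.grid[-1])))
    return OverlapResult(
        grid=band_a.grid,
        overlap=overlap,
        significant=bool(regions),
        regions=regions,
    )
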