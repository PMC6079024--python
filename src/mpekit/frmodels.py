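"""Closed-form functional-response mathematics.

Implements the Holling type-II instantaneous feeding rate and the
depletion-corrected random predator equation (Rogers), which gives the
cumulative number of prey eaten over a trial of fixed duration when eaten
prey are not replaced.

Units are fixed throughout the package: time in days, attack rate in
arena·day⁻¹, handling time in day·prey⁻¹, prey densities per arena.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import lambertw

__all__ = [
    "ResponseType",
    "FRParams",
    "TrialRecord",
    "holling2_rate",
    "rogers_eaten",
]


class ResponseType(enum.Enum):
    """Functional response shape.

    TYPE_II is the saturating disc equation with constant attack rate.
    TYPE_III is a hook: the attack rate is a caller-supplied non-negative
    function of the initial prey density, constant within a trial.
    """

    TYPE_II = "type_ii"
    TYPE_III = "type_iii"


@dataclass(frozen=True)
class FRParams:
    """A predator's functional response parameters.

    Parameters
    ----------
    attack_rate:
        Instantaneous search/capture coefficient ``a`` (arena·day⁻¹); > 0.
        For TYPE_III this is the value reported by ``attack_fn`` evaluated
        lazily per trial; ``attack_rate`` then serves as a fallback/label.
    handling_time:
        Time ``h`` spent per prey item (day·prey⁻¹); ≥ 0.  Sets the feeding
        rate asymptote 1/h.
    response_type:
        TYPE_II (default) or TYPE_III.
    attack_fn:
        Only for TYPE_III: maps initial prey density N0 to an effective
        attack rate.  Must be non-negative.
    """

    attack_rate: float
    handling_time: float
    response_type: ResponseType = ResponseType.TYPE_II
    attack_fn: Optional[Callable[[float], float]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.attack_rate > 0) or not math.isfinite(self.attack_rate):
            raise ValueError(f"attack_rate must be finite and > 0, got {self.attack_rate}")
        if self.handling_time < 0 or not math.isfinite(self.handling_time):
            raise ValueError(f"handling_time must be finite and >= 0, got {self.handling_time}")
        if self.response_type is ResponseType.TYPE_III and self.attack_fn is None:
            raise ValueError("TYPE_III requires attack_fn(N0)")

    def attack_at(self, n0) -> np.ndarray | float:
        """Effective attack rate for a trial starting at density ``n0``."""
        if self.response_type is ResponseType.TYPE_III:
            a = np.asarray([self.attack_fn(float(n)) for n in np.atleast_1d(n0)], dtype=float)
            if np.any(a < 0):
                raise ValueError("attack_fn returned a negative attack rate")
            return a if np.ndim(n0) else float(a[0])
        return self.attack_rate

    def to_dict(self) -> dict:
        return {
            "attack_rate": self.attack_rate,
            "handling_time": self.handling_time,
            "response_type": self.response_type.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FRParams":
        return cls(
            attack_rate=d["attack_rate"],
            handling_time=d["handling_time"],
            response_type=ResponseType(d.get("response_type", "type_ii")),
        )


@dataclass(frozen=True)
class TrialRecord:
    """One feeding trial: ``eaten`` of ``n0`` prey removed over ``duration`` days."""

    assemblage_id: str
    replicate_id: int
    n0: int
    eaten: float
    duration: float
    extras: tuple = field(default=(), compare=True)

    def __post_init__(self) -> None:
        if self.n0 < 1 or int(self.n0) != self.n0:
            raise ValueError(f"n0 must be an integer >= 1, got {self.n0}")
        if not (0 <= self.eaten <= self.n0):
            raise ValueError(f"eaten must satisfy 0 <= eaten <= n0, got eaten={self.eaten}, n0={self.n0}")
        if not (self.duration > 0):
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.replicate_id < 1 or int(self.replicate_id) != self.replicate_id:
            raise ValueError(f"replicate_id must be an integer >= 1, got {self.replicate_id}")


def holling2_rate(params: FRParams, N, n0=None):
    """Instantaneous per-capita feeding rate f(N) = aN / (1 + a h N).

    Parameters
    ----------
    params:
        Functional response parameters.
    N:
        Current prey density (scalar or array); must be >= 0.
    n0:
        Initial trial density, used only to resolve the TYPE_III attack
        rate.  Defaults to N.

    Returns
    -------
    Feeding rate in prey·day⁻¹, same shape as ``N``.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("prey density N must be >= 0")
    a = params.attack_at(N if n0 is None else n0)
    h = params.handling_time
    rate = a * N / (1.0 + a * h * N)
    return rate if rate.ndim else float(rate)


def _lambertw_exp(z: np.ndarray) -> np.ndarray:
    """Principal-branch W(e^z), stable for arbitrarily large z.

    For z <= 700 the argument e^z is representable and scipy's lambertw is
    used directly.  Beyond that, W(e^z) solves w + log w = z; Newton from
    the asymptotic start w0 = z - log z converges in a handful of steps.
    """
    z = np.asarray(z, dtype=float)
    w = np.empty_like(z)
    small = z <= 700.0
    if np.any(small):
        w[small] = lambertw(np.exp(z[small])).real
    if np.any(~small):
        zz = z[~small]
        ww = zz - np.log(zz)
        for _ in range(50):
            step = (ww + np.log(ww) - zz) / (1.0 + 1.0 / ww)
            ww -= step
            if np.all(np.abs(step) < 1e-13 * np.maximum(ww, 1.0)):
                break
        w[~small] = ww
    return w


def _rogers_fixed_point(ah, aPt, n0, max_iter: int = 100_000, tol: float = 1e-12):
    # Damped fixed-point fallback on Ne = N0 (1 - exp(-(aPt - a h Ne))).
    n0 = np.asarray(n0, dtype=float)
    ne = np.zeros_like(n0)
    for _ in range(max_iter):
        nxt = 0.5 * ne + 0.5 * n0 * (1.0 - np.exp(-(aPt - ah * ne)))
        if np.all(np.abs(nxt - ne) < tol):
            ne = nxt
            break
        ne = nxt
    return ne


def rogers_eaten(params: FRParams, n0, t, pred_density: int = 1):
    """Expected prey eaten over a trial under type-II feeding with depletion.

    Solves the random predator equation
    ``Ne = N0 (1 - exp(-a (t - h Ne)))`` for a single predator, via the
    principal branch of the Lambert W function:
    ``Ne = N0 - W(a h N0 exp(a h N0 - a t)) / (a h)``.

    ``pred_density`` identical predators are handled by the substitution
    (a, h) -> (P a, h / P), which is algebraically the integral of
    ``dN/dt = -P a N / (1 + a h N)``.

    Parameters
    ----------
    params:
        Functional response parameters (type II, or type III via attack_fn).
    n0:
        Initial prey count(s), >= 1 (scalar or array).
    t:
        Trial duration in days, > 0 (scalar or array broadcastable to n0).
    pred_density:
        Number of identical predators P >= 1.

    Returns
    -------
    Expected eaten, in [0, n0), same shape as the broadcast of n0 and t.
    """
    n0_arr = np.asarray(n0, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(n0_arr < 1):
        raise ValueError("n0 must be >= 1")
    if np.any(t_arr <= 0):
        raise ValueError("t must be > 0")
    if pred_density < 1:
        raise ValueError("pred_density must be >= 1")
    n0_b, t_b = np.broadcast_arrays(n0_arr, t_arr)
    a = np.broadcast_to(np.asarray(params.attack_at(n0_b), dtype=float), n0_b.shape)
    h = params.handling_time
    P = float(pred_density)

    if h == 0.0:
        ne = n0_b * (1.0 - np.exp(-a * P * t_b))
    else:
        z = np.log(a * h * n0_b) + a * h * n0_b - a * P * t_b
        w = _lambertw_exp(z)
        ne = n0_b - w / (a * h)
        bad = ~np.isfinite(ne)
        if np.any(bad):
            ne = np.where(bad, _rogers_fixed_point(a * h, a * P * t_b, n0_b), ne)
        if np.any(~np.isfinite(ne)):
            raise RuntimeError("random predator equation solver failed to converge")
    ne = np.clip(ne, 0.0, n0_b)
    return ne if np.ndim(n0) or np.ndim(t) else float(ne)
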