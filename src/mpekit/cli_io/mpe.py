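"""Empirical multiple-predator-effect test.

Compares observed multi-predator trials against a null model built from
single-predator trials.  Per density the verdict is

* ``independent`` — the observed 95% CI overlaps the prediction CI;
* ``risk_reduction`` — fewer prey killed than predicted (observed CI
  entirely below the prediction CI);
* ``risk_enhancement`` — more prey killed than predicted.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..fitting import bootstrap_band, fit_rogers
from ..frmodels import TrialRecord
from ..nullmodels import pair_replicates, popdyn_ci, popdyn_predict, PredatorAssemblage, AssemblageMember

__all__ = ["cmd_mpe_test"]


def _group_by_species(trials: Sequence[TrialRecord]) -> dict:
    groups = defaultdict(list)
    for tr in trials:
        groups[tr.assemblage_id].append(tr)
    return dict(groups)


def _observed_mean_ci(values: np.ndarray, rng, n_boot: int = 1000):
    """Bootstrap 95% CI of the observed replicate mean.

    Eaten counts are integers, so the mean is only known to the counting
    resolution; the interval is widened by half a prey to avoid degenerate
    zero-width CIs when replicates coincide (e.g. at full depletion).
    """
    if values.size == 1:
        lo = hi = float(values[0])
    else:
        idx = rng.integers(0, values.size, size=(n_boot, values.size))
        means = values[idx].mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
    return float(values.mean()), (float(lo) - 0.5, float(hi) + 0.5)


def _verdict(obs_ci, pred_ci) -> str:
    if obs_ci[1] < pred_ci[0]:
        return "risk_reduction"
    if obs_ci[0] > pred_ci[1]:
        return "risk_enhancement"
    return "independent"


def cmd_mpe_test(
    single_trials: Sequence[TrialRecord],
    multi_trials: Sequence[TrialRecord],
    members: Sequence[tuple],
    model: str = "pop_dyn",
    seed: Optional[int] = None,
    n_lhs: int = 1000,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Run the null-model comparison and return a per-density verdict table.

    Parameters
    ----------
    single_trials:
        Single-predator trials, one assemblage_id per predator species.
    multi_trials:
        Observed multi-predator trials (non-empty).
    members:
        The multi-predator assemblage as (species_label, density) pairs;
        labels must match single-trial assemblage ids.
    model:
        ``pop_dyn`` (LHS prediction interval) or ``direct_fr`` (bootstrap
        band on paired expected data).
    """
    multi_trials = list(multi_trials)
    if not multi_trials:
        raise ValueError("observed multi-predator table is empty")
    if model not in ("pop_dyn", "direct_fr"):
        raise ValueError(f"model must be 'pop_dyn' or 'direct_fr', got {model!r}")
    by_species = _group_by_species(single_trials)
    for label, _density in members:
        if label not in by_species:
            raise ValueError(f"no single-predator trials for declared member {label!r}")
    t_obs = {tr.duration for tr in multi_trials}
    if len(t_obs) != 1:
        raise ValueError("observed trials must share a single duration")
    t = t_obs.pop()

    obs = defaultdict(list)
    for tr in multi_trials:
        obs[tr.n0].append(tr.eaten)
    densities = np.array(sorted(obs), dtype=int)
    rng = np.random.default_rng(seed)

    rows = []
    if model == "pop_dyn":
        fits = {label: fit_rogers(by_species[label]) for label, _ in members}
        for label, fit in fits.items():
            if not fit.converged:
                raise RuntimeError(f"single-predator fit for {label!r} did not converge: {fit.message}")
        assemblage = PredatorAssemblage(
            tuple(AssemblageMember(label, density, fits[label].estimates) for label, density in members)
        )
        member_fits = [fits[label] for label, _ in members]
        member_densities = [density for _, density in members]
        ci_seeds = rng.integers(0, 2**31 - 1, size=densities.size)
        for i, n0 in enumerate(densities):
            pred = popdyn_predict(assemblage, float(n0), t)
            pred_ci, _ = popdyn_ci(member_fits, member_densities, float(n0), t, n_lhs=n_lhs, seed=int(ci_seeds[i]))
            obs_mean, obs_ci = _observed_mean_ci(np.asarray(obs[n0], dtype=float), rng, n_boot)
            rows.append((int(n0), pred, pred_ci, obs_mean, obs_ci))
    else:
        label_a, label_b = members[0][0], members[-1][0]
        trials_a = by_species[label_a]
        trials_b = by_species[label_b] if label_b != label_a else trials_a
        pair_seed = int(rng.integers(0, 2**31 - 1))
        paired = pair_replicates(trials_a, trials_b, seed=pair_seed)
        fit_null = fit_rogers(paired)
        band_null = bootstrap_band(paired, fit_null, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1)),
                                   grid=densities.astype(float))
        fit_obs = fit_rogers(multi_trials, start=fit_null.estimates if fit_null.converged else None)
        band_obs = bootstrap_band(multi_trials, fit_obs, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1)),
                                  grid=densities.astype(float))
        for i, n0 in enumerate(densities):
            pred = float(band_null.point_curve[i])
            pred_ci = (float(band_null.lower95[i]), float(band_null.upper95[i]))
            obs_mean = float(band_obs.point_curve[i])
            obs_ci = (float(band_obs.lower95[i]), float(band_obs.upper95[i]))
            rows.append((int(n0), pred, pred_ci, obs_mean, obs_ci))

    return pd.DataFrame(
        [
            {
                "n0": n0,
                "t_days": t,
                "model": model,
                "predicted": pred,
                "pred_lo": pred_ci[0],
                "pred_hi": pred_ci[1],
                "observed": obs_mean,
                "obs_lo": obs_ci[0],
                "obs_hi": obs_ci[1],
                "verdict": _verdict(obs_ci, pred_ci),
            }
            for n0, pred, pred_ci, obs_mean, obs_ci in rows
        ]
    )
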