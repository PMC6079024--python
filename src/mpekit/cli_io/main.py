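"""``mpekit`` command line: fit, predict, simulate, sweep, mpe-test."""

from __future__ import annotations

import json
import logging
import sys

import click
import numpy as np
import yaml

from .. import __version__
from ..bias_analysis import SweepConfig, run_sweep
from ..fitting import fit_rogers
from ..frmodels import FRParams
from ..nullmodels import (
    AssemblageMember,
    PredatorAssemblage,
    multiplicative_risk,
    popdyn_predict,
)
from ..simulator import NoiseSpec, simulate_deterministic, simulate_stochastic, default_density_grid
from .mpe import cmd_mpe_test
from .tables import read_trials, write_trials

logger = logging.getLogger("mpekit")


def _setup_logging(seed=None) -> None:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    logger.info("mpekit %s (seed=%s)", __version__, seed)


def _parse_members(spec: str):
    """Parse 'A:1,B:1' into [(label, density), ...]."""
    members = []
    for chunk in spec.split(","):
        label, _, density = chunk.partition(":")
        members.append((label.strip(), int(density or 1)))
    return members


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Null models and simulation for multiple predator effects."""


@cli.command()
@click.option("--trials", "trials_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--start-a", type=float, default=None, help="starting attack rate")
@click.option("--start-h", type=float, default=None, help="starting handling time")
def fit(trials_path, out_path, start_a, start_h):
    """Fit the random predator equation to single-predator trials."""
    _setup_logging()
    trials = read_trials(trials_path)
    start = FRParams(start_a, start_h) if start_a is not None and start_h is not None else None
    result = fit_rogers(trials, start=start)
    payload = {
        "attack_rate": result.estimates.attack_rate,
        "handling_time": result.estimates.handling_time,
        "log_likelihood": result.log_likelihood,
        "ci95_a": list(result.ci95_a),
        "ci95_h": list(result.ci95_h),
        "vcov": None if result.vcov is None else result.vcov.tolist(),
        "n_trials": result.n_trials,
        "converged": result.converged,
        "message": result.message,
    }
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    logger.info("fit written to %s (converged=%s)", out_path, result.converged)


@cli.command()
@click.option("--model", type=click.Choice(["mult_risk", "pop_dyn"]), required=True)
@click.option("--a", "a_values", type=float, multiple=True, required=True, help="attack rate per member")
@click.option("--h", "h_values", type=float, multiple=True, required=True, help="handling time per member")
@click.option("--n0", "n0_values", type=int, multiple=True, required=True)
@click.option("--t-days", type=float, required=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def predict(model, a_values, h_values, n0_values, t_days, out_path):
    """Predict expected eaten for an assemblage at given densities."""
    _setup_logging()
    if len(a_values) != len(h_values):
        raise click.UsageError("--a and --h must be given once per predator")
    params = [FRParams(a, h) for a, h in zip(a_values, h_values)]
    lines = ["model,n0,t_days,expected_eaten"]
    for n0 in n0_values:
        if model == "pop_dyn":
            assemblage = PredatorAssemblage(
                tuple(AssemblageMember(f"M{i+1}", 1, p) for i, p in enumerate(params))
            )
            value = popdyn_predict(assemblage, float(n0), t_days)
        else:
            from ..frmodels import rogers_eaten

            probs = [rogers_eaten(p, float(n0), t_days) / n0 for p in params[:2]]
            value = multiplicative_risk(n0, probs[0], probs[1] if len(probs) > 1 else 0.0)
        lines.append(f"{model},{n0},{t_days},{value}")
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    logger.info("predictions written to %s", out_path)


@cli.command()
@click.option("--mode", type=click.Choice(["deterministic", "stochastic"]), required=True)
@click.option("--a", "a_values", type=float, multiple=True, required=True)
@click.option("--h", "h_values", type=float, multiple=True, required=True)
@click.option("--t-days", type=float, default=1.0, show_default=True)
@click.option("--n-replicates", type=int, default=10, show_default=True)
@click.option("--seed", type=int, default=None, help="required for stochastic mode")
@click.option("--out", "out_path", required=True, type=click.Path())
def simulate(mode, a_values, h_values, t_days, n_replicates, seed, out_path):
    """Generate simulated trials (plus a YAML metadata sidecar)."""
    _setup_logging(seed)
    if len(a_values) != len(h_values):
        raise click.UsageError("--a and --h must be given once per predator")
    grid = default_density_grid()
    if mode == "deterministic":
        if len(a_values) != 1:
            raise click.UsageError("deterministic mode simulates a single predator")
        ds = simulate_deterministic(FRParams(a_values[0], h_values[0]), grid=grid, t=t_days)
    else:
        if seed is None:
            raise click.UsageError("stochastic simulation requires --seed")
        members = tuple(
            AssemblageMember(f"M{i+1}", 1, FRParams(a, h))
            for i, (a, h) in enumerate(zip(a_values, h_values))
        )
        ds = simulate_stochastic(
            PredatorAssemblage(members), grid=grid, t=t_days,
            noise=NoiseSpec(), n_replicates=n_replicates, seed=seed,
        )
    write_trials(ds.trials, out_path)
    sidecar = {
        "params": {k: p.to_dict() for k, p in ds.params.items()},
        "grid": [int(n) for n in ds.grid],
        "n_replicates": ds.n_replicates,
        "seed": ds.seed,
        "metadata": ds.metadata,
    }
    with open(str(out_path) + ".meta.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(sidecar, fh)
    logger.info("%d trials written to %s", len(ds.trials), out_path)


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML with SweepConfig fields")
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_path", required=True, type=click.Path())
def sweep(config_path, seed, out_path):
    """Run the prediction-vs-simulation bias sweep."""
    overrides = {}
    if config_path:
        with open(config_path, encoding="utf-8") as fh:
            overrides = yaml.safe_load(fh) or {}
    if seed is not None:
        overrides["seed"] = seed
    if "noise" in overrides and isinstance(overrides["noise"], dict):
        overrides["noise"] = NoiseSpec(**overrides["noise"])
    for key in ("durations_h", "h_grid", "a_grid", "modes", "varied", "density_grid"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    config = SweepConfig(**overrides)
    if config.seed is None:
        raise click.UsageError("sweep requires a seed (--seed or config)")
    _setup_logging(config.seed)
    table = run_sweep(config)
    table.to_csv(out_path, index=False)
    logger.info("%d rows written to %s (%d grid-point failures)",
                len(table), out_path, len(table.attrs.get("failures", [])))


@cli.command("mpe-test")
@click.option("--single", "single_path", required=True, type=click.Path(exists=True))
@click.option("--multi", "multi_path", required=True, type=click.Path(exists=True))
@click.option("--members", required=True, help="assemblage as label:density pairs, e.g. 'A:1,B:1'")
@click.option("--model", type=click.Choice(["pop_dyn", "direct_fr"]), default="pop_dyn", show_default=True)
@click.option("--seed", type=int, required=True)
@click.option("--n-lhs", type=int, default=1000, show_default=True)
@click.option("--n-boot", type=int, default=1000, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def mpe_test(single_path, multi_path, members, model, seed, n_lhs, n_boot, out_path):
    """Test observed multi-predator trials against a null model."""
    _setup_logging(seed)
    single = read_trials(single_path)
    multi = read_trials(multi_path)
    table = cmd_mpe_test(
        single, multi, _parse_members(members), model=model, seed=seed, n_lhs=n_lhs, n_boot=n_boot
    )
    table.to_csv(out_path, index=False)
    counts = table["verdict"].value_counts().to_dict()
    logger.info("verdicts: %s -> %s", counts, out_path)


if __name__ == "__main__":
    cli()
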