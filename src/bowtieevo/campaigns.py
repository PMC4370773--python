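"""Experiment orchestration: seeded multi-run campaigns and parameter sweeps.

A campaign runs ``repeats`` independent simulations of one experiment
(identical parameters, per-run random streams seeded ``seed_base + index``),
filters the converged runs and aggregates their bow-tie statistics.  A sweep
varies one evolutionary parameter axis at a time around a base campaign and
tabulates the mean and spread of the evolved waist width per grid cell.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .analysis import EnsembleSummary, summarize_ensemble
from .evolution import EvolutionConfig, MutationConfig, RunRecord, run_ensemble
from .goals import GoalMatrix, GoalSpec, add_fixed_noise, make_goal
from .retina import retina_active_nodes, run_retina_ensemble

__all__ = [
    "CampaignSpec",
    "SweepSpec",
    "run_campaign",
    "run_sweep",
    "record_to_dict",
    "record_from_dict",
    "save_records",
    "load_records",
]

log = logging.getLogger("bowtieevo")


@dataclass(frozen=True)
class CampaignSpec:
    """One batch of repeated simulations of a single experiment."""

    name: str
    evolution: EvolutionConfig
    goal_spec: GoalSpec | None = None
    retina: bool = False
    n_layers: int = 4
    repeats: int = 1
    seed_base: int = 0
    noise: Literal["none", "fixed_goal", "temporal"] = "none"
    noise_param: float = 0.0
    activity_threshold: float | None = None  # default: 1e-3 linear, 1e-4 retina

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")
        if not self.retina and self.goal_spec is None:
            raise ValueError("a linear campaign needs a goal_spec")


def _noise_seed(run_seed: int) -> int:
    # separate stream from the run's own seed so goal noise and evolutionary
    # randomness are independent
    return int(np.random.SeedSequence((run_seed, 0xB0)).generate_state(1)[0] % 2**31)


def run_campaign(
    spec: CampaignSpec, return_records: bool = False, outdir: str | Path | None = None
):
    """Execute all repeats and aggregate the converged runs.

    Returns the :class:`~bowtieevo.analysis.EnsembleSummary` (and the per-run
    records if requested).  Deterministic given the spec: run ``i`` uses seed
    ``seed_base + i`` and results do not depend on execution order.
    """
    seeds = [spec.seed_base + i for i in range(spec.repeats)]
    if spec.retina:
        cfg = spec.evolution
        records = run_retina_ensemble(cfg, seeds=seeds)
        threshold = spec.activity_threshold or 1e-4
        summary = summarize_ensemble(
            records,
            threshold=threshold,
            activity_fn=lambda net, thr: retina_active_nodes(net, threshold=thr),
        )
    else:
        clean = make_goal(spec.goal_spec)
        cfg = spec.evolution
        if spec.noise == "fixed_goal":
            goals = [
                add_fixed_noise(clean, spec.noise_param, _noise_seed(s)) for s in seeds
            ]
        else:
            goals = [clean] * len(seeds)
            if spec.noise == "temporal":
                cfg = replace(
                    cfg, temporal_noise_sigma=spec.noise_param, early_stop=False
                )
        records = run_ensemble(cfg, goals, spec.n_layers, seeds=seeds)
        threshold = spec.activity_threshold or 1e-3
        summary = summarize_ensemble(
            records, threshold=threshold, converged_only=spec.noise != "temporal"
        )
    log.info(
        "campaign %s: %d/%d converged, median waist %.1f (goal rank %d)",
        spec.name,
        summary.n_converged,
        summary.n_total,
        summary.median_waist,
        summary.goal_rank,
    )
    if outdir is not None:
        _persist(spec, records, summary, Path(outdir))
    if return_records:
        return summary, records
    return summary


@dataclass(frozen=True)
class SweepSpec:
    """One-axis-at-a-time parameter grid around a base campaign."""

    population_sizes: tuple[int, ...] = ()
    mutation_sizes: tuple[float, ...] = ()
    mutation_rates: tuple[float, ...] = ()  # absolute per-element rates
    tournament_sizes: tuple[int, ...] = ()
    repeats: int = 50

    def __post_init__(self) -> None:
        if not (
            self.population_sizes
            or self.mutation_sizes
            or self.mutation_rates
            or self.tournament_sizes
        ):
            raise ValueError("sweep needs at least one non-empty axis")


def _with_param(cfg: EvolutionConfig, axis: str, value) -> EvolutionConfig:
    if axis == "population_size":
        return replace(cfg, population_size=int(value))
    if axis == "mutation_size":
        return replace(cfg, mutation=replace(cfg.mutation, size=float(value)))
    if axis == "mutation_rate":
        return replace(cfg, mutation=replace(cfg.mutation, per_element_rate=float(value)))
    if axis == "tournament_size":
        return replace(cfg, tournament_size=int(value))
    raise ValueError(f"unknown sweep axis {axis!r}")


def run_sweep(sweep: SweepSpec, base: CampaignSpec) -> pd.DataFrame:
    """Run one campaign per grid cell; tabulate mean +/- std waist width."""
    axes = {
        "population_size": sweep.population_sizes,
        "mutation_size": sweep.mutation_sizes,
        "mutation_rate": sweep.mutation_rates,
        "tournament_size": sweep.tournament_sizes,
    }
    rows = []
    for axis, values in axes.items():
        for v in values:
            cell = replace(
                base,
                name=f"{base.name}/{axis}={v}",
                evolution=_with_param(base.evolution, axis, v),
                repeats=sweep.repeats,
            )
            summary = run_campaign(cell)
            rows.append(
                {
                    "parameter": axis,
                    "value": v,
                    "mean_waist": float(np.mean(summary.waist_widths)),
                    "std_waist": float(np.std(summary.waist_widths)),
                    "n_converged": summary.n_converged,
                    "n_total": summary.n_total,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence


def record_to_dict(rec) -> dict:
    cfg = dataclasses.asdict(rec.config)
    cfg["init_range"] = list(cfg["init_range"])
    d = {
        "seed": rec.seed,
        "generations_run": rec.generations_run,
        "converged": rec.converged,
        "config": cfg,
        "mean_fitness": np.asarray(rec.mean_fitness).tolist(),
        "best_fitness": np.asarray(rec.best_fitness).tolist(),
        "final_fitness": np.asarray(rec.final_fitness).tolist(),
    }
    if isinstance(rec, RunRecord):
        d["kind"] = "linear"
        d["final_population"] = np.asarray(rec.final_population).tolist()
        d["goal"] = {
            "values": rec.goal.values.tolist(),
            "declared_rank": rec.goal.declared_rank,
            "noise_level": rec.goal.noise_level,
        }
        d["initial_mean_fitness"] = rec.initial_mean_fitness
        d["initial_best_fitness"] = rec.initial_best_fitness
    else:
        d["kind"] = "retina"
        d["final_weights"] = np.asarray(rec.final_weights).tolist()
        d["final_thresholds"] = np.asarray(rec.final_thresholds).tolist()
    return d


def record_from_dict(d: dict):
    from .retina import RetinaRunRecord

    cfg = dict(d["config"])
    cfg["mutation"] = MutationConfig(**cfg["mutation"])
    cfg["init_range"] = tuple(cfg["init_range"])
    config = EvolutionConfig(**cfg)
    common = dict(
        mean_fitness=np.asarray(d["mean_fitness"]),
        best_fitness=np.asarray(d["best_fitness"]),
        final_fitness=np.asarray(d["final_fitness"]),
        generations_run=d["generations_run"],
        converged=d["converged"],
        config=config,
        seed=d["seed"],
    )
    if d["kind"] == "linear":
        goal = GoalMatrix(
            values=np.asarray(d["goal"]["values"]),
            declared_rank=d["goal"]["declared_rank"],
            noise_level=d["goal"]["noise_level"],
        )
        return RunRecord(
            final_population=np.asarray(d["final_population"]),
            goal=goal,
            initial_mean_fitness=d["initial_mean_fitness"],
            initial_best_fitness=d["initial_best_fitness"],
            **common,
        )
    return RetinaRunRecord(
        final_weights=np.asarray(d["final_weights"]),
        final_thresholds=np.asarray(d["final_thresholds"]),
        **common,
    )


def save_records(records: Sequence, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        path = outdir / f"run_{rec.seed}.json"
        path.write_text(json.dumps(record_to_dict(rec)))


def load_records(outdir: str | Path) -> list:
    outdir = Path(outdir)
    return [
        record_from_dict(json.loads(p.read_text()))
        for p in sorted(outdir.glob("run_*.json"))
    ]


def summary_to_frame(summary: EnsembleSummary) -> pd.DataFrame:
    """One row per converged run per layer: long-format active-count table."""
    rows = []
    for run_idx, act in enumerate(summary.activities):
        for layer, count in enumerate(act.active_counts, start=1):
            rows.append(
                {
                    "run": run_idx,
                    "layer": layer,
                    "active_nodes": count,
                    "waist_width": act.waist_width,
                    "waist_layer": act.waist_layer_index,
                }
            )
    return pd.DataFrame(rows)


def _persist(spec, records, summary, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    save_records(records, outdir / "runs")
    summary_to_frame(summary).to_csv(outdir / "layer_activity.csv", index=False)
    agg = {
        "name": spec.name,
        "goal_rank": summary.goal_rank,
        "n_converged": summary.n_converged,
        "n_total": summary.n_total,
        "median_waist": summary.median_waist,
        "fraction_waist_equals_rank": summary.fraction_waist_equals_rank,
        "fraction_waist_above_rank": summary.fraction_waist_above_rank,
        "layer_medians": summary.layer_medians.tolist(),
        "waist_widths": summary.waist_widths.tolist(),
    }
    (outdir / "summary.json").write_text(json.dumps(agg, indent=1))
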