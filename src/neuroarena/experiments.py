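"""Trial metrics and batch experiment runners.

Learning accuracy follows the open-field convention: the trajectory is cut
into 3-s intervals and each interval scores the fraction of logged poses
lying outside every bumper zone.  Batch experiments replicate the study's
three behavioural conditions (plus an explicit CS-only probe condition)
at desk scale — 10-20 seeded 60-s simulated trials per condition — and
summarize per-trial success, collision counts and path lengths with mean,
SD and a t-based 95% confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point

from . import arena_sim, associative_net as anet

__all__ = [
    "AccuracySeries",
    "ExperimentSummary",
    "learning_accuracy",
    "trial_metrics",
    "trials_to_criterion",
    "run_experiment",
    "EXPERIMENT_NAMES",
]

EXPERIMENT_NAMES = ("baseline", "learning", "post_learning", "probe")


@dataclass
class AccuracySeries:
    """Per-interval learning accuracy (fraction of non-bumper trajectory
    points per interval of ``interval_s`` seconds)."""

    interval_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not (
            np.all(self.values >= 0.0) and np.all(self.values <= 1.0)
        ):
            raise ValueError("accuracy values must lie in [0, 1]")

    @property
    def final(self) -> float:
        return float(self.values[-1])


def learning_accuracy(
    result: arena_sim.TrialResult,
    arena: arena_sim.ArenaConfig,
    interval_s: float = 3.0,
) -> AccuracySeries:
    """Accuracy per whole interval: non-bumper poses / total poses.

    A pose counts as a bumper point when it lies inside (or on) a zone
    polygon.  Every logged pose belongs to exactly one interval; a
    trailing partial interval is dropped.
    """
    if result.n_steps == 0:
        raise ValueError("empty trajectory")
    per_interval = int(round(interval_s / result.dt_motion))
    n_int = result.n_steps // per_interval
    if n_int == 0:
        raise ValueError("trial shorter than one accuracy interval")
    inside = np.array(
        [
            any(z.covers(Point(x, y)) for z in arena.bumper_zones)
            for x, y in result.poses[: n_int * per_interval, :2]
        ]
    )
    vals = 1.0 - inside.reshape(n_int, per_interval).mean(axis=1)
    return AccuracySeries(interval_s=interval_s, values=vals)


def trial_metrics(result: arena_sim.TrialResult) -> dict:
    """Per-trial record: success (collision-free), debounced collision
    count, path length."""
    collisions = len(result.collision_events)
    return {
        "seed": result.seed,
        "success": collisions == 0,
        "collisions": collisions,
        "path_length_m": result.path_length(),
        "wall_contacts": len(result.wall_contacts),
    }


def trials_to_criterion(
    batch: Sequence[arena_sim.TrialResult | dict | int],
) -> int | None:
    """Smallest n such that trials n-1 and n (1-based) are both
    bumper-free; None (flagged absent) if never achieved.

    Accepts TrialResults, trial_metrics dicts, or raw collision counts.
    """
    counts = []
    for item in batch:
        if isinstance(item, arena_sim.TrialResult):
            counts.append(len(item.collision_events))
        elif isinstance(item, dict):
            counts.append(int(item["collisions"]))
        else:
            counts.append(int(item))
    for n in range(1, len(counts)):
        if counts[n - 1] == 0 and counts[n] == 0:
            return n + 1
    return None


def _agg(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    else:
        half = 0.0
    return {"mean": mean, "sd": sd, "ci95": (mean - half, mean + half)}


@dataclass
class ExperimentSummary:
    """Aggregated batch results for one experimental condition."""

    name: str
    trials: pd.DataFrame
    aggregates: dict
    results: list = field(default_factory=list, repr=False)

    @property
    def success_rate(self) -> float:
        """Percent of collision-free trials."""
        return 100.0 * float(self.trials["success"].mean())

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "n_trials": int(len(self.trials)),
            "success_rate_pct": self.success_rate,
            "aggregates": {
                k: {
                    "mean": v["mean"],
                    "sd": v["sd"],
                    "ci95": list(v["ci95"]),
                }
                for k, v in self.aggregates.items()
            },
        }


def run_experiment(
    name: str,
    n_trials: int = 10,
    seeds: Sequence[int] | None = None,
    arena: arena_sim.ArenaConfig | None = None,
    net_cfg: anet.NetworkConfig | None = None,
    duration: float = 60.0,
    trained_state: anet.NetworkState | None = None,
    n_pairings: int = 15,
) -> ExperimentSummary:
    """Run one behavioural condition as a seeded trial batch.

    baseline      : fresh network, learning disabled (reflex-only).
    learning      : fresh network, in-arena CS+US pairing enabled.
    post_learning : weights frozen after desk conditioning; US live.
    probe         : frozen weights, the whole US channel disabled.

    ``trained_state`` lets post_learning/probe reuse one conditioned
    network; otherwise conditioning is run from ``net_cfg.seed``.
    """
    if name not in EXPERIMENT_NAMES:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {EXPERIMENT_NAMES}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    arena = arena if arena is not None else arena_sim.ArenaConfig()
    net_cfg = net_cfg if net_cfg is not None else anet.NetworkConfig()
    if seeds is None:
        seeds = list(range(1, n_trials + 1))
    if len(seeds) != n_trials:
        raise ValueError("need one seed per trial")

    if name in ("post_learning", "probe"):
        if trained_state is None:
            trained_state, _ = anet.condition_network(
                net_cfg, n_pairings=n_pairings
            )
        base_state = trained_state
        learning_on = False
        us_enabled = name == "post_learning"
    else:
        base_state = None
        learning_on = name == "learning"
        us_enabled = True

    records, results = [], []
    for seed in seeds:
        state = (
            base_state.copy()
            if base_state is not None
            else anet.build_network(
                anet.NetworkConfig(**{**net_cfg.__dict__, "seed": seed})
            )
        )
        res = arena_sim.run_trial(
            arena, state, net_cfg, duration=duration,
            learning_on=learning_on, us_enabled=us_enabled, seed=seed,
        )
        res.phase = name
        rec = trial_metrics(res)
        rec["final_accuracy"] = learning_accuracy(res, arena).final
        rec["final_mean_w_cs"] = float(res.w_cs_trace[-1].mean())
        records.append(rec)
        results.append(res)

    trials = pd.DataFrame(records)
    aggregates = {
        key: _agg(trials[key].to_numpy(dtype=float))
        for key in ("collisions", "path_length_m", "final_accuracy",
                    "final_mean_w_cs")
    }
    aggregates["success"] = _agg(trials["success"].to_numpy(dtype=float))
    return ExperimentSummary(
        name=name, trials=trials, aggregates=aggregates, results=results
    )
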