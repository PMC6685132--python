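"""Scoring screener output against ground truth.

Confusion counts are defined over the *structurally-screened* universe:
the patients present in the dashboard state who passed a trial's
structured filter. The screener never text-scores structurally excluded
patients, so true negatives (and hence specificity-style quantities) are
relative to that post-filter universe — stated explicitly because it
changes their interpretation.

Micro-averaged metrics pool the confusion counts over all (patient,
trial) recommendation decisions before computing precision/recall/F; the
macro alternative (average of per-trial F) is deliberately not reported.
``workload_reduction = 1 - recommended/screened`` summarizes how much of
the post-filter review burden the text matcher removes.

Time-cutoff recall — recall measured in the dashboard state at an early
cutoff time — quantifies the effect of documentation delay: a candidate
whose qualifying note has not yet arrived cannot be recommended, however
eligible they are.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace as dc_replace
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

import pandas as pd

from .service import DashboardState
from .synth import GeneratorConfig, GroundTruth


@dataclass(frozen=True)
class Confusion:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "Confusion") -> "Confusion":
        return Confusion(self.tp + other.tp, self.fp + other.fp,
                         self.fn + other.fn, self.tn + other.tn)


@dataclass
class ScreeningMetrics:
    per_trial: dict  # trial_id -> Confusion
    micro: Confusion
    workload_reduction: float  # 1 - recommended/screened, in [0, 1]

    def to_dict(self) -> dict:
        def fmt(c: Confusion) -> dict:
            return {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                    "precision": c.precision, "recall": c.recall, "f1": c.f1}

        return {
            "per_trial": {t: fmt(c) for t, c in sorted(self.per_trial.items())},
            "micro": fmt(self.micro),
            "workload_reduction": self.workload_reduction,
        }


def score_run(state: DashboardState, truth: GroundTruth) -> ScreeningMetrics:
    """Score one dashboard state against ground truth.

    A recommended candidate is a true positive iff the truth marks that
    patient eligible for that trial. Every patient in the state must be
    covered by the truth.
    """
    per_trial: dict = {}
    total_screened = 0
    total_recommended = 0
    for trial_id in sorted(state.candidates):
        universe = state.screened.get(trial_id, [])
        for pid in universe:
            if pid not in truth.labels:
                raise KeyError(f"patient {pid!r} in state but missing from ground truth")
        recommended = {c.patient_id for c in state.candidates[trial_id]}
        eligible = {pid for pid in universe if truth.labels[pid].get(trial_id, False)}
        universe_set = set(universe)
        tp = len(recommended & eligible)
        fp = len(recommended - eligible)
        fn = len(eligible - recommended)
        tn = len(universe_set - recommended - eligible)
        per_trial[trial_id] = Confusion(tp=tp, fp=fp, fn=fn, tn=tn)
        total_screened += len(universe_set)
        total_recommended += len(recommended)

    micro = sum(per_trial.values(), Confusion())
    workload = 1.0 - total_recommended / total_screened if total_screened else 0.0
    return ScreeningMetrics(per_trial=per_trial, micro=micro, workload_reduction=workload)


def state_at(states: Sequence[DashboardState], cutoff: datetime) -> Optional[DashboardState]:
    """The last state whose as_of is at or before the cutoff."""
    chosen = None
    for state in states:
        if state.as_of is not None and state.as_of <= cutoff:
            chosen = state
    return chosen


def time_cutoff_recall(states: Sequence[DashboardState], truth: GroundTruth,
                       cutoff: datetime) -> float:
    """Micro recall of the dashboard as it stood at an early cutoff time."""
    state = state_at(states, cutoff)
    if state is None:
        return 0.0
    return score_run(state, truth).micro.recall


def noise_sweep(grid: Mapping[str, Sequence],
                seeds: Sequence[int],
                trials=None,
                lexicon=None,
                base_config: Optional[GeneratorConfig] = None,
                screen_config=None,
                cutoff_minutes: Optional[float] = None) -> pd.DataFrame:
    """Run generate -> screen -> score over a parameter grid.

    ``grid`` maps GeneratorConfig field names (e.g. ``negation_rate``,
    ``delay_mean_minutes``, ``prevalence``) to value lists. Returns a
    long-format DataFrame with one row per (cell, seed) carrying micro
    precision/recall/F, workload reduction and (when ``cutoff_minutes`` is
    given) time-cutoff recall.
    """
    from . import service, synth

    lexicon = lexicon or synth.fixture_lexicon()
    trials = trials if trials is not None else synth.fixture_trials(lexicon)
    base_config = base_config or GeneratorConfig()

    rows = []
    names = list(grid)
    for values in itertools.product(*(grid[n] for n in names)):
        cell = dict(zip(names, values))
        for seed in seeds:
            config = dc_replace(base_config, seed=seed, **cell)
            snapshots, truth = synth.generate(config, trials, lexicon)
            states, _ = service.run_stream(snapshots, trials, lexicon, config=screen_config)
            m = score_run(states[-1], truth)
            row = {**cell, "seed": seed,
                   "micro_precision": m.micro.precision,
                   "micro_recall": m.micro.recall,
                   "micro_f": m.micro.f1,
                   "workload_reduction": m.workload_reduction}
            if cutoff_minutes is not None:
                cutoff = config.start_time + timedelta(minutes=cutoff_minutes)
                row["cutoff_recall"] = time_cutoff_recall(states, truth, cutoff)
            rows.append(row)
    return pd.DataFrame(rows)


def sweep_summary(sweep: pd.DataFrame, cell_columns: Sequence[str]) -> pd.DataFrame:
    """Per-cell mean and standard deviation over seeds, long format."""
    metric_columns = [c for c in sweep.columns if c not in (*cell_columns, "seed")]
    grouped = sweep.groupby(list(cell_columns))[metric_columns].agg(["mean", "std"])
    grouped.columns = [f"{metric}_{stat}" for metric, stat in grouped.columns]
    return grouped.reset_index()
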