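"""Continuous screening over a snapshot stream with periodic refresh.

The service walks a visit-snapshot stream on a simulated clock, refreshing
a per-trial dashboard at fixed intervals (default 600 s, matching a
10-minute dashboard cadence). Each refresh:

* folds in the snapshots that became visible since the last tick (a
  snapshot is the complete current view of its patient, so the latest one
  per patient wins);
* re-extracts a patient's concept bag only when their notes changed
  (cached by note count + latest note time — the batch-equivalence
  invariant in the test suite guards this optimization);
* drops discharged patients;
* re-applies the structured filter and the matcher for every active trial.

Event-time simulation keeps runs deterministic and fast: the cadence is
honored on the data's own timeline, and a patient's candidacy can change
only at refresh boundaries. Trials with ``active=False`` are skipped
entirely (hidden from the dashboard).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from . import filters, matching, nlp
from .model import ConceptBag, Lexicon, PatientSnapshot, TrialDefinition

logger = logging.getLogger(__name__)

DEFAULT_INTERVAL_SECONDS = 600  # 10-minute dashboard refresh


@dataclass
class ScreenConfig:
    interval_seconds: int = DEFAULT_INTERVAL_SECONDS
    threshold: float = matching.DEFAULT_THRESHOLD
    policy: str = "lenient"  # unknown-handling for the structured filter
    binary: bool = False  # presence instead of counts in the matcher

    def __post_init__(self) -> None:
        if self.interval_seconds <= 0:
            raise ValueError("interval_seconds must be positive")


@dataclass
class _CacheEntry:
    snapshot: PatientSnapshot
    note_key: tuple  # (number of notes, latest note_time or None)
    bag: ConceptBag


def _note_key(snapshot: PatientSnapshot) -> tuple:
    times = [n.note_time for n in snapshot.notes]
    return (len(times), max(times) if times else None)


@dataclass
class DashboardState:
    """One dashboard refresh: ranked candidates per trial as of a tick.

    ``screened`` records, per trial, the structurally-passing patients
    (the universe over which text matching ran); ``candidates`` the ranked
    recommendations. Discharged patients appear in neither.
    """

    as_of: Optional[datetime]
    candidates: dict = field(default_factory=dict)  # trial_id -> [RankedCandidate]
    screened: dict = field(default_factory=dict)  # trial_id -> [patient_id]
    cache: dict = field(default_factory=dict)  # patient_id -> _CacheEntry

    @classmethod
    def empty(cls, as_of: Optional[datetime] = None) -> "DashboardState":
        return cls(as_of=as_of)

    def to_dict(self) -> dict:
        return {
            "as_of": self.as_of.isoformat() if self.as_of else None,
            "trials": {
                trial_id: {
                    "screened": sorted(self.screened.get(trial_id, [])),
                    "candidates": [c.to_dict() for c in cands],
                }
                for trial_id, cands in self.candidates.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, data: dict) -> "DashboardState":
        """Rebuild a (cache-less) state from its serialized form."""
        state = cls(as_of=datetime.fromisoformat(data["as_of"]) if data.get("as_of") else None)
        for trial_id, payload in data.get("trials", {}).items():
            state.screened[trial_id] = list(payload.get("screened", []))
            state.candidates[trial_id] = [
                matching.RankedCandidate(
                    patient_id=c["patient_id"], trial_id=c["trial_id"],
                    score=float(c["score"]),
                    matched_inclusion_terms=[(t, float(w))
                                             for t, w in c.get("matched_inclusion_terms", [])],
                    matched_exclusion_terms=list(c.get("matched_exclusion_terms", [])),
                    rank=int(c["rank"]),
                )
                for c in payload.get("candidates", [])
            ]
        return state


def refresh(state: DashboardState,
            new_snapshots: Sequence[PatientSnapshot],
            trials: Sequence[TrialDefinition],
            lexicon: Lexicon,
            rules=None,
            config: Optional[ScreenConfig] = None) -> DashboardState:
    """Advance the dashboard by one interval, folding in new snapshots."""
    config = config or ScreenConfig()
    if rules is None:
        rules = nlp.default_rules()

    cache = dict(state.cache)
    for snapshot in new_snapshots:
        if snapshot.discharged:
            cache.pop(snapshot.patient_id, None)
            continue
        previous = cache.get(snapshot.patient_id)
        key = _note_key(snapshot)
        if previous is not None and previous.note_key == key:
            bag = previous.bag  # notes unchanged: reuse the extracted bag
        else:
            text = "\n".join(n.text for n in snapshot.notes)
            bag = nlp.extract_concepts(text, lexicon, rules)
        cache[snapshot.patient_id] = _CacheEntry(snapshot=snapshot, note_key=key, bag=bag)

    as_of = (state.as_of + timedelta(seconds=config.interval_seconds)
             if state.as_of is not None else None)
    new_state = DashboardState(as_of=as_of, cache=cache)
    ordered = [cache[pid] for pid in sorted(cache)]
    for trial in trials:
        if not trial.active:
            continue
        screened = [
            entry for entry in ordered
            if filters.apply_structured(entry.snapshot, trial, config.policy).passed
        ]
        scored = [
            (entry.snapshot, *matching.score_patient(entry.bag, trial, binary=config.binary))
            for entry in screened
        ]
        new_state.screened[trial.trial_id] = [e.snapshot.patient_id for e in screened]
        new_state.candidates[trial.trial_id] = matching.rank_candidates(
            trial, scored, threshold=config.threshold
        )
    return new_state


def run_stream(snapshots: Sequence[PatientSnapshot],
               trials: Sequence[TrialDefinition],
               lexicon: Lexicon,
               rules=None,
               config: Optional[ScreenConfig] = None) -> tuple:
    """Screen a whole stream on the interval grid; returns (states, audit).

    The simulated clock starts at the first snapshot_time and steps by the
    refresh interval until every snapshot is visible, producing one
    DashboardState per tick. ``audit`` is a list of plain-text lines, one
    per recommendation per tick.
    """
    config = config or ScreenConfig()
    snapshots = sorted(snapshots, key=lambda s: (s.snapshot_time, s.patient_id))
    audit: list = []
    if not snapshots:
        logger.warning("empty snapshot stream: producing a single empty state")
        return [DashboardState.empty()], audit

    t0 = snapshots[0].snapshot_time
    t_end = snapshots[-1].snapshot_time
    interval = timedelta(seconds=config.interval_seconds)
    n_ticks = 1
    while t0 + (n_ticks - 1) * interval < t_end:
        n_ticks += 1

    states: list = []
    state = DashboardState.empty(as_of=t0 - interval)
    idx = 0
    for k in range(n_ticks):
        tick = t0 + k * interval
        due = []
        while idx < len(snapshots) and snapshots[idx].snapshot_time <= tick:
            due.append(snapshots[idx])
            idx += 1
        state = refresh(state, due, trials, lexicon, rules, config)
        states.append(state)
        for trial_id in sorted(state.candidates):
            for c in state.candidates[trial_id]:
                audit.append(
                    f"{tick.isoformat()} trial={trial_id} rank={c.rank} "
                    f"patient={c.patient_id} score={c.score:.4f}"
                )
    return states, audit


def summarize(states: Sequence[DashboardState]) -> dict:
    """Per-trial recommended / screened counts in the final state."""
    if not states:
        return {}
    final = states[-1]
    return {
        trial_id: {
            "recommended": len(final.candidates.get(trial_id, [])),
            "screened": len(final.screened.get(trial_id, [])),
        }
        for trial_id in sorted(final.candidates)
    }


def write_states(states: Sequence[DashboardState], out_dir: Union[str, Path]) -> list:
    """Serialize each state to a timestamped JSON file; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, state in enumerate(states):
        stamp = state.as_of.strftime("%Y%m%dT%H%M%S") if state.as_of else f"{i:04d}"
        path = out_dir / f"state_{i:04d}_{stamp}.json"
        path.write_text(state.to_json() + "\n", encoding="utf-8")
        paths.append(path)
    return paths
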