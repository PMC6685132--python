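"""Active-learning refinement of trial criteria from coordinator feedback.

After coordinators confirm or decline recommended candidates, their
eligible / not-eligible decisions partition the reviewed patients' concept
bags into two document sets. For every rendered term we form the 2x2
presence table

    a = eligible bags containing the term      b = eligible bags lacking it
    c = ineligible bags containing the term    d = ineligible bags lacking it

and score it with the Haldane–Anscombe-corrected log odds ratio

    score = ln[ (a+0.5)(d+0.5) / ((b+0.5)(c+0.5)) ].

A positive score marks a term associated with eligibility. The top-k terms
above a minimum score that are not already authored criteria are folded
into the trial as *learned terms* with weights normalized to the best
score; they participate in future matching but never touch the authored
bags, and each update replaces the previous learned set (so the learned
set never exceeds k). The canonical behavior this reproduces: a trial
whose inclusion names "head injury" learns the co-occurring finding
"skull fractures" (C0037304) from the records of patients coordinators
deemed eligible.

The default gate min_score=2.0 corresponds to an odds ratio of about 7.4 —
a term must be strongly class-associated before it can steer matching.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

from .model import ConceptBag, FeedbackRecord, TrialDefinition, LearnedTerm, read_feedback

DEFAULT_K = 5
DEFAULT_MIN_SCORE = 2.0


@dataclass(frozen=True)
class TermStatistic:
    """Presence counts of one rendered term across feedback classes."""

    term: str
    a: int  # eligible bags containing the term
    b: int  # eligible bags lacking it
    c: int  # ineligible bags containing it
    d: int  # ineligible bags lacking it
    score: float


def informativeness(a: int, b: int, c: int, d: int) -> float:
    """Smoothed log odds of term presence given eligibility.

    Requires at least one feedback record in each class; the 0.5 correction
    keeps the score finite for zero cells.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b < 1 or c + d < 1:
        raise ValueError("need at least one feedback record per class")
    return math.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))


def term_statistics(eligible_bags: Sequence[ConceptBag],
                    ineligible_bags: Sequence[ConceptBag]) -> list:
    """Per-term presence statistics over the two feedback classes, scored.

    Returned sorted by score descending, ties broken lexicographically.
    """
    if not eligible_bags or not ineligible_bags:
        raise ValueError("need at least one feedback record per class")
    n_e, n_i = len(eligible_bags), len(ineligible_bags)
    terms = sorted({t for bag in eligible_bags for t in bag}
                   | {t for bag in ineligible_bags for t in bag})
    stats = []
    for term in terms:
        a = sum(1 for bag in eligible_bags if term in bag)
        c = sum(1 for bag in ineligible_bags if term in bag)
        b, d = n_e - a, n_i - c
        stats.append(TermStatistic(term=term, a=a, b=b, c=c, d=d,
                                   score=informativeness(a, b, c, d)))
    stats.sort(key=lambda s: (-s.score, s.term))
    return stats


class FeedbackStore:
    """Append-only store of coordinator decisions, latest-per-pair wins.

    Duplicate (patient_id, trial_id) submissions keep the record with the
    latest decision_time. Feedback for inactive trials is accepted (it may
    arrive after deactivation); feedback for a trial the store has never
    heard of is an error.
    """

    def __init__(self, known_trials: Iterable[str]):
        self.known_trials = set(known_trials)
        self._records: Dict[tuple, FeedbackRecord] = {}

    def __len__(self) -> int:
        return len(self._records)

    def ingest(self, record: FeedbackRecord) -> "FeedbackStore":
        if record.trial_id not in self.known_trials:
            raise KeyError(f"feedback for unknown trial {record.trial_id!r}")
        key = (record.patient_id, record.trial_id)
        existing = self._records.get(key)
        if existing is None or record.decision_time >= existing.decision_time:
            self._records[key] = record
        return self

    def records(self) -> list:
        return sorted(self._records.values(),
                      key=lambda r: (r.decision_time, r.patient_id, r.trial_id))

    def for_trial(self, trial_id: str) -> list:
        return [r for r in self.records() if r.trial_id == trial_id]

    def save(self, path: Union[str, Path]) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for r in self.records():
                fh.write(json.dumps(r.model_dump(mode="json"), sort_keys=True,
                                    separators=(",", ":")) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path], known_trials: Iterable[str]) -> "FeedbackStore":
        store = cls(known_trials)
        for record in read_feedback(path):
            store.ingest(record)
        return store


def update_criteria(trial: TrialDefinition,
                    feedback: Sequence[FeedbackRecord],
                    patient_bags: Mapping[str, ConceptBag],
                    k: int = DEFAULT_K,
                    min_score: float = DEFAULT_MIN_SCORE) -> TrialDefinition:
    """Fold the top informative terms from feedback into a trial.

    Pure: returns a new TrialDefinition; the input trial and its authored
    bags are untouched. ``learned_terms`` is replaced by at most ``k``
    terms with score >= min_score that are not already authored criteria,
    weighted by score normalized to the maximum selected score. With
    ``k=0`` the trial is returned unchanged (modulo a defensive copy).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    new_trial = trial.model_copy(deep=True)
    if k == 0:
        return new_trial

    relevant = [r for r in feedback if r.trial_id == trial.trial_id]
    eligible_bags, ineligible_bags = [], []
    for record in relevant:
        if record.patient_id not in patient_bags:
            raise KeyError(f"feedback references unknown patient {record.patient_id!r}")
        bag = patient_bags[record.patient_id]
        (eligible_bags if record.decision == "eligible" else ineligible_bags).append(bag)

    stats = term_statistics(eligible_bags, ineligible_bags)
    authored = set(trial.inclusion_bag) | set(trial.exclusion_bag)
    selected = [s for s in stats if s.score >= min_score and s.term not in authored][:k]
    if selected:
        max_score = selected[0].score
        stamp = max(r.decision_time for r in relevant).date().isoformat()
        new_trial.learned_terms = [
            LearnedTerm(term=s.term, weight=s.score / max_score,
                        provenance=f"learned:{stamp}")
            for s in selected
        ]
    else:
        new_trial.learned_terms = []
    return new_trial
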