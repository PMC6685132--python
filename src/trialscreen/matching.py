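"""Bag-of-phrases patient-trial matching and ranking.

The matcher scores a patient's concept bag against a trial's weighted
inclusion bag with cosine similarity over rendered (assertion-qualified)
terms: ``score = <counts, weights> / (||counts|| * ||weights||)``. Terms
match only in identical rendered form — ``NEG_C0032285`` never matches an
inclusion term ``C0032285``; the conversion to prefixed terms happens
upstream precisely so that matching operates on the converted forms.

Exclusion semantics are a hard override: any exclusion-bag term whose own
assertion is AFFIRMED and which appears (affirmed) in the patient bag
forces the score to 0 and disqualifies the candidate. A *negated* mention
of an exclusion finding is not disqualifying.

Learned terms (from the active learner) join the inclusion vector at their
learned weights. Scoring is isolated behind :func:`score_patient` so that
alternative IR weightings (BM25, overlap) could be swapped in; a binary
mode (presence instead of counts) is available via ``binary=True``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import Assertion, ConceptBag, ConceptTerm, PatientSnapshot, TrialDefinition

DEFAULT_THRESHOLD = 0.2


@dataclass
class MatchEvidence:
    """Why a score is what it is: matched terms and their contributions."""

    matched_inclusion_terms: list = field(default_factory=list)  # (term, weight*count)
    matched_exclusion_terms: list = field(default_factory=list)


@dataclass
class RankedCandidate:
    patient_id: str
    trial_id: str
    score: float  # in [0, 1]
    matched_inclusion_terms: list
    matched_exclusion_terms: list
    rank: int  # 1-based, consecutive

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "patient_id": self.patient_id,
            "trial_id": self.trial_id,
            "score": round(self.score, 6),
            "matched_inclusion_terms": [[t, round(c, 6)] for t, c in self.matched_inclusion_terms],
            "matched_exclusion_terms": list(self.matched_exclusion_terms),
        }


def score_patient(patient_bag: ConceptBag, trial: TrialDefinition,
                  binary: bool = False) -> tuple:
    """Weighted cosine similarity of a patient bag against a trial.

    Returns ``(score, MatchEvidence)``. Empty bags on either side score 0.
    """
    counts = {t: (1.0 if binary else float(c)) for t, c in patient_bag.items()}
    weights = trial.inclusion_vector()

    excluded = sorted(
        t for t in trial.exclusion_bag
        if ConceptTerm.parse(t).assertion is Assertion.AFFIRMED and t in counts
    )
    if excluded:
        return 0.0, MatchEvidence(matched_inclusion_terms=[], matched_exclusion_terms=excluded)

    shared = set(counts) & set(weights)
    dot = sum(counts[t] * weights[t] for t in shared)
    if dot <= 0.0:
        return 0.0, MatchEvidence()
    norm_p = math.sqrt(sum(c * c for c in counts.values()))
    norm_t = math.sqrt(sum(w * w for w in weights.values()))
    score = dot / (norm_p * norm_t)
    matched = sorted(((t, counts[t] * weights[t]) for t in shared),
                     key=lambda item: (-item[1], item[0]))
    return min(score, 1.0), MatchEvidence(matched_inclusion_terms=matched)


def rank_candidates(trial: TrialDefinition,
                    scored: Iterable[tuple],
                    threshold: float = DEFAULT_THRESHOLD) -> list:
    """Turn ``(patient, score, evidence)`` triples into a ranked dashboard list.

    Admission rule: exclusion-overridden patients never appear. For trials
    with text criteria a candidate needs ``score >= threshold`` and a
    strictly positive score (a zero-overlap patient is not a match even at
    threshold 0). Structured-only trials (empty inclusion vector) admit
    every structurally-passing patient at score 0 — there is no text
    requirement left to satisfy.

    Ordering: score descending; ties broken by earlier arrival_time, then
    lexicographic patient_id. Ranks are 1-based and consecutive.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    has_text = trial.has_text_criteria
    admitted = []
    for patient, score, evidence in scored:
        if evidence.matched_exclusion_terms:
            continue
        if has_text and (score < threshold or score <= 0.0):
            continue
        admitted.append((patient, score, evidence))
    admitted.sort(key=lambda item: (-item[1], item[0].arrival_time, item[0].patient_id))
    return [
        RankedCandidate(
            patient_id=patient.patient_id,
            trial_id=trial.trial_id,
            score=score,
            matched_inclusion_terms=list(evidence.matched_inclusion_terms),
            matched_exclusion_terms=list(evidence.matched_exclusion_terms),
            rank=i,
        )
        for i, (patient, score, evidence) in enumerate(admitted, start=1)
    ]


def write_candidates_csv(candidates: Sequence[RankedCandidate], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "patient_id", "trial_id", "score", "evidence"])
        for c in candidates:
            evidence = ";".join(t for t, _ in c.matched_inclusion_terms)
            writer.writerow([c.rank, c.patient_id, c.trial_id, f"{c.score:.6f}", evidence])


def write_candidates_json(candidates: Sequence[RankedCandidate], path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps([c.to_dict() for c in candidates], indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
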