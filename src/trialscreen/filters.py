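"""Structured-entry eligibility filtering.

Patients whose structured EHR fields fail a trial's structured constraints
are excluded before any text matching. Each constraint evaluates to
``pass``, ``fail`` or ``unknown`` (the patient's value is missing), and a
verdict aggregates them under one of two unknown-handling policies:

* ``lenient`` (default): unknowns pass through for human review — the
  screener is a recommender with coordinator confirmation, so a false
  exclusion is the costlier error;
* ``strict``: a pass requires every constraint evaluable and passing.

Conventions: numeric intervals are closed below, open above ([lo, hi));
set constraints test membership; a required code set passes iff the
patient's codes intersect it; a forbidden code set passes iff disjoint.
Vitals are the most recent measurement at snapshot time (the snapshot's
``vitals`` map holds current values). ``sex == "U"`` and ``race``/
``language == "unknown"`` count as unknown for their constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .model import (
    CodeSetConstraint,
    Interval,
    PatientSnapshot,
    StructuredEntries,
    TrialDefinition,
)

ConstraintResult = Literal["pass", "fail", "unknown"]
Policy = Literal["lenient", "strict"]


@dataclass
class FilterVerdict:
    """Aggregated structured-filter outcome for one patient-trial pair."""

    passed: bool
    failed_fields: list = field(default_factory=list)
    unevaluable_fields: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "failed_fields": list(self.failed_fields),
            "unevaluable_fields": list(self.unevaluable_fields),
        }


def _patient_value(field_name: str, structured: StructuredEntries):
    """The patient's value for a constraint field, None when unknown."""
    if field_name.startswith("vitals."):
        return structured.vitals.get(field_name.split(".", 1)[1])
    if field_name == "sex":
        return None if structured.sex == "U" else structured.sex
    if field_name in ("race", "language"):
        value = getattr(structured, field_name)
        return None if value == "unknown" else value
    return getattr(structured, field_name)


def check_constraint(field_name: str, patient_value, constraint_spec) -> ConstraintResult:
    """Evaluate one constraint against one patient value."""
    if isinstance(constraint_spec, Interval):
        if patient_value is None:
            return "unknown"
        return "pass" if constraint_spec.contains(float(patient_value)) else "fail"
    if isinstance(constraint_spec, CodeSetConstraint):
        codes = set(patient_value or ())  # an empty code set is known, not unknown
        if constraint_spec.required and not codes & set(constraint_spec.required):
            return "fail"
        if constraint_spec.forbidden and codes & set(constraint_spec.forbidden):
            return "fail"
        return "pass"
    if isinstance(constraint_spec, bool):  # guardian_present
        if patient_value is None:
            return "unknown"
        return "pass" if bool(patient_value) == constraint_spec else "fail"
    if isinstance(constraint_spec, (list, tuple, set, frozenset)):
        if patient_value is None:
            return "unknown"
        return "pass" if patient_value in constraint_spec else "fail"
    raise TypeError(f"malformed constraint spec for {field_name!r}: {constraint_spec!r}")


def apply_structured(patient: PatientSnapshot, trial: TrialDefinition,
                     policy: Policy = "lenient") -> FilterVerdict:
    """Evaluate every structured constraint of an active trial.

    The verdict is order-independent: fields are reported in the schema's
    canonical order regardless of evaluation order.
    """
    if policy not in ("lenient", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    failed: list = []
    unevaluable: list = []
    for field_name, spec in trial.structured_constraints.items():
        result = check_constraint(field_name, _patient_value(field_name, patient.structured), spec)
        if result == "fail":
            failed.append(field_name)
        elif result == "unknown":
            unevaluable.append(field_name)
    passed = not failed and (policy == "lenient" or not unevaluable)
    return FilterVerdict(passed=passed, failed_fields=failed, unevaluable_fields=unevaluable)
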