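"""Domain model and file formats for trial-eligibility screening.

The unit of text matching throughout the package is the *rendered concept
term*: a concept identifier qualified by an assertion status. Affirmed
mentions render as the bare identifier (``C0032285``); negated, historical
and family (non-patient experiencer) mentions render with a prefix
(``NEG_C0032285``, ``HIST_C0032285``, ``FAM_C0032285``). A patient note or a
trial criterion text reduces to a :data:`ConceptBag`, a multiset of rendered
terms.

File formats handled here:

* lexicon — TSV, UTF-8, header ``phrase\\tconcept_id\\tcategory``;
* patient snapshots — JSON Lines, one visit snapshot per line;
* trial definitions — YAML (JSON is a YAML subset and is accepted), keys
  ``trial_id, active, structured_constraints, inclusion_text,
  exclusion_text, term_weights, learned_terms``;
* feedback — JSON Lines of coordinator eligibility decisions.

Timestamps are ISO-8601 and treated as timezone-naive.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence, Union

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

logger = logging.getLogger(__name__)

LEXICON_CATEGORIES = {"symptom", "disease", "medication", "procedure", "finding", "other"}


class FormatError(ValueError):
    """Raised for malformed input files (lexicon, trial, rules)."""


# ---------------------------------------------------------------------------
# Concept terms and bags
# ---------------------------------------------------------------------------


class Assertion(str, Enum):
    """Assertion status of a concept mention.

    AFFIRMED is the default; NEG marks negated mentions, HIST temporal-past
    mentions, FAM mentions attributed to someone other than the patient.
    """

    AFFIRMED = "AFFIRMED"
    NEG = "NEG"
    HIST = "HIST"
    FAM = "FAM"


_ASSERTION_PREFIXES = tuple(f"{a.value}_" for a in (Assertion.NEG, Assertion.HIST, Assertion.FAM))


@dataclass(frozen=True, order=True)
class ConceptTerm:
    """An assertion-qualified concept identifier.

    Rendering is bijective: ``ConceptTerm.parse(t.render()) == t`` for every
    valid term. To keep the bijection, a concept_id may not itself start
    with an assertion prefix.
    """

    concept_id: str
    assertion: Assertion = Assertion.AFFIRMED

    def __post_init__(self) -> None:
        if not self.concept_id or any(ch.isspace() for ch in self.concept_id):
            raise ValueError(f"invalid concept_id: {self.concept_id!r}")
        if self.concept_id.startswith(_ASSERTION_PREFIXES):
            raise ValueError(
                f"concept_id {self.concept_id!r} collides with an assertion prefix"
            )

    def render(self) -> str:
        if self.assertion is Assertion.AFFIRMED:
            return self.concept_id
        return f"{self.assertion.value}_{self.concept_id}"

    @classmethod
    def parse(cls, rendered: str) -> "ConceptTerm":
        for assertion in (Assertion.NEG, Assertion.HIST, Assertion.FAM):
            prefix = f"{assertion.value}_"
            if rendered.startswith(prefix):
                return cls(rendered[len(prefix):], assertion)
        return cls(rendered, Assertion.AFFIRMED)


#: Multiset of rendered concept terms: rendered term -> positive count.
ConceptBag = dict


def bag_is_valid(bag: ConceptBag) -> bool:
    return all(isinstance(c, int) and c >= 1 for c in bag.values())


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LexiconEntry:
    phrase: str  # lower-cased surface phrase, >= 1 token
    concept_id: str
    category: str


class Lexicon:
    """A concept lexicon indexed by the first token of each phrase.

    One phrase may map to several concept identifiers; exact duplicate
    (phrase, concept_id) pairs collapse to one entry.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        seen: dict = {}
        for e in entries:
            key = (e.phrase, e.concept_id)
            if key not in seen:
                seen[key] = e
        self.entries: tuple = tuple(seen.values())
        if not self.entries:
            raise FormatError("lexicon contains no entries")
        self._by_first_token: dict = {}
        self._by_phrase: dict = {}
        self._by_concept: dict = {}
        for e in self.entries:
            first = e.phrase.split()[0]
            self._by_first_token.setdefault(first, []).append(e)
            self._by_phrase.setdefault(e.phrase, set()).add(e.concept_id)
            self._by_concept.setdefault(e.concept_id, []).append(e.phrase)
        # longest phrases first so greedy matching can scan in order
        for lst in self._by_first_token.values():
            lst.sort(key=lambda e: (-len(e.phrase.split()), e.phrase, e.concept_id))

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, phrase: str) -> set:
        """Concept ids mapped to an exact (lower-cased) phrase."""
        return set(self._by_phrase.get(phrase.lower().strip(), set()))

    def starting_with(self, token: str) -> Sequence[LexiconEntry]:
        """Entries whose phrase starts with *token*, longest phrase first."""
        return self._by_first_token.get(token, ())

    def concept_ids(self) -> set:
        return set(self._by_concept)

    def phrases_for(self, concept_id: str) -> list:
        return sorted(self._by_concept.get(concept_id, []))


def load_lexicon(path: Union[str, Path]) -> Lexicon:
    """Load a 3-column TSV lexicon (header: phrase, concept_id, category)."""
    path = Path(path)
    entries = []
    with path.open(encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty lexicon file")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise FormatError(
                f"{path}: line {lineno}: expected 3 tab-separated columns, got {len(cols)}"
            )
        phrase, concept_id, category = (c.strip() for c in cols)
        phrase = phrase.lower()
        if not phrase:
            raise FormatError(f"{path}: line {lineno}: empty phrase")
        if category not in LEXICON_CATEGORIES:
            raise FormatError(f"{path}: line {lineno}: unknown category {category!r}")
        entries.append(LexiconEntry(phrase=phrase, concept_id=concept_id, category=category))
    if not entries:
        raise FormatError(f"{path}: no lexicon rows after header")
    return Lexicon(entries)


def write_lexicon(lexicon: Lexicon, path: Union[str, Path]) -> None:
    path = Path(path)
    rows = sorted(lexicon.entries, key=lambda e: (e.phrase, e.concept_id))
    with path.open("w", encoding="utf-8") as fh:
        fh.write("phrase\tconcept_id\tcategory\n")
        for e in rows:
            fh.write(f"{e.phrase}\t{e.concept_id}\t{e.category}\n")


# ---------------------------------------------------------------------------
# Patients
# ---------------------------------------------------------------------------


class StructuredEntries(BaseModel):
    """Structured EHR fields for one visit snapshot.

    Unknown values are explicit: ``sex="U"``, ``guardian_present=None``,
    ``acuity=None``, a vital missing from ``vitals``, ``race``/``language``
    equal to ``"unknown"``. They are never imputed, so downstream filters
    can distinguish "fails a constraint" from "cannot evaluate".
    """

    model_config = ConfigDict(extra="forbid")

    age: float = Field(ge=0)  # years, fractional allowed
    sex: Literal["M", "F", "U"] = "U"
    race: str = "unknown"
    language: str = "unknown"
    guardian_present: Optional[bool] = None
    acuity: Optional[int] = Field(default=None, ge=1, le=5)
    vitals: dict = Field(default_factory=dict)  # name -> value (C, bpm, /min, %)
    medication_codes: list = Field(default_factory=list)
    procedure_codes: list = Field(default_factory=list)

    @field_validator("vitals")
    @classmethod
    def _finite_vitals(cls, v: dict) -> dict:
        for name, value in v.items():
            value = float(value)
            if not math.isfinite(value):
                raise ValueError(f"vital {name!r} is not finite")
            v[name] = value
        return v

    @field_validator("medication_codes", "procedure_codes")
    @classmethod
    def _sorted_codes(cls, v: list) -> list:
        return sorted(set(str(c) for c in v))


class Note(BaseModel):
    model_config = ConfigDict(extra="forbid")

    note_time: datetime
    note_type: str = "note"
    text: str = ""


class PatientSnapshot(BaseModel):
    """Structured entries plus clinical notes for one visit at one time.

    A snapshot is the complete current view of the patient: ``notes``
    contains every note filed so far. Notes may carry a ``note_time``
    earlier than ``snapshot_time`` but never later (documentation delay
    moves a note's *availability*, not its timestamp, forward).
    """

    model_config = ConfigDict(extra="forbid")

    patient_id: str
    arrival_time: datetime
    snapshot_time: datetime
    discharged: bool = False
    structured: StructuredEntries
    notes: list = Field(default_factory=list)

    @field_validator("notes")
    @classmethod
    def _coerce_notes(cls, v: list) -> list:
        return [n if isinstance(n, Note) else Note.model_validate(n) for n in v]

    @model_validator(mode="after")
    def _check_times(self) -> "PatientSnapshot":
        if self.snapshot_time < self.arrival_time:
            raise ValueError("snapshot_time precedes arrival_time")
        for n in self.notes:
            if n.note_time > self.snapshot_time:
                raise ValueError("note_time after snapshot_time")
        return self


def snapshot_to_json(snapshot: PatientSnapshot) -> str:
    """Canonical single-line JSON rendering (stable key order, compact)."""
    return json.dumps(snapshot.model_dump(mode="json"), sort_keys=True, separators=(",", ":"))


def read_snapshots(path: Union[str, Path]) -> list:
    """Read a JSON Lines snapshot stream, sorted ascending by snapshot_time.

    Invalid records (bad JSON, invariant violations) are skipped with a
    warning naming the line number; they never abort the read.
    """
    path = Path(path)
    snapshots = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                snapshots.append(PatientSnapshot.model_validate(json.loads(line)))
            except (json.JSONDecodeError, ValidationError, ValueError) as exc:
                logger.warning("%s: line %d: skipping invalid snapshot (%s)", path, lineno, exc)
    snapshots.sort(key=lambda s: s.snapshot_time)  # stable: preserves file order on ties
    return snapshots


def write_snapshots(snapshots: Iterable[PatientSnapshot], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in snapshots:
            fh.write(snapshot_to_json(s) + "\n")


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------


class Interval(BaseModel):
    """Numeric constraint interval, closed below and open above: [min, max)."""

    model_config = ConfigDict(extra="forbid")

    min: Optional[float] = None
    max: Optional[float] = None

    def contains(self, value: float) -> bool:
        if self.min is not None and value < self.min:
            return False
        if self.max is not None and value >= self.max:
            return False
        return True


class CodeSetConstraint(BaseModel):
    """Order-code constraint: required passes iff the patient's code set
    intersects ``required`` (when non-empty); forbidden passes iff it is
    disjoint from ``forbidden``."""

    model_config = ConfigDict(extra="forbid")

    required: list = Field(default_factory=list)
    forbidden: list = Field(default_factory=list)


class StructuredConstraints(BaseModel):
    """Per-field bounds on StructuredEntries; any unknown key is an error."""

    model_config = ConfigDict(extra="forbid")

    age: Optional[Interval] = None
    sex: Optional[list] = None
    race: Optional[list] = None
    language: Optional[list] = None
    guardian_present: Optional[bool] = None
    acuity: Optional[list] = None
    vitals: dict = Field(default_factory=dict)  # vital name -> Interval
    medication_codes: Optional[CodeSetConstraint] = None
    procedure_codes: Optional[CodeSetConstraint] = None

    @field_validator("vitals")
    @classmethod
    def _coerce_vitals(cls, v: dict) -> dict:
        return {
            name: iv if isinstance(iv, Interval) else Interval.model_validate(iv)
            for name, iv in v.items()
        }

    def items(self) -> Iterator:
        """Yield (constraint name, spec) for every defined constraint."""
        for name in ("age", "sex", "race", "language", "guardian_present",
                     "acuity", "medication_codes", "procedure_codes"):
            spec = getattr(self, name)
            if spec is not None:
                yield name, spec
        for vital, interval in sorted(self.vitals.items()):
            yield f"vitals.{vital}", interval


class LearnedTerm(BaseModel):
    """A criteria term added by the active learner, never by a trial author.

    ``provenance`` distinguishes learned terms (``learned:<date>``) from
    authored ones and is mandatory."""

    model_config = ConfigDict(extra="forbid")

    term: str
    weight: float = Field(ge=0)
    provenance: str

    @field_validator("provenance")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("learned term requires provenance")
        return v


class TrialDefinition(BaseModel):
    """Structured constraints plus weighted inclusion/exclusion term bags."""

    model_config = ConfigDict(extra="forbid")

    trial_id: str
    active: bool = True
    structured_constraints: StructuredConstraints = Field(default_factory=StructuredConstraints)
    inclusion_text: str = ""
    exclusion_text: str = ""
    inclusion_bag: dict = Field(default_factory=dict)  # rendered term -> weight >= 0
    exclusion_bag: dict = Field(default_factory=dict)
    learned_terms: list = Field(default_factory=list)

    @field_validator("inclusion_bag", "exclusion_bag")
    @classmethod
    def _valid_weights(cls, v: dict) -> dict:
        for term, w in v.items():
            ConceptTerm.parse(term)  # raises on malformed rendered terms
            if float(w) < 0:
                raise ValueError(f"negative weight for term {term!r}")
            v[term] = float(w)
        return v

    @field_validator("learned_terms")
    @classmethod
    def _coerce_learned(cls, v: list) -> list:
        return [t if isinstance(t, LearnedTerm) else LearnedTerm.model_validate(t) for t in v]

    @model_validator(mode="after")
    def _disjoint_bags(self) -> "TrialDefinition":
        overlap = set(self.inclusion_bag) & set(self.exclusion_bag)
        if overlap:
            raise ValueError(
                f"term {sorted(overlap)[0]!r} appears in both inclusion and exclusion bags"
            )
        return self

    def inclusion_vector(self) -> dict:
        """Authored inclusion weights merged with learned-term weights."""
        vec = dict(self.inclusion_bag)
        for lt in self.learned_terms:
            vec[lt.term] = lt.weight
        return vec

    @property
    def has_text_criteria(self) -> bool:
        return bool(self.inclusion_bag) or bool(self.learned_terms)


_TRIAL_KEYS = {"trial_id", "active", "structured_constraints", "inclusion_text",
               "exclusion_text", "term_weights", "learned_terms"}


def trial_from_mapping(data: dict, lexicon: Optional[Lexicon] = None,
                       rules=None) -> TrialDefinition:
    """Build a TrialDefinition from a parsed trial mapping.

    Free-text criteria are run through the NLP pipeline (when a lexicon is
    supplied) to produce the term bags, each extracted term at weight 1.0;
    ``term_weights`` may override the weight of an extracted term.
    """
    from . import nlp  # local import: nlp depends on model-level types

    unknown = set(data) - _TRIAL_KEYS
    if unknown:
        raise FormatError(f"unknown trial key(s): {sorted(unknown)}")
    if "trial_id" not in data:
        raise FormatError("trial file missing trial_id")

    inclusion_text = data.get("inclusion_text") or ""
    exclusion_text = data.get("exclusion_text") or ""
    inclusion_bag: dict = {}
    exclusion_bag: dict = {}
    if lexicon is not None:
        inclusion_bag = {t: 1.0 for t in nlp.extract_concepts(inclusion_text, lexicon, rules)}
        exclusion_bag = {t: 1.0 for t in nlp.extract_concepts(exclusion_text, lexicon, rules)}
    for term, weight in (data.get("term_weights") or {}).items():
        if term in inclusion_bag:
            inclusion_bag[term] = float(weight)
        elif term in exclusion_bag:
            exclusion_bag[term] = float(weight)
        else:
            raise FormatError(f"term_weights names {term!r}, not extracted from criteria text")
    try:
        return TrialDefinition(
            trial_id=str(data["trial_id"]),
            active=bool(data.get("active", True)),
            structured_constraints=StructuredConstraints.model_validate(
                data.get("structured_constraints") or {}
            ),
            inclusion_text=inclusion_text,
            exclusion_text=exclusion_text,
            inclusion_bag=inclusion_bag,
            exclusion_bag=exclusion_bag,
            learned_terms=data.get("learned_terms") or [],
        )
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def load_trial(path: Union[str, Path], lexicon: Optional[Lexicon] = None,
               rules=None) -> TrialDefinition:
    """Load one trial YAML/JSON file; see :func:`trial_from_mapping`."""
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise FormatError(f"{path}: trial file must contain a mapping")
    try:
        return trial_from_mapping(data, lexicon, rules)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def load_trials(directory: Union[str, Path], lexicon: Optional[Lexicon] = None,
                rules=None) -> list:
    """Load every ``*.yaml``/``*.yml``/``*.json`` trial in a directory, sorted by filename."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix in {".yaml", ".yml", ".json"})
    return [load_trial(p, lexicon, rules) for p in paths]


def save_trial(trial: TrialDefinition, path: Union[str, Path]) -> None:
    """Write a trial back to YAML; bags persist via term_weights + learned_terms."""
    data = {
        "trial_id": trial.trial_id,
        "active": trial.active,
        "structured_constraints": trial.structured_constraints.model_dump(
            mode="json", exclude_none=True
        ),
        "inclusion_text": trial.inclusion_text,
        "exclusion_text": trial.exclusion_text,
        "term_weights": {**trial.inclusion_bag, **trial.exclusion_bag},
        "learned_terms": [lt.model_dump(mode="json") for lt in trial.learned_terms],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


# ---------------------------------------------------------------------------
# Feedback
# ---------------------------------------------------------------------------


class FeedbackRecord(BaseModel):
    """A coordinator's eligibility decision for one patient-trial pair.

    ``reason_text`` is expected (but not required) when the decision is
    not_eligible; coordinators document why a recommendation was declined.
    """

    model_config = ConfigDict(extra="forbid")

    patient_id: str
    trial_id: str
    decision: Literal["eligible", "not_eligible"]
    reason_text: str = ""
    decision_time: datetime


def read_feedback(path: Union[str, Path]) -> list:
    path = Path(path)
    records = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(FeedbackRecord.model_validate(json.loads(line)))
            except (json.JSONDecodeError, ValidationError) as exc:
                logger.warning("%s: line %d: skipping invalid feedback (%s)", path, lineno, exc)
    return records


def write_feedback(records: Iterable[FeedbackRecord], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.model_dump(mode="json"), sort_keys=True,
                                separators=(",", ":")) + "\n")
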