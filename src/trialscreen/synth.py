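"""Seeded synthetic emergency-department visit streams with ground truth.

The generator emulates, at desk scale, the stream a pediatric ED feeds a
screening service: per patient one arrival snapshot (structured entries
only) and one clinical-note snapshot whose availability lags arrival by a
geometric documentation delay. Note text is template-based — slot-filled
sentences exercising every NLP rule (affirmed, negated, historical and
family mentions; duplicated sentences; distractor concepts) — rather than
free generation, which is sufficient to drive the pipeline
deterministically.

Each patient is designated eligible for at most one trial (categorical
draw over per-trial prevalences); designation forces the structured
entries to satisfy that trial's constraints and injects every inclusion
concept as an affirmed sentence. A configurable fraction of designated
patients instead *violate* the trial by also carrying an affirmed
exclusion concept. Ground-truth labels are then recomputed post hoc for
ALL trials from the injected evidence plus a strict structured check, so
accidental cross-trial eligibility is labeled correctly and the invariant

    eligible  <=>  structured pass (strict) AND every inclusion concept
                   affirmed AND no exclusion concept affirmed

holds by construction. All randomness flows from the single seed through
one numpy Generator; the per-patient draw sequence has fixed length, so
runs with the same seed but different noise/delay settings stay paired
draw-for-draw (and geometric delays, sampled by inverse CDF, are monotone
in the mean for a fixed seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np

from . import filters, nlp
from .model import (
    Assertion,
    ConceptTerm,
    Lexicon,
    LexiconEntry,
    Note,
    PatientSnapshot,
    StructuredEntries,
    TrialDefinition,
    trial_from_mapping,
    write_lexicon,
    write_snapshots,
    save_trial,
)

# ---------------------------------------------------------------------------
# Fixture lexicon, rules and trials
# ---------------------------------------------------------------------------

#: (phrase, concept_id, category). Concept ids use a reserved C9xxxxxx range
#: except two well-known CUIs kept for recognizability: pneumonia C0032285
#: and skull fractures C0037304. "cold" deliberately maps to two concepts.
FIXTURE_LEXICON_ROWS = [
    ("pneumonia", "C0032285", "disease"),
    ("skull fractures", "C0037304", "finding"),
    ("skull fracture", "C0037304", "finding"),
    ("fever", "C9000001", "symptom"),
    ("cough", "C9000002", "symptom"),
    ("asthma", "C9000003", "disease"),
    ("wheezing", "C9000004", "symptom"),
    ("vomiting", "C9000005", "symptom"),
    ("nausea", "C9000006", "symptom"),
    ("testicular pain", "C9000007", "symptom"),
    ("scrotal swelling", "C9000008", "finding"),
    ("head injury", "C9000010", "finding"),
    ("headache", "C9000012", "symptom"),
    ("lethargy", "C9000013", "symptom"),
    ("poor perfusion", "C9000014", "finding"),
    ("irritability", "C9000015", "symptom"),
    ("seizure", "C9000016", "disease"),
    ("seizure disorder", "C9000017", "disease"),
    ("dehydration", "C9000018", "finding"),
    ("diarrhea", "C9000019", "symptom"),
    ("rash", "C9000020", "finding"),
    ("sore throat", "C9000021", "symptom"),
    ("ear pain", "C9000022", "symptom"),
    ("runny nose", "C9000023", "symptom"),
    ("congestion", "C9000024", "symptom"),
    ("shortness of breath", "C9000025", "symptom"),
    ("chest pain", "C9000026", "symptom"),
    ("abdominal pain", "C9000027", "symptom"),
    ("bronchiolitis", "C9000028", "disease"),
    ("croup", "C9000029", "disease"),
    ("urinary tract infection", "C9000030", "disease"),
    ("otitis media", "C9000031", "disease"),
    ("fracture", "C9000032", "finding"),
    ("arm fracture", "C9000033", "finding"),
    ("concussion", "C9000034", "finding"),
    ("loss of consciousness", "C9000035", "finding"),
    ("dizziness", "C9000036", "symptom"),
    ("migraine", "C9000037", "disease"),
    ("diabetes", "C9000038", "disease"),
    ("sickle cell disease", "C9000039", "disease"),
    ("amoxicillin", "C9000040", "medication"),
    ("albuterol", "C9000041", "medication"),
    ("appendicitis", "C9000042", "disease"),
    ("cold", "C9000045", "disease"),
    ("cold", "C9000046", "finding"),
]


def fixture_lexicon() -> Lexicon:
    return Lexicon(LexiconEntry(phrase=p, concept_id=c, category=cat)
                   for p, c, cat in FIXTURE_LEXICON_ROWS)


def fixture_trial_mappings() -> list:
    """Six toy trials mirroring the *types* seen in a pediatric ED portfolio:
    a demographics-only trial, a multi-condition respiratory trial with an
    exclusion, a head-trauma trial (whose criteria the active learner can
    supplement with "skull fractures"), a guardian-gated multi-condition
    trial, a sex-restricted trial, and a vitals/order-code trial.
    Inclusion concept sets are pairwise disjoint across trials.
    """
    return [
        {
            "trial_id": "teen-survey",
            "active": True,
            "structured_constraints": {"age": {"min": 12, "max": 18}},
            "inclusion_text": "",
            "exclusion_text": "",
        },
        {
            "trial_id": "resp-infection",
            "active": True,
            "structured_constraints": {
                "age": {"min": 0.25, "max": 18},
                "acuity": [2, 3, 4],
            },
            "inclusion_text": "Fever. Cough. Pneumonia.",
            "exclusion_text": "Asthma.",
        },
        {
            "trial_id": "head-trauma",
            "active": True,
            "structured_constraints": {
                "age": {"min": 2, "max": 18},
                "acuity": [1, 2, 3],
            },
            "inclusion_text": "Head injury.",
            "exclusion_text": "Seizure disorder.",
        },
        {
            "trial_id": "family-asthma",
            "active": True,
            "structured_constraints": {
                "age": {"min": 1, "max": 18},
                "guardian_present": True,
            },
            "inclusion_text": "Asthma. Wheezing.",
            "exclusion_text": "",
        },
        {
            "trial_id": "torsion",
            "active": True,
            "structured_constraints": {
                "age": {"min": 4, "max": 18},
                "sex": ["M"],
            },
            "inclusion_text": "Testicular pain. Scrotal swelling.",
            "exclusion_text": "",
        },
        {
            "trial_id": "sepsis-biomarker",
            "active": True,
            "structured_constraints": {
                "age": {"min": 0, "max": 5},
                "vitals": {"temperature": {"min": 38.0, "max": 43.0}},
                "procedure_codes": {"required": ["PR100"]},
            },
            "inclusion_text": "Lethargy. Poor perfusion.",
            "exclusion_text": "Sickle cell disease.",
        },
    ]


def fixture_trials(lexicon: Optional[Lexicon] = None, rules=None) -> list:
    lexicon = lexicon or fixture_lexicon()
    return [trial_from_mapping(m, lexicon, rules) for m in fixture_trial_mappings()]


# ---------------------------------------------------------------------------
# Generator configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic stream.

    Rates are per patient: ``negation_rate`` etc. give the probability of
    injecting one extra mention of that kind into the patient's note;
    ``distractor_rate`` injects an affirmed non-criterion concept;
    ``exclusion_violation_rate`` is the probability that a designated
    patient also carries an affirmed exclusion concept (making them truth
    -ineligible). ``delay_mean_minutes`` is the mean of the geometric
    documentation delay between arrival and note availability.
    """

    n_patients: int = 200
    seed: int = 0
    prevalence: Union[float, Dict[str, float]] = 0.08  # per-trial eligibility
    negation_rate: float = 0.30
    history_rate: float = 0.15
    family_rate: float = 0.10
    duplicate_rate: float = 0.20
    distractor_rate: float = 0.50
    exclusion_violation_rate: float = 0.10
    delay_mean_minutes: float = 20.0
    window_minutes: float = 120.0
    start_time: datetime = field(default_factory=lambda: datetime(2024, 3, 1, 8, 0, 0))

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        rates = [self.negation_rate, self.history_rate, self.family_rate,
                 self.duplicate_rate, self.distractor_rate, self.exclusion_violation_rate]
        if isinstance(self.prevalence, dict):
            rates.extend(self.prevalence.values())
        else:
            rates.append(self.prevalence)
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")

    def prevalence_for(self, trials: Sequence[TrialDefinition]) -> list:
        if isinstance(self.prevalence, dict):
            ps = [float(self.prevalence.get(t.trial_id, 0.0)) for t in trials]
        else:
            ps = [float(self.prevalence)] * len(trials)
        if sum(ps) > 1.0:
            raise ValueError("per-trial prevalences sum above 1; overlapping designation "
                             "is not supported")
        return ps


@dataclass
class GroundTruth:
    """Per patient-trial eligibility labels plus the injected evidence."""

    labels: dict  # patient_id -> {trial_id: bool}
    evidence: dict  # patient_id -> [{concept_id, assertion, source, delay_minutes}]

    def to_json(self) -> str:
        return json.dumps({"labels": self.labels, "evidence": self.evidence},
                          sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        return cls(labels=data["labels"], evidence=data["evidence"])

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "GroundTruth":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------


def _affirmed_concept_ids(bag: Mapping[str, float]) -> list:
    ids = []
    for term in bag:
        parsed = ConceptTerm.parse(term)
        if parsed.assertion is not Assertion.AFFIRMED:
            raise ValueError(f"generator requires affirmed criterion terms, got {term!r}")
        ids.append(parsed.concept_id)
    return sorted(ids)


def _affirmed_sentence(phrase: str) -> str:
    # deterministic template choice, no RNG
    if len(phrase) % 2 == 0:
        return f"Patient presents with {phrase} today"
    return f"Exam shows {phrase}"


_RACES = ["white", "black", "asian", "hispanic", "other"]
_LANGUAGES = ["english", "english", "english", "spanish", "other"]
_MED_POOL = ["RX001", "RX002", "RX003", "RX004", "RX005"]
_PROC_POOL = ["PR001", "PR002", "PR003", "PR100"]
_AGE_BANDS = [(0.15, 0.0, 1.0), (0.40, 1.0, 5.0), (0.70, 5.0, 12.0), (1.0, 12.0, 18.0)]
_ACUITY_CUM = [(0.05, 1), (0.25, 2), (0.65, 3), (0.90, 4), (1.0, 5)]


def _geometric_minutes(u: float, mean: float) -> int:
    """Inverse-CDF geometric delay (support 0, 1, 2, ... minutes).

    Monotone non-decreasing in *mean* for fixed u, which keeps paired-seed
    delay sweeps honest. Capped at 240 min.
    """
    if mean <= 0:
        return 0
    p = 1.0 / (1.0 + mean)
    delay = int(math.floor(math.log(max(1.0 - u, 1e-300)) / math.log(1.0 - p)))
    return min(max(delay, 0), 240)


def _force_constraints(trial: TrialDefinition, entries: dict, u_force: np.ndarray) -> None:
    """Overwrite sampled structured entries so the trial's constraints pass."""
    i = 0

    def u() -> float:
        nonlocal i
        value = float(u_force[i % len(u_force)])
        i += 1
        return value

    sc = trial.structured_constraints
    if sc.age is not None:
        lo = sc.age.min if sc.age.min is not None else 0.0
        hi = sc.age.max if sc.age.max is not None else lo + 18.0
        age = round(lo + u() * (hi - lo), 2)
        entries["age"] = min(max(age, lo), hi - 0.01 if hi > lo else lo)
    if sc.sex:
        entries["sex"] = sc.sex[int(u() * len(sc.sex)) % len(sc.sex)]
    if sc.race:
        entries["race"] = sc.race[int(u() * len(sc.race)) % len(sc.race)]
    if sc.language:
        entries["language"] = sc.language[int(u() * len(sc.language)) % len(sc.language)]
    if sc.guardian_present is not None:
        entries["guardian_present"] = sc.guardian_present
    if sc.acuity:
        entries["acuity"] = sc.acuity[int(u() * len(sc.acuity)) % len(sc.acuity)]
    for vital, interval in sorted(sc.vitals.items()):
        lo = interval.min if interval.min is not None else (interval.max or 1.0) - 2.0
        hi = interval.max if interval.max is not None else lo + 2.0
        span = min(hi - lo, 3.0)  # stay near the clinically plausible edge
        entries["vitals"] = dict(entries["vitals"])
        entries["vitals"][vital] = round(lo + u() * span * 0.9, 1)
    if sc.medication_codes is not None:
        codes = set(entries["medication_codes"]) | set(sc.medication_codes.required)
        codes -= set(sc.medication_codes.forbidden)
        entries["medication_codes"] = sorted(codes)
    if sc.procedure_codes is not None:
        codes = set(entries["procedure_codes"]) | set(sc.procedure_codes.required)
        codes -= set(sc.procedure_codes.forbidden)
        entries["procedure_codes"] = sorted(codes)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(config: GeneratorConfig,
             trials: Sequence[TrialDefinition],
             lexicon: Lexicon) -> tuple:
    """Generate a snapshot stream and its ground truth.

    Returns ``(snapshots, GroundTruth)``; snapshots are sorted by
    (snapshot_time, patient_id) and serialize byte-identically for a fixed
    seed. Raises before generating anything if a criterion concept is
    missing from the lexicon.
    """
    incl_ids = {t.trial_id: _affirmed_concept_ids(t.inclusion_bag) for t in trials}
    excl_ids = {t.trial_id: _affirmed_concept_ids(t.exclusion_bag) for t in trials}
    known = lexicon.concept_ids()
    for trial in trials:
        missing = (set(incl_ids[trial.trial_id]) | set(excl_ids[trial.trial_id])) - known
        if missing:
            raise ValueError(
                f"trial {trial.trial_id!r} references concepts missing from the lexicon: "
                f"{sorted(missing)}"
            )

    criterion_pool = sorted({c for ids in incl_ids.values() for c in ids}
                            | {c for ids in excl_ids.values() for c in ids})
    distractor_pool = sorted(known - set(criterion_pool))
    prevalences = config.prevalence_for(trials)

    rng = np.random.default_rng(config.seed)
    snapshots: list = []
    labels: dict = {}
    evidence: dict = {}

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        u_arrival = rng.random()
        u_desig = rng.random()
        u_cat, u_age = rng.random(), rng.random()
        u_sex = rng.random()
        u_race, u_lang = rng.random(), rng.random()
        u_guard = rng.random()
        u_acuity = rng.random()
        z = rng.normal(size=4)
        u_med, u_proc = rng.random(), rng.random()
        u_force = rng.random(10)
        u_delay = rng.random()
        u_neg, u_neg_pick = rng.random(), rng.random()
        u_hist, u_hist_pick = rng.random(), rng.random()
        u_fam, u_fam_pick = rng.random(), rng.random()
        u_dup, u_dup_pick = rng.random(), rng.random()
        u_dis, u_dis_pick = rng.random(), rng.random()
        u_vio, u_vio_pick = rng.random(), rng.random()

        arrival = config.start_time + timedelta(
            seconds=int(u_arrival * config.window_minutes * 60)
        )

        # designation: at most one trial per patient
        designated: Optional[TrialDefinition] = None
        cum = 0.0
        for trial, p in zip(trials, prevalences):
            cum += p
            if u_desig < cum:
                designated = trial
                break

        # baseline structured entries
        lo, hi = 0.0, 18.0
        for threshold, band_lo, band_hi in _AGE_BANDS:
            if u_cat < threshold:
                lo, hi = band_lo, band_hi
                break
        entries = {
            "age": round(lo + u_age * (hi - lo), 1),
            "sex": "M" if u_sex < 0.49 else ("F" if u_sex < 0.98 else "U"),
            "race": _RACES[int(u_race * len(_RACES)) % len(_RACES)],
            "language": _LANGUAGES[int(u_lang * len(_LANGUAGES)) % len(_LANGUAGES)],
            "guardian_present": True if u_guard < 0.80 else (False if u_guard < 0.95 else None),
            "acuity": None,
            "vitals": {
                "temperature": float(np.clip(round(37.0 + 0.6 * z[0], 1), 35.0, 41.0)),
                "heart_rate": float(np.clip(round(110 + 25 * z[1]), 50, 220)),
                "respiratory_rate": float(np.clip(round(24 + 6 * z[2]), 10, 60)),
                "spo2": float(np.clip(round(98 + 1.5 * z[3], 1), 80.0, 100.0)),
            },
            "medication_codes": (
                [_MED_POOL[int((u_med / 0.15) * len(_MED_POOL)) % len(_MED_POOL)]]
                if u_med < 0.15 else []
            ),
            "procedure_codes": (
                [_PROC_POOL[int((u_proc / 0.10) * len(_PROC_POOL)) % len(_PROC_POOL)]]
                if u_proc < 0.10 else []
            ),
        }
        if u_acuity < 0.97:
            ua = u_acuity / 0.97
            for threshold, level in _ACUITY_CUM:
                if ua < threshold:
                    entries["acuity"] = level
                    break

        mentions: list = []  # (concept_id, assertion, source)
        sentences: list = ["Seen and examined in the emergency department"]

        if designated is not None:
            _force_constraints(designated, entries, u_force)
            for cid in incl_ids[designated.trial_id]:
                phrase = lexicon.phrases_for(cid)[0]
                sentences.append(_affirmed_sentence(phrase))
                mentions.append((cid, "AFFIRMED", "inclusion"))
            violation_targets = excl_ids[designated.trial_id]
            if violation_targets and u_vio < config.exclusion_violation_rate:
                cid = violation_targets[int(u_vio_pick * len(violation_targets))
                                        % len(violation_targets)]
                phrase = lexicon.phrases_for(cid)[0]
                sentences.append(_affirmed_sentence(phrase))
                mentions.append((cid, "AFFIRMED", "exclusion_violation"))

        if criterion_pool:
            if u_neg < config.negation_rate:
                cid = criterion_pool[int(u_neg_pick * len(criterion_pool)) % len(criterion_pool)]
                sentences.append(f"No {lexicon.phrases_for(cid)[0]} noted")
                mentions.append((cid, "NEG", "noise"))
            if u_hist < config.history_rate:
                cid = criterion_pool[int(u_hist_pick * len(criterion_pool)) % len(criterion_pool)]
                sentences.append(f"History of {lexicon.phrases_for(cid)[0]}")
                mentions.append((cid, "HIST", "noise"))
            if u_fam < config.family_rate:
                cid = criterion_pool[int(u_fam_pick * len(criterion_pool)) % len(criterion_pool)]
                sentences.append(f"Family history of {lexicon.phrases_for(cid)[0]}")
                mentions.append((cid, "FAM", "noise"))
        if distractor_pool and u_dis < config.distractor_rate:
            cid = distractor_pool[int(u_dis_pick * len(distractor_pool)) % len(distractor_pool)]
            sentences.append(_affirmed_sentence(lexicon.phrases_for(cid)[0]))
            mentions.append((cid, "AFFIRMED", "distractor"))
        if u_dup < config.duplicate_rate:
            sentences.append(sentences[int(u_dup_pick * len(sentences)) % len(sentences)])

        delay = _geometric_minutes(u_delay, config.delay_mean_minutes)
        note_time = arrival + timedelta(minutes=delay)
        structured = StructuredEntries.model_validate(entries)
        note = Note(note_time=note_time, note_type="ed note",
                    text=". ".join(sentences) + ".")
        snapshots.append(PatientSnapshot(
            patient_id=pid, arrival_time=arrival, snapshot_time=arrival,
            structured=structured, notes=[],
        ))
        snapshots.append(PatientSnapshot(
            patient_id=pid, arrival_time=arrival, snapshot_time=note_time,
            structured=structured, notes=[note],
        ))

        affirmed = {cid for cid, assertion, _ in mentions if assertion == "AFFIRMED"}
        probe = snapshots[-1]
        labels[pid] = {}
        for trial in trials:
            structured_ok = filters.apply_structured(probe, trial, policy="strict").passed
            text_ok = (set(incl_ids[trial.trial_id]) <= affirmed
                       and not set(excl_ids[trial.trial_id]) & affirmed)
            labels[pid][trial.trial_id] = bool(structured_ok and text_ok)
        evidence[pid] = [
            {"concept_id": cid, "assertion": assertion, "source": source,
             "delay_minutes": delay}
            for cid, assertion, source in mentions
        ]

    snapshots.sort(key=lambda s: (s.snapshot_time, s.patient_id, len(s.notes)))
    return snapshots, GroundTruth(labels=labels, evidence=evidence)


# ---------------------------------------------------------------------------
# Self-consistency validation
# ---------------------------------------------------------------------------


def validate_ground_truth(snapshots: Sequence[PatientSnapshot],
                          truth: GroundTruth,
                          trials: Sequence[TrialDefinition],
                          lexicon: Lexicon,
                          rules=None) -> list:
    """Independently re-derive every label through the real NLP pipeline.

    Takes each patient's final snapshot, extracts the concept bag with the
    production pipeline, recomputes the eligibility predicate (strict
    structured pass + all inclusion concepts affirmed + no exclusion
    concept affirmed) and compares with the stored label. Returns a list
    of violation descriptions; empty means fully consistent.
    """
    if rules is None:
        rules = nlp.default_rules()
    incl_ids = {t.trial_id: _affirmed_concept_ids(t.inclusion_bag) for t in trials}
    excl_ids = {t.trial_id: _affirmed_concept_ids(t.exclusion_bag) for t in trials}

    final: dict = {}
    for s in sorted(snapshots, key=lambda s: s.snapshot_time):
        final[s.patient_id] = s  # later snapshots overwrite earlier ones

    violations = []
    for pid, snapshot in sorted(final.items()):
        bag = nlp.extract_concepts("\n".join(n.text for n in snapshot.notes), lexicon, rules)
        affirmed = {
            ConceptTerm.parse(t).concept_id
            for t in bag
            if ConceptTerm.parse(t).assertion is Assertion.AFFIRMED
        }
        for trial in trials:
            structured_ok = filters.apply_structured(snapshot, trial, policy="strict").passed
            text_ok = (set(incl_ids[trial.trial_id]) <= affirmed
                       and not set(excl_ids[trial.trial_id]) & affirmed)
            expected = bool(structured_ok and text_ok)
            actual = truth.labels.get(pid, {}).get(trial.trial_id)
            if actual != expected:
                violations.append(
                    f"{pid}/{trial.trial_id}: truth={actual} recomputed={expected}"
                )
    return violations


# ---------------------------------------------------------------------------
# Fixture suite and feedback cohorts
# ---------------------------------------------------------------------------

FIXTURE_SEED = 1234


def make_fixture_suite(out_dir: Union[str, Path], seed: int = FIXTURE_SEED,
                       n_patients: int = 200,
                       config: Optional[GeneratorConfig] = None) -> dict:
    """Write a complete, self-contained fixture tree.

    Produces ``lexicon.tsv``, ``rules.tsv``, ``trials/*.yaml``,
    ``patients.jsonl`` and ``truth.json``; regenerating with the same seed
    is byte-identical. Returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials_dir = out_dir / "trials"
    trials_dir.mkdir(exist_ok=True)

    lexicon = fixture_lexicon()
    trials = fixture_trials(lexicon)
    config = config or GeneratorConfig(n_patients=n_patients, seed=seed)
    snapshots, truth = generate(config, trials, lexicon)

    paths = {
        "lexicon": out_dir / "lexicon.tsv",
        "rules": out_dir / "rules.tsv",
        "patients": out_dir / "patients.jsonl",
        "truth": out_dir / "truth.json",
        "trials_dir": trials_dir,
    }
    write_lexicon(lexicon, paths["lexicon"])
    nlp.write_rules(nlp.default_rules(), paths["rules"])
    for trial in trials:
        save_trial(trial, trials_dir / f"{trial.trial_id}.yaml")
    write_snapshots(snapshots, paths["patients"])
    truth.save(paths["truth"])
    return paths


def skull_fracture_scenario(seed: int = 0, n_eligible: int = 12,
                            n_ineligible: int = 12) -> tuple:
    """The canonical criteria-supplementation scenario, end to end.

    A head-trauma trial's inclusion names only "head injury". Coordinators
    review recommended candidates; the patients they deem eligible happen
    to also carry the finding "skull fractures" (C0037304) in their notes,
    while the declined ones do not. Bags are produced by the real NLP
    pipeline from templated notes (with distractor sentences in both
    classes), so the active learner should surface C0037304 as the top
    learned term. Returns ``(trial, feedback records, patient bags)``.
    """
    from .model import FeedbackRecord

    lexicon = fixture_lexicon()
    trial = next(t for t in fixture_trials(lexicon) if t.trial_id == "head-trauma")
    rng = np.random.default_rng(seed)
    distractors = ["rash", "ear pain", "runny nose", "dizziness", "sore throat"]
    base = datetime(2024, 3, 2, 9, 0, 0)
    records, bags = [], {}
    for j in range(n_eligible + n_ineligible):
        is_eligible = j < n_eligible
        pid = f"S{j:04d}"
        sentences = ["Patient presents with head injury today"]
        if is_eligible:
            sentences.append("Exam shows skull fractures")
        if rng.random() < 0.5:
            sentences.append(_affirmed_sentence(
                distractors[int(rng.random() * len(distractors)) % len(distractors)]))
        bags[pid] = nlp.extract_concepts(". ".join(sentences) + ".", lexicon)
        records.append(FeedbackRecord(
            patient_id=pid, trial_id=trial.trial_id,
            decision="eligible" if is_eligible else "not_eligible",
            reason_text="" if is_eligible else "imaging negative",
            decision_time=base + timedelta(minutes=j),
        ))
    return trial, records, bags


def simulate_feedback_cohort(seed: int,
                             trial_id: str = "head-trauma",
                             planted: str = "C0037304",
                             n_eligible: int = 10,
                             n_ineligible: int = 10,
                             p_planted_eligible: float = 0.9,
                             p_planted_ineligible: float = 0.05,
                             n_background: int = 10,
                             p_background: float = 0.3) -> tuple:
    """A feedback cohort with one planted informative concept.

    The planted concept appears in eligible patients' bags with probability
    ``p_planted_eligible`` and in ineligible ones with
    ``p_planted_ineligible``; background terms appear at the same rate in
    both classes (uninformative by construction). Returns
    ``(feedback records, patient bags)``.
    """
    from .model import FeedbackRecord

    rng = np.random.default_rng(seed)
    base = datetime(2024, 3, 1, 12, 0, 0)
    records, bags = [], {}
    for j in range(n_eligible + n_ineligible):
        is_eligible = j < n_eligible
        pid = f"F{j:04d}"
        bag: dict = {"C9000010": 1}  # the authored inclusion concept, present for all
        p_planted = p_planted_eligible if is_eligible else p_planted_ineligible
        if rng.random() < p_planted:
            bag[planted] = 1
        for b in range(n_background):
            if rng.random() < p_background:
                bag[f"C9100{b:03d}"] = 1
        bags[pid] = bag
        records.append(FeedbackRecord(
            patient_id=pid, trial_id=trial_id,
            decision="eligible" if is_eligible else "not_eligible",
            reason_text="" if is_eligible else "did not meet criteria",
            decision_time=base + timedelta(minutes=j),
        ))
    return records, bags
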