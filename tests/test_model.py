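"""Domain types, rendering bijection, and file-format round-trips."""

import json
from datetime import datetime

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialscreen import (
    Assertion,
    ConceptTerm,
    FormatError,
    Note,
    PatientSnapshot,
    StructuredEntries,
    load_lexicon,
    load_trial,
    read_snapshots,
    write_snapshots,
)
from trialscreen.model import snapshot_to_json, save_trial, trial_from_mapping


# ---------------------------------------------------------------------------
# ConceptTerm
# ---------------------------------------------------------------------------


concept_ids = st.from_regex(r"C[0-9]{1,7}", fullmatch=True)


@given(concept_ids, st.sampled_from(list(Assertion)))
def test_concept_term_rendering_bijection(concept_id, assertion):
    term = ConceptTerm(concept_id, assertion)
    assert ConceptTerm.parse(term.render()) == term


@pytest.mark.parametrize("rendered, concept_id, assertion", [
    ("NEG_C0032285", "C0032285", Assertion.NEG),
    ("HIST_C9000003", "C9000003", Assertion.HIST),
    ("FAM_C9000003", "C9000003", Assertion.FAM),
    ("C0032285", "C0032285", Assertion.AFFIRMED),
])
def test_concept_term_parse_examples(rendered, concept_id, assertion):
    assert ConceptTerm.parse(rendered) == ConceptTerm(concept_id, assertion)


def test_concept_id_may_not_collide_with_prefixes():
    with pytest.raises(ValueError):
        ConceptTerm("NEG_C1")
    with pytest.raises(ValueError):
        ConceptTerm("")


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------


def _write_lexicon(tmp_path, rows):
    path = tmp_path / "lex.tsv"
    lines = ["phrase\tconcept_id\tcategory"] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def test_load_lexicon_basic_and_lookup(tmp_path):
    path = _write_lexicon(tmp_path, [
        ("pneumonia", "C0032285", "disease"),
        ("Skull Fractures", "C0037304", "finding"),
    ])
    lex = load_lexicon(path)
    assert len(lex) == 2
    assert lex.lookup("skull fractures") == {"C0037304"}
    assert lex.lookup("pneumonia") == {"C0032285"}


def test_load_lexicon_collapses_duplicates(tmp_path):
    path = _write_lexicon(tmp_path, [("fever", "C9000001", "symptom")] * 2)
    assert len(load_lexicon(path)) == 1


def test_load_lexicon_one_phrase_many_concepts(tmp_path):
    path = _write_lexicon(tmp_path, [
        ("cold", "C9000045", "disease"),
        ("cold", "C9000046", "finding"),
    ])
    assert load_lexicon(path).lookup("cold") == {"C9000045", "C9000046"}


def test_load_lexicon_malformed_row_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("phrase\tconcept_id\tcategory\nfever\tC9000001\n", encoding="utf-8")
    with pytest.raises(FormatError, match="line 2"):
        load_lexicon(path)


def test_load_lexicon_empty_after_header(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("phrase\tconcept_id\tcategory\n", encoding="utf-8")
    with pytest.raises(FormatError):
        load_lexicon(path)


# ---------------------------------------------------------------------------
# Snapshots
# ---------------------------------------------------------------------------


def _snapshot(pid="P1", minute=0, note_minute=None, **kwargs):
    arrival = datetime(2024, 3, 1, 8, 0, 0)
    snap_time = arrival.replace(minute=minute)
    notes = []
    if note_minute is not None:
        notes = [Note(note_time=arrival.replace(minute=note_minute),
                      note_type="ed note", text="Fever today.")]
    return PatientSnapshot(
        patient_id=pid, arrival_time=arrival, snapshot_time=snap_time,
        structured=StructuredEntries(age=7.5, sex="F", acuity=3,
                                     vitals={"temperature": 38.2}),
        notes=notes, **kwargs)


def test_snapshot_roundtrip_is_byte_exact(tmp_path):
    snaps = [_snapshot("P1", minute=5, note_minute=3), _snapshot("P2", minute=2)]
    path = tmp_path / "s.jsonl"
    write_snapshots(snaps, path)
    first = path.read_bytes()
    reread = read_snapshots(path)
    write_snapshots(sorted(reread, key=lambda s: s.patient_id), path)
    # sort by patient_id restores original write order here (P1 before P2 by time is P2 first)
    assert sorted(snapshot_to_json(s) for s in snaps) == sorted(
        snapshot_to_json(s) for s in reread)
    write_snapshots(read_snapshots(path), path)
    assert sorted(path.read_bytes().splitlines()) == sorted(first.splitlines())


def test_read_snapshots_sorted_by_snapshot_time(tmp_path):
    snaps = [_snapshot("P1", minute=30), _snapshot("P2", minute=10), _snapshot("P3", minute=20)]
    path = tmp_path / "s.jsonl"
    write_snapshots(snaps, path)
    assert [s.patient_id for s in read_snapshots(path)] == ["P2", "P3", "P1"]


def test_read_snapshots_empty_file(tmp_path):
    path = tmp_path / "empty.jsonl"
    path.write_text("", encoding="utf-8")
    assert read_snapshots(path) == []


def test_read_snapshots_skips_invalid_records_with_warning(tmp_path, caplog):
    good = _snapshot("P1", minute=5)
    bad = json.loads(snapshot_to_json(good))
    bad["patient_id"] = "P2"
    bad["notes"] = [{"note_time": "2024-03-01T09:00:00", "note_type": "n", "text": "x"}]
    path = tmp_path / "s.jsonl"
    path.write_text(snapshot_to_json(good) + "\n" + json.dumps(bad) + "\n"
                    + "not json at all\n", encoding="utf-8")
    with caplog.at_level("WARNING"):
        result = read_snapshots(path)
    assert [s.patient_id for s in result] == ["P1"]
    assert sum("line 2" in r.message for r in caplog.records) == 1
    assert sum("line 3" in r.message for r in caplog.records) == 1


def test_snapshot_invariants_rejected():
    with pytest.raises(ValueError):
        _snapshot(minute=0, note_minute=30)  # note after snapshot_time
    with pytest.raises(ValueError):
        PatientSnapshot(patient_id="P", arrival_time=datetime(2024, 3, 1, 9),
                        snapshot_time=datetime(2024, 3, 1, 8),
                        structured=StructuredEntries(age=1))


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------


def test_load_trial_extracts_bags_through_nlp(tmp_path, lexicon):
    path = tmp_path / "t.yaml"
    path.write_text(
        "trial_id: toy\ninclusion_text: Head injury.\nexclusion_text: Asthma.\n",
        encoding="utf-8")
    trial = load_trial(path, lexicon)
    assert trial.inclusion_bag == {"C9000010": 1.0}
    assert trial.exclusion_bag == {"C9000003": 1.0}


def test_load_trial_structured_only(tmp_path, lexicon):
    path = tmp_path / "t.yaml"
    path.write_text(
        "trial_id: demo\nstructured_constraints:\n  age: {min: 12, max: 18}\n",
        encoding="utf-8")
    trial = load_trial(path, lexicon)
    assert trial.inclusion_bag == {} and trial.exclusion_bag == {}
    assert not trial.has_text_criteria


def test_load_trial_overlapping_term_is_error_naming_term(tmp_path, lexicon):
    path = tmp_path / "t.yaml"
    path.write_text(
        "trial_id: bad\ninclusion_text: Fever.\nexclusion_text: Fever.\n",
        encoding="utf-8")
    with pytest.raises(FormatError, match="C9000001"):
        load_trial(path, lexicon)


def test_load_trial_unknown_constraint_key_is_error(tmp_path, lexicon):
    path = tmp_path / "t.yaml"
    path.write_text(
        "trial_id: bad\nstructured_constraints:\n  shoe_size: {min: 1}\n",
        encoding="utf-8")
    with pytest.raises(FormatError):
        load_trial(path, lexicon)


def test_trial_term_weights_override_and_validate(lexicon):
    trial = trial_from_mapping(
        {"trial_id": "w", "inclusion_text": "Fever. Cough.",
         "term_weights": {"C9000001": 2.5}}, lexicon)
    assert trial.inclusion_bag == {"C9000001": 2.5, "C9000002": 1.0}
    with pytest.raises(FormatError, match="C9000099"):
        trial_from_mapping(
            {"trial_id": "w", "inclusion_text": "Fever.",
             "term_weights": {"C9000099": 2.0}}, lexicon)


def test_trial_save_load_is_deterministic(tmp_path, lexicon, trials):
    trial = trials[1]  # resp-infection: both bags populated
    path = tmp_path / "t.yaml"
    save_trial(trial, path)
    again = load_trial(path, lexicon)
    assert again == trial
    save_trial(again, tmp_path / "t2.yaml")
    assert (tmp_path / "t2.yaml").read_bytes() == path.read_bytes()


def test_learned_terms_require_provenance(lexicon):
    with pytest.raises(Exception):
        trial_from_mapping(
            {"trial_id": "p", "learned_terms": [{"term": "C0037304", "weight": 1.0,
                                                 "provenance": ""}]}, lexicon)
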