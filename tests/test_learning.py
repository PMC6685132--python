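"""Log-odds term informativeness and criteria refinement from feedback."""

import math
from datetime import datetime, timedelta

import pytest

from trialscreen import (
    FeedbackRecord,
    FeedbackStore,
    informativeness,
    score_patient,
    update_criteria,
)
from trialscreen.learning import term_statistics
from trialscreen.model import TrialDefinition
from trialscreen.synth import simulate_feedback_cohort, skull_fracture_scenario


def _record(pid, decision, minute=0, trial_id="t1"):
    return FeedbackRecord(patient_id=pid, trial_id=trial_id, decision=decision,
                          decision_time=datetime(2024, 3, 1, 12, 0) + timedelta(minutes=minute))


# ---------------------------------------------------------------------------
# Informativeness
# ---------------------------------------------------------------------------


def test_perfectly_separating_term_value():
    assert informativeness(5, 0, 0, 5) == pytest.approx(math.log(121), abs=1e-9)


def test_balanced_term_scores_exactly_zero():
    assert informativeness(2, 2, 2, 2) == 0.0


def test_sign_flips_under_class_swap():
    assert informativeness(0, 5, 5, 0) == pytest.approx(-math.log(121), abs=1e-9)


def test_antisymmetry_exact():
    for a, b, c, d in [(3, 1, 2, 4), (0, 7, 7, 0), (5, 5, 1, 9)]:
        assert informativeness(a, b, c, d) == pytest.approx(
            -informativeness(c, d, a, b), abs=1e-12)


def test_requires_feedback_in_both_classes():
    with pytest.raises(ValueError):
        informativeness(0, 0, 3, 2)
    with pytest.raises(ValueError):
        term_statistics([], [{"C1": 1}])


def test_term_statistics_counts_sum_to_class_sizes():
    stats = term_statistics([{"C1": 1}, {"C1": 1, "C2": 1}], [{"C2": 1}])
    by_term = {s.term: s for s in stats}
    for s in stats:
        assert s.a + s.b == 2 and s.c + s.d == 1
    assert by_term["C1"].a == 2 and by_term["C1"].c == 0
    assert by_term["C2"].a == 1 and by_term["C2"].c == 1


# ---------------------------------------------------------------------------
# Feedback store
# ---------------------------------------------------------------------------


def test_store_latest_decision_wins():
    store = FeedbackStore(known_trials={"t1"})
    store.ingest(_record("P1", "not_eligible", minute=0))
    store.ingest(_record("P1", "eligible", minute=5))
    assert len(store) == 1
    assert store.records()[0].decision == "eligible"


def test_store_rejects_unknown_trial_accepts_inactive():
    store = FeedbackStore(known_trials={"t1"})  # t1 may be inactive: still known
    store.ingest(_record("P1", "eligible"))
    assert len(store) == 1
    with pytest.raises(KeyError):
        store.ingest(_record("P2", "eligible", trial_id="nope"))


def test_store_save_load_roundtrip(tmp_path):
    store = FeedbackStore(known_trials={"t1"})
    store.ingest(_record("P1", "eligible"))
    store.ingest(_record("P2", "not_eligible", minute=2))
    path = tmp_path / "fb.jsonl"
    store.save(path)
    again = FeedbackStore.load(path, known_trials={"t1"})
    assert again.records() == store.records()


# ---------------------------------------------------------------------------
# Criteria updates
# ---------------------------------------------------------------------------


def test_k_zero_returns_trial_unchanged():
    trial = TrialDefinition(trial_id="t1", inclusion_bag={"C1": 1.0})
    updated = update_criteria(trial, [], {}, k=0)
    assert updated == trial
    assert updated is not trial


def test_skull_fracture_term_is_learned():
    """Eligible head-injury patients' notes carry "skull fractures"; the
    learner surfaces C0037304 and leaves authored criteria untouched."""
    trial, feedback, bags = skull_fracture_scenario(seed=0)
    before = trial.model_copy(deep=True)
    updated = update_criteria(trial, feedback, bags)
    assert updated.learned_terms
    assert updated.learned_terms[0].term == "C0037304"
    assert updated.learned_terms[0].weight == pytest.approx(1.0)
    assert updated.learned_terms[0].provenance.startswith("learned:")
    assert updated.inclusion_bag == before.inclusion_bag
    assert updated.exclusion_bag == before.exclusion_bag
    assert trial == before  # purity: input untouched


def test_learned_terms_capped_at_k_and_replace_previous():
    trial, feedback, bags = skull_fracture_scenario(seed=1)
    first = update_criteria(trial, feedback, bags, k=1)
    assert len(first.learned_terms) == 1
    again = update_criteria(first, feedback, bags, k=1)
    assert len(again.learned_terms) == 1


def test_authored_terms_never_learned():
    trial, feedback, bags = skull_fracture_scenario(seed=2)
    updated = update_criteria(trial, feedback, bags, min_score=0.0, k=50)
    learned = {lt.term for lt in updated.learned_terms}
    assert learned.isdisjoint(trial.inclusion_bag)
    assert learned.isdisjoint(trial.exclusion_bag)


def test_feedback_for_unknown_patient_is_error():
    trial = TrialDefinition(trial_id="t1")
    with pytest.raises(KeyError):
        update_criteria(trial, [_record("ghost", "eligible")], {})


def test_planted_concept_recovered_in_seeded_runs():
    hits = 0
    for seed in range(30):
        records, bags = simulate_feedback_cohort(seed, trial_id="t1")
        stats = term_statistics(
            [bags[r.patient_id] for r in records if r.decision == "eligible"],
            [bags[r.patient_id] for r in records if r.decision == "not_eligible"])
        if stats[0].term == "C0037304":
            hits += 1
    assert hits >= 28


def test_no_false_learning_when_classes_are_exchangeable():
    """With no term differing in prevalence between classes, the rate of
    runs where any term clears the min_score=2.0 gate stays within the
    99.9% binomial envelope of the exact null distribution (computed here
    by enumerating the 2x2 presence tables)."""
    n, p, n_terms, n_runs = 10, 0.3, 11, 30

    def binom_pmf(k):
        return math.comb(n, k) * p ** k * (1 - p) ** (n - k)

    q_term = sum(
        binom_pmf(a) * binom_pmf(c)
        for a in range(n + 1) for c in range(n + 1)
        if informativeness(a, n - a, c, n - c) >= 2.0)
    p_run = 1 - (1 - q_term) ** n_terms
    cumulative, bound = 0.0, n_runs
    for k in range(n_runs + 1):
        cumulative += math.comb(n_runs, k) * p_run ** k * (1 - p_run) ** (n_runs - k)
        if cumulative >= 0.999:
            bound = k
            break

    false_runs = 0
    for seed in range(n_runs):
        records, bags = simulate_feedback_cohort(
            seed + 1000, trial_id="t1", p_planted_eligible=p, p_planted_ineligible=p)
        stats = term_statistics(
            [bags[r.patient_id] for r in records if r.decision == "eligible"],
            [bags[r.patient_id] for r in records if r.decision == "not_eligible"])
        if any(s.score >= 2.0 for s in stats):
            false_runs += 1
    assert false_runs <= bound
    assert p_run < 0.5  # the gate keeps null learning a minority event


def test_matcher_improves_for_heldout_eligible_after_update():
    trial, feedback, bags = skull_fracture_scenario(seed=3)
    heldout = {"C9000010": 1, "C0037304": 1}  # eligible-profile patient
    before, _ = score_patient(heldout, trial)
    updated = update_criteria(trial, feedback, bags)
    after, _ = score_patient(heldout, updated)
    assert after >= before
    assert after > before  # skull fractures now contributes
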