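"""Refine a trial's criteria from coordinator eligibility decisions.

A head-trauma trial's inclusion names only "head injury". Coordinators
review recommended candidates; the ones they deem eligible happen to also
carry the finding "skull fractures" in their notes. The active learner
scores every term with smoothed log odds of presence given eligibility
and folds the winners back into the trial as learned terms.
"""

from trialscreen import score_patient, update_criteria
from trialscreen.learning import term_statistics
from trialscreen.synth import skull_fracture_scenario

trial, feedback, bags = skull_fracture_scenario(seed=0)
eligible = [bags[r.patient_id] for r in feedback if r.decision == "eligible"]
ineligible = [bags[r.patient_id] for r in feedback if r.decision == "not_eligible"]

print(f"feedback: {len(eligible)} eligible, {len(ineligible)} not eligible")
print("top term statistics (a=eligible with term, c=ineligible with term):")
for stat in term_statistics(eligible, ineligible)[:4]:
    print(f"  {stat.term:>14}  a={stat.a:2d} c={stat.c:2d}  log-odds={stat.score:+.3f}")

updated = update_criteria(trial, feedback, bags)
print("learned terms:", [(lt.term, round(lt.weight, 3)) for lt in updated.learned_terms])

held_out = {"C9000010": 1, "C0037304": 1}  # a future head-injury + skull-fracture patient
before, _ = score_patient(held_out, trial)
after, _ = score_patient(held_out, updated)
print(f"held-out eligible patient score: {before:.3f} -> {after:.3f}")
print()
print("C0037304 (skull fractures) clears the log-odds gate and now "
      "contributes to matching, so future patients documenting it rank "
      "higher without any change to the authored criteria.")
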