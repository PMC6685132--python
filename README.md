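# trialscreen

Continuous clinical-trial eligibility screening over electronic-health-record
visit snapshots, built for the emergency-department recruitment setting:
clinical research coordinators (CRCs) must find trial-eligible patients
during short, unplanned visits, and the information they need is split
between structured EHR fields (age, vitals, acuity, order codes) and
free-text clinical notes that arrive with a documentation delay.

`trialscreen` is a library plus a thin CLI that implements the whole
screening loop on synthetic data:

1. **Structured filtering** — patients whose structured entries fail a
   trial's constraints (intervals `[lo, hi)`, membership sets, required /
   forbidden order-code sets) are excluded before any text processing.
   Unknown values are explicit and, under the default *lenient* policy,
   pass through for human review.
2. **Concept extraction** — notes are segmented, lemmatized and
   de-duplicated; lexicon phrases are tagged greedy-longest-match; NegEx-
   style trigger/scope rules qualify each mention as affirmed, negated
   (`NEG_`), historical (`HIST_`) or family (`FAM_`). A note becomes a
   *bag of phrases*: rendered term → count (e.g. "to rule out pneumonia"
   → `{NEG_C0032285: 1}`).
3. **Matching and ranking** — a patient bag **x** is scored against a
   trial's weighted inclusion bag **w** by cosine similarity,
   `s = ⟨x, w⟩ / (‖x‖‖w‖) ∈ [0, 1]`, with a hard override to 0 when any
   affirmed exclusion term is present (a *negated* exclusion finding is
   not disqualifying). Candidates with `s ≥ threshold` are ranked for the
   dashboard; ties break by earlier arrival.
4. **Active learning** — coordinator eligible / not-eligible decisions
   partition reviewed patients' bags; each term is scored with smoothed
   log odds `ln[(a+½)(d+½)/((b+½)(c+½))]` of presence given eligibility,
   and the top terms are folded back into the trial as weighted *learned
   terms* (the canonical case: a head-injury trial learning the
   co-occurring finding "skull fractures", C0037304).
5. **Screening service** — a simulated clock walks the snapshot stream at
   a 10-minute refresh cadence, caching per-patient bags, dropping
   discharged patients, and serializing a dashboard state per tick.
6. **Synthetic ED generator + evaluation** — seeded streams with
   ground-truth labels (eligible ⟺ structured pass ∧ all inclusion
   concepts affirmed ∧ no affirmed exclusion concept), plus micro-averaged
   precision/recall/F, workload reduction and time-cutoff recall.

## Worked example

```bash
python examples/screen_visit_stream.py
```

prints (150 patients, seed 7, default study conditions):

```
300 snapshots over 22 ten-minute refreshes
final dashboard (recommended / structurally screened):
     family-asthma:  16 / 112   F1=0.968
       head-trauma:  11 /  93   F1=1.000
    resp-infection:   6 / 130   F1=1.000
  sepsis-biomarker:  10 /  10   F1=1.000
       teen-survey:  46 /  46   F1=1.000
           torsion:   7 /  60   F1=1.000
micro F = 0.995, workload reduction = 78.7%
```

Each line is one toy trial: of the patients who passed its structured
filter, how many the text matcher recommended, and how well those
recommendations agree with ground truth. Workload reduction is the share
of structurally-screened patients the coordinator no longer needs to
review. The one imperfect trial (family-asthma) shows realistic
cross-talk: a patient excluded from the respiratory trial for affirmed
asthma partially matches the asthma-inclusion trial.

The other examples cover single-note concept extraction
(`extract_concepts_from_note.py`), criteria refinement from feedback
(`learn_from_feedback.py`) and the documentation-delay sweep
(`delay_and_noise_sweep.py`).

The same pipeline is scriptable from a shell:

```bash
trialscreen generate --seed 11 --n-patients 200 --out suite/
trialscreen screen --patients suite/patients.jsonl --trials suite/trials \
    --lexicon suite/lexicon.tsv --rules suite/rules.tsv --out run/
trialscreen evaluate --state run/states/<last>.json --truth suite/truth.json
trialscreen demo --seed 7 --out demo/
```

## Layout

```
src/trialscreen/   model.py (types + file formats)   nlp.py (pipeline)
                   filters.py (structured filter)    matching.py (IR ranking)
                   learning.py (active learner)      service.py (refresh loop)
                   synth.py (generator + fixtures)   metrics.py (evaluation)
                   cli.py (thin click CLI)
tests/             unit + property + end-to-end acceptance suite
examples/          one narrative script per capability
docs/methods.md    models, parameters, design choices, limitations
```
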