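# Methods

This note documents the models and procedures `trialscreen` implements,
the parameters that matter, what the synthetic data does and does not
emulate, and the design choices made where the design was genuinely open.

## Problem setting

An emergency department sees a continuous stream of visits. For each of a
handful of actively enrolling trials, a coordinator must decide — during
the visit — whether a patient is worth approaching. The evidence is split
between structured EHR fields and free-text notes, and the notes arrive
late relative to the clinical events they describe (documentation delay).
`trialscreen` models the screening system as a recommender with a human
confirmer: it ranks likely-eligible candidates on a periodically refreshed
dashboard, and coordinator decisions feed back into the trial criteria.

## Text pipeline

**Normalization.** Sentences split on `. ! ?` and newlines; word tokens
are lower-cased; punctuation-only tokens are dropped. Lemmatization is
rule-based (plural `-s`/`-es`, `-ies→y`) with a small exception table for
irregulars (`noted→note`, `denies→deny`, `children→child`, …); a
dictionary-driven rather than model-based lemmatizer keeps the pipeline
deterministic and dependency-free. Duplicate sentences — endemic in
copied-forward clinical notes — are removed by exact match on the lemma
sequence, keeping the first occurrence; this makes extraction idempotent
under text duplication, which the suite tests end to end.

**Concept tagging.** The lexicon (TSV: phrase, concept id, category) is
compiled to lemma sequences and matched greedy longest-match left-to-right;
matched spans never overlap, and a phrase mapping to several concept ids
yields one tag per id. Greedy matching equals the token-coverage-optimal
tiling on the shipped lexicon (no conflicting phrase chains); a brute-force
tiling oracle in the tests guards this.

**Assertion detection.** NegEx-style rules: a trigger phrase assigns NEG,
HIST or FAM in its direction (forward/backward) within a scope of at most
6 tokens, terminated by the adversatives *but/however/although* and the
sentence boundary. Triggers are found greedy longest-match and do not
overlap, so "family history of" (FAM) shadows its substring "history of"
(HIST). For a tagged concept, the nearest in-scope trigger wins; distance
ties resolve NEG > HIST > FAM (negation is the clinically decisive
assertion for exclusion logic). The default trigger set (negation: no,
not, denies, without, negative for, rule out / ruled out; temporal:
history of, past, previous, prior; experiencer: mother, father, sibling,
family history of) ships as an editable TSV. "ruled out" lemmatizes to the
same sequence as "rule out" and carries a backward rule, so both
pre-position ("rule out pneumonia") and post-position ("pneumonia was
ruled out") negation fire.

The assertion vocabulary is deliberately minimal — four values covering
the negation / temporal / experiencer axes. No word-sense disambiguation,
learned NER, or abbreviation expansion is attempted.

## Structured filter

Constraints are per-field: numeric intervals closed below and open above
(`[lo, hi)`, the boundary convention applied to ages in years and vitals),
membership sets, a boolean guardian requirement, and order-code sets
(required = non-empty intersection, forbidden = empty intersection).
Unknown patient values (explicit `None`, sex `U`, race/language
`unknown`, a missing vital) evaluate to *unknown*, never to fail. The
aggregation policy defaults to **lenient** (unknowns pass through):
because every recommendation is confirmed by a coordinator, a false
exclusion is costlier than a false pass. `strict` is available where the
filter is the final arbiter. Vitals are evaluated against the snapshot's
current (most recent) measurement; no trend logic over repeated vitals is
implemented.

## Matcher

Scoring is weighted cosine similarity between the patient's term counts
and the trial's inclusion weights, computed over *rendered* terms — an
assertion-qualified term matches only its own rendered form, so a negated
mention never satisfies an affirmed criterion. Cosine over counts is the
simplest standard vector-space model consistent with bag-of-phrases
matching; it is isolated behind `score_patient` so BM25 or overlap
variants can be swapped in, and a binary-presence mode is available as a
flag (whether counts or presence is preferable on real notes is an open
question this package does not settle).

Exclusion semantics are a hard override rather than score subtraction:
any affirmed exclusion-bag term present (affirmed) in the patient bag
zeroes the score and disqualifies the candidate, with the matched terms
reported as evidence. Negated/historical/family exclusion mentions do not
disqualify.

**Admission rule.** The dashboard admits a candidate when it is not
exclusion-overridden and either (a) the trial has text criteria and
`score ≥ threshold` with `score > 0`, or (b) the trial is structured-only,
in which case every structurally passing patient is listed at score 0 —
there is no text requirement left to satisfy. The strict-positivity guard
keeps a zero-overlap patient from being "recommended" at threshold 0.
The default threshold is 0.2, configurable per run.

## Active learner

Feedback decisions partition reviewed patients' bags into eligible and
ineligible document sets. Term informativeness is the Haldane–Anscombe-
corrected log odds ratio of presence, `ln[(a+½)(d+½)/((b+½)(c+½))]`; it is
exactly antisymmetric under class swap and exactly zero for balanced
terms. Selection takes at most `k = 5` terms with score ≥ `min_score =
2.0` (odds ratio ≈ 7.4) that are not authored criteria; weights are
normalized to the top selected score; provenance is stamped
`learned:<date>` from the latest feedback time. Updates are pure and
*replace* the learned set, never touching authored bags; criteria removal
and `reason_text` mining are out of scope for this version (only the
label and the EHR-derived bags drive learning). The gate value was chosen
from the null behavior of small feedback samples: with ~10 records per
class and exchangeable classes, the probability that any term clears 2.0
stays a minority event (the suite checks the observed rate against the
exactly enumerated null distribution), while a genuinely separating term
(90% vs 5% prevalence) clears it essentially always.

## Screening service

The service walks the stream on a simulated event-time clock — the
10-minute refresh cadence is honored on the data's own timeline, so runs
are deterministic and fast, and a patient's candidacy changes only at
refresh boundaries. Per-patient concept bags are cached keyed by (note
count, latest note time); the invariant that incremental screening equals
one-shot batch screening guards the cache. Discharged patients drop from
the dashboard; inactive trials are hidden. States serialize to canonical
JSON (stable key order), and an audit log records one line per
recommendation per tick.

## Synthetic ED generator

The generator emulates a desk-scale ED stream: arrivals uniform over a
2-hour window (default 200 patients), one arrival snapshot (structured
only) and one clinical-note snapshot per patient. Defaults define the
study conditions: per-trial eligibility prevalence 0.08 across six toy
trials (demographics-only, multi-condition with exclusion, head-trauma,
guardian-gated, sex-restricted, vitals/order-code), documentation delay
geometric with mean 20 minutes, negated/historical/family mention noise at
0.30/0.15/0.10 per patient, duplicate-sentence rate 0.20, affirmed
distractor-concept rate 0.50, and a 0.10 chance that a designated patient
violates an exclusion criterion. Note text is template-based (slot-filled
sentences), sufficient to exercise every NLP rule deterministically; it is
not realistic clinical language.

Designation assigns each patient to at most one trial (categorical draw),
forces the structured entries to satisfy that trial, and injects its
inclusion concepts as affirmed sentences. Labels are then recomputed post
hoc for *all* trials from the injected evidence plus a strict structured
check, so accidental cross-trial eligibility is labeled correctly and the
ground-truth invariant holds by construction; an independent validator
re-derives every label through the production NLP pipeline. All
randomness flows from one seed through a fixed-length per-patient draw
block, so same-seed runs under different noise/delay settings stay paired,
and the inverse-CDF geometric delay is monotone in its mean for a fixed
seed — which is what makes the per-seed delay/recall monotonicity an exact
property rather than a statistical one.

What passing tests on this generator do **not** show: robustness to real
clinical language (abbreviations, misspellings, section headers, long
range discourse), lexicon coverage gaps, or EHR integration concerns. The
fixture lexicon (~45 phrases, reserved `C9xxxxxx` ids plus two
recognizable CUIs) stands in for licensed terminologies, which cannot be
redistributed.

Discharge snapshots are supported by the service (and tested) but off by
default in the generator: the mean ED stay (~3.4 h) exceeds the simulated
window, and final-state evaluation against ground truth requires the
cohort to still be on the dashboard.

## Evaluation

Confusion counts are defined over the structurally-screened universe in
the dashboard state — the screener never text-scores structurally excluded
patients, so true negatives are post-filter; this changes specificity-
style readings and is stated on the metrics rather than assumed. Micro
metrics pool counts over all (patient, trial) decisions. Workload
reduction `1 − recommended/screened` summarizes the review burden removed.
Time-cutoff recall (recall in the state at a fixed early time) quantifies
the documentation-delay effect; `noise_sweep` runs generate → screen →
score over a parameter grid and returns a long-format table with per-cell
mean and standard deviation.

## Numerical and degenerate-input choices

- Cosine of empty bags (either side) is 0; scores are clamped to `[0, 1]`
  against floating-point drift.
- Ranking ties break by earlier arrival time, then lexicographic patient
  id; ranks are 1-based and consecutive.
- Timestamps are timezone-naive ISO-8601 at second resolution.
- Invalid snapshot or feedback records are skipped with a warning naming
  the line number; malformed lexicon/trial/rules files fail loudly with
  the offending line or term.
- Feedback duplicates keep the latest decision time; a tie keeps the
  later-ingested record.

## Problem sizes

The shipped suites use 40–500 patients per run (1,000 for the generator
self-consistency check, 10 × 500 for noiseless recoverability, 100 seeded
cohorts for planted-concept recovery) — sizes at which every property is
exercised while the whole test suite and the acceptance script each run in
seconds.

## Known limitations

- Bag-of-phrases matching carries no discourse or temporal structure
  beyond the four assertion classes.
- The lenient filter can pass a patient whose unknown field would strictly
  fail; on trials whose truth depends on such a field this shows up as
  recommender-level false positives (by design: the coordinator decides).
- One phrase mapping to several concept ids tags all of them; no sense
  disambiguation.
- The active learner only adds terms; it never removes or down-weights
  authored criteria.
- Simultaneous recommendation of one patient for several trials is
  allowed.
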