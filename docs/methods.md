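# Methods

## Pipeline model

`fedcube` models a push-model federated network of healthcare sites. Each
site runs, entirely locally: bulk-FHIR NDJSON ingestion → note-text NLP →
de-identification → tabular flattening → phenotype evaluation → power-set
count matrix → small-cell suppression. Only the suppressed matrix is
shared; a coordinating step sums matrices cellwise and re-suppresses. The
analytics layer treats the merged matrix as the sole source of truth: every
measure is a function of counts, and a measure whose inputs include a
suppressed or unobserved cell raises an error rather than substituting a
value, because under aggregate-only sharing a missing cell carries
information (it was either never observed or deliberately withheld) and
imputing zero would bias exactly the rare-event cells suppression targets.

## The aggregate matrix

Given a labelled cohort (one row per patient or per encounter) and an
ordered variable list S, `cube_counts` enumerates every subset T ⊆ S and
groups the cohort by the variables in T. The result is sparse: only
observed level combinations appear, plus the mandatory null-set row whose
count is the cohort size. Invariants maintained and tested:

* the null-set row equals the cohort size;
* every row's count is bounded by the count of any row over a subset of its
  variables (monotonicity), and marginal sums within a fixed context
  reproduce the context row;
* the number of variables is capped (default 10, hard error above) since
  the subset count grows as 2^n.

Suppression removes rows with count < threshold (default 10) outright; no
masking token is left, so absent and suppressed cells are
indistinguishable by design. The threshold applies uniformly, including
the null-set row: a cohort smaller than the threshold yields an empty
matrix and a logged refusal. Merging requires identical variable lists,
study periods and thresholds, sums over the union of assignments, unions
the site lists, and re-suppresses. Because each input cell already meets
the threshold and sums only grow, re-suppression after merge is a no-op on
well-formed inputs — it exists to guard hand-edited matrices — and merge is
therefore commutative and associative. The accepted cost: a cell
suppressed at one site contributes zero to the network total, so merged
counts can undercount relative to a pooled line-level computation. The
2,000-patient worked example in the README shows this live (11 of 12
months of a trend series omitted).

## De-identification

Field handling is allow-list: any field without an explicit rule is
dropped, so unanticipated fields fail safe. Dates are truncated to
year-month (matching the month granularity of the trend displays; no date
shifting). Identifiers and references are replaced by HMAC-SHA256
pseudonyms truncated to 16 hex characters under a site secret — a keyed
one-way codebook. Determinism under a fixed secret preserves joins;
distinct secrets de-correlate sites. 64 bits of pseudonym space makes
collisions negligible at desk scale (the codebook still checks). The note
body never reaches this stage: DocumentReference resources are consumed by
the NLP step and dropped entirely. Ages are generated 0–89 so the special
handling of ages over 89 never arises.

## Note NLP

The extraction stage is deliberately deterministic: a value-set dictionary
(five symptoms, each with an ICD-10 code and 1–2 surface forms) matched
case-insensitively at word boundaries, leftmost-longest, non-overlapping;
then NegEx-style polarity: a pre-cue ("no", "denies", "without", "negative
for", …) within a 5-token window before the mention — or a post-cue within
the window after — negates it, with the scope cut by conjunctions ("but",
"however", …) and sentence boundaries. Uncertainty ("possible fever") is
treated as affirmed; there is no uncertain class. The cue list and window
are YAML configuration so the stage can be swapped without touching the
rest of the pipeline. Only affirmed mentions become records, and records
carry codes, references and months — never note text.

## Computable phenotypes

Case definitions are boolean combinations of three primitives evaluated
per in-period encounter: code-in-value-set (over condition, symptom or
medication tables), numeric threshold (over observations), and their
any/all/not combinations; exclusions are applied after inclusions. The
shipped hypertension phenotype is systolic ≥ 140 OR diastolic ≥ 90 mm Hg,
both comparators inclusive — the reading that makes either arm critical
qualifies, consistent with quality-measure practice of treating either
elevated arm as uncontrolled. Patient-level counting marks a patient a
case if any in-period encounter qualifies; encounter-level counting is
also supported. Study variables are boolean (criterion-backed),
categorical (patient attributes), binned integer (age at encounter from
birth year and encounter month, right-open intervals), or month (YYYY-MM;
for patient-level cohorts, the first in-period encounter month).

## Synthetic data: what it emulates and what it does not

The generator emulates a five-site surveillance export: per patient a
disease Bernoulli draw (default prevalence 0.30), conditionally
independent symptom draws (e.g. fever: 0.60 given disease, 0.05 without),
1 + Poisson(0.2) encounters uniform over a 12-month window, per-encounter
blood pressure from per-stratum normals (hypertensive: 152/96 ± 10/8;
normotensive: 118/74 ± 6–8 mm Hg; 25% of patients hypertensive), and one
templated note per encounter. Detection is asymmetric by default — a true
symptom is mentioned in the note with probability 0.9 but ICD-coded with
probability 0.5 — so the text-derived monthly detection percentage exceeds
the code-derived one in expectation, a qualitative property of real EHR
data that the tests assert on adequately powered months. The disease
itself is coded with probability 1.0 so aggregate-derived prevalence is an
unbiased estimator of the configured prevalence; lowering
`disease_coding_sensitivity` breaks that identity deliberately.

What the generator does **not** model: comorbidity structure, care
pathways, coding noise (false-positive codes), abbreviation-laden or
misspelled note language, uncertain/hypothetical mentions, family-history
mentions, and inter-site heterogeneity. Passing tests therefore
demonstrate correctness of the count pipeline and measure algebra under
known ground truth — not clinical NLP accuracy on real notes, for which no
claim is made.

## Numerical choices

* Odds ratio (ad/bc) and relative risk with log-scale Wald 95% intervals;
  zero cells handled by the Haldane–Anscombe 0.5 correction and flagged,
  never silent.
* Chi-square uses the closed-form 2×2 statistic N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)],
  1 df, no continuity correction by default (Yates available by flag); it
  agrees with scipy's contingency routine in the tests.
* 2×2 tables are extracted from four matrix rows (joint, two marginals,
  total) by subtraction; negative results indicate inconsistent inputs and
  raise.
* Matrix rows are sorted canonically (subset size, variable names, level
  labels) and timestamps in pipeline artifacts are fixed, so outputs are
  byte-stable for a given seed and secret.
* All generator randomness flows from one `numpy.random.Generator`; the
  test suite exercises the network at 10,000 patients across five sites
  (about 10 s end to end) and the cube oracle at up to 1,000 rows × 6
  variables × 200 cohorts.

## Known limitations

Suppress-then-merge undercounts (above). The negation rules are
scope-window heuristics and will mis-handle constructions the cue list
does not cover. The value-set vocabulary is small by design. Propensity
matching, Bayesian/tree classifiers, differential privacy noise and live
Bulk-FHIR authentication are out of scope; comparison cohorts are simply
all in-period non-cases.
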