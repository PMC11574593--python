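# Methods

## The decision rule

The engine (`uti_cdst.engine`) is a deterministic, side-effect-free
function of decision-time information only. Three questions are evaluated
in a fixed order with short-circuiting, so the reported `fired_question`
is the lowest-numbered affirmative: Q1 special populations (pregnancy,
impending endourological procedure, renal transplant within 60 days), Q2
localized urinary symptoms, Q3 unexplained systemic signs. Two modelling
choices deserve note:

* **Poor historians.** A patient unable to report symptoms is not an
  automatic indication. Q2 evaluates *documented* localized flags only,
  and such patients reach Q3, where objective systemic signs (fever,
  instability, mental-status change) decide. This mirrors how long-term-
  care guidance handles patients who cannot give a history.
* **Clinical instability is an input flag**, not derived from vital
  signs: no vital-sign thresholds are part of the rule, and deriving them
  would add an unvalidated layer.
* The single boolean output covers urine testing and antibiotic
  treatment jointly; whether Q3-positive cases start empirically or await
  exclusion of other causes is left to the caller.

## Syndrome adjudication and the reference standard

`classify_syndrome` partitions cases with precedence
`other_infection > pyelonephritis > cystitis > asb`. A documented
non-urinary infection source is resolved first (the pyelonephritis
definition requires the absence of another etiology). The precedence is
intentionally independent of the adjudicated treatment need: a pneumonia
patient later found to have a concurrent UTI stays in the other-infection
stratum while the reference standard records the true need. Cystitis is
any localized urinary symptom without fever; ASB is the all-negative
residual, and systemic signs carrying a documented alternate explanation
(seizure, psychosis, metabolic derangement, shock, and the like) do not
remove a case from ASB.

The reference standard (`true_need`) is an input field carried on each
record, never computed: it encodes a human full-stay chart review, and
recomputing it from decision-time data would collapse the two arms of the
validation into one.

`inappropriate_treatment_flag` marks antibiotic exposure with no
justification anywhere in the record: ASB without a special-population
indication, without a documented non-urinary source, and without an
adjudicated true need.

## Diagnostic accuracy and group comparisons

Sensitivity and specificity come from the 2×2 table of tool indication
vs reference standard. Confidence intervals default to exact
Clopper–Pearson at 95% (`statsmodels.stats.proportion.proportion_confint`,
method `"beta"`): the specificity estimate sits at 100%, where Wald
intervals degenerate to zero width. Binary urinalysis markers are
compared by Pearson chi-square without continuity correction by default
(a keyword enables Yates correction); continuous markers by the Welch
two-sample t test (pooled-variance available via `equal_var=True`). Welch
is the default because equal group variances cannot be assumed for
heavily skewed leukocyte counts. Records missing the relevant measurement
are excluded from the affected comparison only. A marker constant across
both groups carries no association and returns statistic 0, p = 1 rather
than an undefined chi-square. Reported percentages are rounded half-up to
one decimal (clinical convention; 73/74 → 98.6).

One reporting subtlety: 265/787 = 33.67%, which rounds to 33.7% but
truncates to 33.6%; the burden report therefore emits the unrounded
fraction together with both one-decimal renderings.

## Antibiotic burden

Days of therapy are per-agent calendar days summed over agents (two drugs
for three days each = six days); class-level day totals are only coherent
under this counting. Appropriateness is a record-level property applied
to all of a patient's courses, because the burden stratification is by
patient, not by course. Outpatient continuation days are included
whenever present in the input.

## The fixture cohort

`build_fixture()` compiles, with no randomness, a 124-record cohort
satisfying all of these marginals simultaneously, verified by a built-in
self-check that raises on any failure:

* syndromes 50 pyelonephritis / 15 cystitis / 13 other infection / 46 ASB,
  with 8 ASB carrying a procedural treatment indication;
* 38 patients treated without any documented indication; 36 poor
  historians; 9 ASB cases with altered mental status explained by other
  causes; 2 ASB cases with shock states explaining their instability;
* tool-validation margins TP=73, FP=0, FN=1, TN=50 — the false negative
  is the pneumonia case with *E. coli* bacteremia and bacteriuria;
* 787 antibiotic days, 265 on inappropriately treated patients;
  third-generation cephalosporins (203, 91), amoxicillin–clavulanate
  (51, 21);
* 75 female patients including one pregnant patient with cystitis;
  median age 64 (IQR 46–74.25), pinned via a fixed quantile-spaced age
  sequence under linear-interpolation percentiles.

Quantities the marginals do not pin down are filled by fixed schedules
documented in the source and are not load-bearing: per-patient course
durations (near-equal splits hitting the exact class-day quotas), the
allocation of the 36 poor historians across strata (one consistent choice
among many), and all urinalysis values. One genuinely ambiguous case —
the trauma patient with a kidney laceration and pelvic pain — is encoded
as ASB with the pain recorded in free-text notes and attributed to the
trauma rather than coded as a urinary-symptom flag; any other encoding
would break the 46-ASB and TN=50 margins jointly.

## The synthetic generator

`generate(CohortConfig)` samples line-level cohorts for simulation
studies. Defaults are the study conditions: n = 124; syndrome
probabilities 50/15/13/46 over 124; procedural-indication fraction 8/46
among ASB; altered-mental-status fraction 9/46 among ASB; poor-historian
fraction 36/124; urinalysis availability 85/124; marker positivity per
group at the observed proportions (e.g. leukocyturia 0.953 UTI vs 0.946
ASB); antibiotic class mix 203/51/533 over 787. Leukocyte counts are
log-normal with group-specific location (log-scale μ 5.64 vs 3.98,
σ = 1.5): group means near 860 vs 165 cells/µL with spreads wide enough
that a t test at these sample sizes is underpowered — the qualitative
behaviour expected of this marker. Course lengths follow a shifted
Poisson, `1 + Poisson(mean − 1)` with mean 4.2 days, and each patient
receives 1–3 distinct agent classes (probabilities 0.6/0.3/0.1).

Records are generated consistently with their syndrome (pyelonephritis ⇒
flank pain and/or fever, truly needed; other infection ⇒ fever explained
by the documented source; non-procedural ASB ⇒ not truly needed), so the
generator emulates the *joint* structure the pipeline consumes, not just
the margins. It does **not** emulate several features of real EHR data:
correlated comorbidities, within-hospital clustering, documentation noise
in the reference standard, or any dependence of symptom documentation on
who records it. Passing recovery tests therefore demonstrates internal
consistency of the pipeline, not field performance of the rule.

All randomness flows from one `numpy` `default_rng(seed)`; a fixed seed
reproduces a byte-identical serialized cohort.

## Serialization

The tabular dialect is CSV with an empty cell as the missing token,
distinct from an explicit `false` — "no symptoms documented" and
"patient unable to report" must remain distinguishable. Booleans are
literal `true`/`false` (case-insensitive on read). Courses occupy three
`agent_class_k`/`dot_k` column pairs plus an `other_dot` spillover that
merges any courses beyond three under the class `other`; round-trip is
lossless for records with at most three courses (the fixture and
generator never exceed three; the JSON structured format is lossless
unconditionally). Multiple courses of one class are summed on read.
Unparseable optional fields become absent with a logged warning; missing
mandatory fields raise an error naming the record and field.

## Numerical and testing choices

* Syndrome-mix calibration of the generator is tested by pooling counts
  over 100 seeded cohorts into one goodness-of-fit test (per-seed testing
  at any fixed α would fail some seeds by chance for a correct
  generator); convergence is additionally checked on one cohort of
  n = 10,000 at 2% tolerance, and pipeline parameter recovery of the
  ASB-without-indication fraction over 200 seeded cohorts at 3 standard
  errors. These problem sizes keep the full suite to well under a minute
  while leaving the statistical checks comfortably powered.
* The rule engine is validated by exhaustive enumeration against an
  independently written nested-conditional oracle over all 2¹² flag
  combinations × alternate-explanation presence.
* Exact-interval code is cross-checked against direct beta-quantile
  evaluation; chi-square and t statistics against closed-form arithmetic
  on toy tables.

## Known limitations

* The rule addresses newly hospitalized adults without indwelling
  catheters; catheter-associated UTI logic is out of scope.
* Urinalysis subgroup analyses are implemented as general operations, but
  the fixture's urinalysis values are synthetic filler: per-marker
  denominators of the original subgroup analyses are not recoverable, so
  those percentages are not reproduced or asserted.
* The decision-time rule and the full-stay review share criteria; as in
  any retrospective design with partially overlapping standards, the
  accuracy estimates are optimistic relative to prospective use.
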