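# uti-cdst

A clinical decision-support rule engine and retrospective validation
pipeline for distinguishing urinary tract infection (UTI) from
asymptomatic bacteriuria (ASB) in hospitalized adults.

Bacteriuria without attributable symptoms (ASB) is common — especially in
elderly patients and those unable to communicate — and usually should not
be treated; unnecessary antibiotics drive *C. difficile* infection and
resistance. This package implements a sequential 3-question rule, applied
at the moment a urine culture or antibiotic order is considered, that
gates testing and treatment for antimicrobial and diagnostic stewardship.
It is aimed at stewardship teams and methods researchers who want to
evaluate such rules against chart-review reference standards.

## The rule

For a newly hospitalized adult without an indwelling catheter, testing and
antibiotic treatment are indicated iff any question answers *yes*
(evaluated in order, short-circuiting):

1. **Special population** — pregnancy, an impending endourological
   procedure, or renal transplantation within 60 days (the situations in
   which ASB itself warrants treatment).
2. **Localized urinary symptoms** — urgency, frequency, dysuria,
   suprapubic pain, pelvic discomfort, or flank pain.
3. **Systemic signs without an alternate explanation** — fever, clinical
   instability, or acute mental-status change with no documented
   non-urinary cause (UTI as a diagnosis of exclusion).

Validation compares the rule's decision-time indication against the
full-stay chart-review reference standard, yielding a 2×2 table with

```
sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
```

with exact (Clopper–Pearson) 95% confidence intervals. Antibiotic burden
is measured in days of therapy (DOT, per-agent calendar days), stratified
by antibiotic class and by whether the patient had any documented
indication for treatment.

## Worked example

The package ships a deterministic 124-patient validation cohort
(`build_fixture()`); cohorts can also be sampled (`generate(CohortConfig)`)
or loaded from CSV/JSON (`read_cohort`). End to end from the shell:

```sh
cdst fixture  --output fixture.csv
cdst validate --input fixture.csv --report report.json
cdst burden   --input fixture.csv --report burden.json
```

prints

```
wrote 124 records to fixture.csv
sensitivity 98.6% / specificity 100.0%
265/787 unjustified antibiotic days
```

`report.json` holds the underlying counts — 73 true positives, 0 false
positives, 1 false negative (a pneumonia patient whose *E. coli*
bacteremia and bacteriuria revealed a concurrent UTI only on full-stay
review), 50 true negatives — plus exact intervals (sensitivity 98.6%,
95% CI 92.7–100%) and urinalysis-marker comparisons between UTI and ASB
cases. `burden.json` shows that 265 of 787 antibiotic days (33.7%
rounded; 33.6% truncated) went to patients with no documented treatment
indication, including 91 of 203 third-generation-cephalosporin days and
21 of 51 amoxicillin–clavulanate days.

The same pipeline in Python:

```python
from uti_cdst import (build_fixture, evaluate_cohort, true_need,
                      confusion, accuracy, percent)

cohort = build_fixture()
cm = confusion(evaluate_cohort(cohort), [true_need(r) for r in cohort])
est = accuracy(cm)
print(cm, percent(est.sensitivity), percent(est.specificity))
# tp=73 fp=0 fn=1 tn=50 98.6 100.0
```

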