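# progeval

A toolkit for the quantitative side of implementation evaluations of
community health programs — the kind of participatory process evaluation in
which stakeholders agree on a weighted indicator checklist, field teams
collect expected/observed counts from facility inventories, registers and
observed consultations, exit interviews measure user acceptability on a
Likert battery, and the findings are summarized as judged achievement
percentages plus an odds-ratio analysis of what drives acceptability.

It was built around an integrated community case management (ICCM) program
evaluation — community-level assessment, classification and treatment of
childhood pneumonia, diarrhea, malaria and malnutrition delivered by health
extension workers at health posts — and ships that evaluation's indicator
checklists and exit-interview count tables as worked example data, but every
component is configuration-driven and reusable.

## The model

**Indicator scoring.** Each checklist indicator has an expected count `E`,
an observed count `O` and a stakeholder weight `W` (points). Its score and
achievement are

```
S = O·W / E          A = 100·S / W  (= 100·O/E)
```

A dimension (availability, compliance, acceptability, …) pools its
indicators as `A_d = 100·ΣS / ΣW`, and the overall implementation is the
weighted mean `Σ(A_d·W_d) / ΣW_d` over the nominal dimension weights
(35/40/25 in the example data). Every achievement is mapped to a verbal
judgment by a band scale, by default poor [0, 60), fair [60, 75),
good [75, 85), very good [85, 100].

**Satisfaction classification.** Respondents answering `n` Likert items on
a `[min, max]` scale are classified against the demarcation threshold — the
midpoint of the attainable total-score range, `(n·max − n·min)/2 + n·min`
(42 for 14 five-point items). Totals strictly above the cutoff are
"satisfied". Per-item top-two-box counts become the O values of the
acceptability dimension's indicators.

**Association analysis.** Crude odds ratios `OR = ad/bc` with Woolf
intervals `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`; univariable screening keeps
covariates with any-level p < 0.25; a multivariable maximum-likelihood
logistic regression on the retained covariates reports adjusted odds ratios
`exp(β)` with Wald 95% intervals. A single-proportion sample-size helper
(`z²p(1−p)/d²`, inflated for non-response) covers survey planning, and a
largest-remainder apportionment helper allocates the sample across sites
proportional to caseload.

**Synthetic data.** `progeval.synthetic` generates exit-interview records
(covariates from configurable marginals, satisfaction from a logistic model
with a bisection-solved intercept, item responses consistent with the
latent class) and binomial indicator tables, so the entire pipeline is
testable end to end with known truth.

## Worked example

```python
from progeval import AcceptabilityModel, LikertScaleSpec, demarcation_cutoff
from progeval.datasets import load_example_matrix

report = load_example_matrix().evaluate()
print(report.dimension_table[["dimension", "achievement", "judgment"]])
print(round(report.overall_achievement, 1), report.overall_judgment)
print(demarcation_cutoff(LikertScaleSpec(n_items=14, item_min=1, item_max=5)))
```

prints

```
       dimension  achievement judgment
0   availability    84.240688     good
1     compliance    83.125980     good
2  acceptability    75.320000     good
81.6 good
42.0
```

i.e. resource availability reached 84.2% of its weighted points, provider
compliance with the clinical guideline 83.1%, caregiver acceptability
75.3%; their 35/40/25-weighted combination, 81.6%, falls in the
"good" band; and a caregiver answering the 14-item battery counts as
satisfied only with a total above 42.

The same numbers are available from the shell:

```sh
progeval score --indicators src/progeval/data/compliance_indicators.csv \
               --config src/progeval/data/evaluation_config.yaml
progeval samplesize -p 0.74 -d 0.04 --nonresponse 0.10   # -> 508
progeval assoc --counts src/progeval/data/exit_interview_counts.csv
progeval simulate survey --n 484 --seed 7 --out exit.csv
```

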