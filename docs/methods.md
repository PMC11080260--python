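# Methods

This note documents the statistical procedures progeval implements, the
defaults it ships, the numerical choices behind them, and what the bundled
synthetic data can and cannot demonstrate.

## Weighted indicator scoring and the judgment matrix

An indicator is a checklist item with an expected denominator `E > 0`, an
observed numerator `0 ≤ O ≤ E` and a stakeholder-elicited weight `W > 0` in
points. Scores are `S = O·W/E` and achievements `A = 100·S/W`; achievement
is therefore algebraically independent of the weight, which only matters
when indicators are pooled. A dimension's achievement is the pooled ratio
`100·ΣS/ΣW` over its own indicators — equivalently the weight-weighted mean
of indicator achievements. The overall implementation is the weighted mean
of dimension achievements using the *nominal* dimension weights agreed with
stakeholders.

Two deliberate denominator choices:

* **Elicited vs nominal weights.** The per-dimension denominator is the sum
  of the indicator weights actually present, not the nominal dimension
  weight. Elicitation rarely produces weights that add up exactly to the
  nominal total (the bundled availability checklist sums to 34.9 points
  against a nominal 35); dividing by the elicited sum keeps a
  fully-achieved dimension at exactly 100%. The nominal weight is used only
  in the overall aggregation.
* **Score overrides.** An indicator may carry an explicit score `S` in
  place of `O·W/E`, bounded by `[0, W]`. This exists because published
  summary checklists are sometimes internally inconsistent: in the bundled
  acceptability table one item's printed observed count disagrees with its
  own printed score and achievement, and the score column is the record
  from which the dimension total was computed. The reader activates an
  override only where a `score` cell is present.

Judgment bands are lower-inclusive half-open intervals that must partition
[0, 100], with the top band closed at 100 so every value is classified; the
default scale is poor [0, 60), fair [60, 75), good [75, 85), very good
[85, 100]. The published convention writes bands as "60–74.9" style ranges;
the half-open reading avoids the gap between 74.9 and 75 that a literal
reading would leave. Band boundaries are classified into the *upper* band
(60.0 is "fair").

Computation is in full floating precision; rounding (half-up, default one
decimal) happens only at presentation. Published achievement cells mix
rounding conventions (e.g. 11/14 printed as 78.5), so checks against
printed values use a ±0.1 tolerance. An indicator with `E = 0` is rejected:
an item with no eligible units carries no information and should be
excluded upstream (the CSV reader can drop such rows with a logged
warning).

## Demarcation-threshold classification

For `n` items on an integer scale `[min, max]`, the demarcation threshold
is the midpoint of the attainable total range, `(n·max − n·min)/2 + n·min`
— 42 for 14 five-point items. Classification is strict: a total exactly at
the threshold is *dissatisfied*, since the midpoint expresses no net
agreement. Item-level "satisfied with this aspect" counts use the
top-two-box rule (response ≥ 4 on a 1–5 scale), configurable via
`agree_threshold`; the published source does not define the item-level
rule, and top-two-box is the standard survey convention consistent with
agree/strongly-agree labels. Missing item responses are rejected rather
than imputed; the CSV reader can optionally drop incomplete records with a
logged count.

## Odds-ratio association analysis

* **Crude ORs** use `ad/bc` with the Woolf log-normal interval,
  `exp(ln OR ± z·SE)`, `SE = √(1/a+1/b+1/c+1/d)`, and a two-sided Wald
  p-value. This interval reproduces the published education-level intervals
  to the printed precision; exact and mid-p methods are out of scope. A
  zero cell is a hard error unless the Haldane–Anscombe correction (+0.5 to
  every cell) is explicitly requested, in which case the result is flagged
  `corrected`.
* **Screening** fits one univariable logistic model per candidate and
  retains the variable if any level's Wald p-value is below `alpha_screen`
  (0.25 by default, the conventional liberal screen). The source does not
  state which bivariable test it used; Wald screening is the default and a
  Pearson chi-square screen is available as `method="chi2"`. If a
  univariable fit is singular or separated (common at small n), the
  chi-square p-value is used as a fallback for that candidate. Constant
  covariates are excluded with a warning; a constant outcome is an error.
* **The multivariable fit** is a maximum-likelihood binary logistic
  regression (statsmodels, Newton iterations, coefficient-change tolerance
  1e-10, 50-iteration cap). Non-convergence is reported in the result
  object, never silently ignored. Quasi-complete separation is flagged when
  any non-intercept coefficient exceeds 15 in magnitude (an odds ratio
  beyond e¹⁵ ≈ 3.3·10⁶ is not a finite estimate in practice). Adjusted ORs
  are `exp(β)` with Wald intervals; profile-likelihood intervals are not
  offered, matching standard epidemiological reporting.
* **Reference levels** are explicit everywhere and default to the first
  observed level when unspecified; `AcceptabilityModel` accepts a
  per-variable mapping.

The sample-size helper computes `n0 = ⌈z²p(1−p)/d²⌉` and inflates by the
anticipated non-response fraction, rounding to the nearest integer
(0.74/0.04/95%/10% → 462 → 508). Largest-remainder (Hamilton)
apportionment allocates a survey total across sites proportional to
caseload: floors of the exact quotas, remaining units to the largest
fractional remainders, ties broken by input order — deterministic, summing
exactly, and never more than one unit from the exact share.

## Synthetic exit interviews

The generator emulates the study conditions the analysis assumes:

* `n_respondents = 484`, the realized exit-interview sample.
* Covariates drawn **independently** from categorical marginals matching
  the published descriptive table (52.1% illiterate, 85.7% rural, 93%
  female, 84.5% received prescribed drugs, …). Real covariates are
  correlated (education with residence, for instance); only marginals are
  published, so independence is the default and any joint structure would
  be invented. Consequently, agreement between crude and adjusted ORs in
  synthetic data is closer than it would be in real data — passing
  recovery tests demonstrate correctness of the estimation chain, not
  realism of confounding.
* Satisfaction from a logistic model whose default non-zero log-odds are
  the logs of the published significant adjusted ORs (education primary
  0.27, secondary 0.16, college 0.08 vs illiterate; prescribed drugs 2.16;
  arrival time 3.82; waiting time 2.79) and zero for everything else. The
  intercept is solved by bisection (tolerance 1e-6) on the *realized*
  covariate sample so the expected satisfied fraction equals
  `target_prevalence`, default 0.762 (= 369/484, the satisfied column total
  of the published association table).
* Item responses conditional on the latent class — satisfied respondents
  draw from a distribution concentrated on agree/strongly-agree,
  dissatisfied ones on the lower categories — with rejection sampling
  forcing the total to the correct side of the demarcation cutoff (after
  100 rounds the rare stragglers are pinned to the scale extreme). Likert
  classification therefore recovers the latent class exactly; the loop
  generate → classify → screen → fit is a clean parameter-recovery check.
* One root seed is expanded into named substreams (per covariate, one for
  satisfaction, one for items), so adding or removing a covariate leaves
  the other draws untouched.

Indicator tables are emulated as `O ~ Binomial(E, p)` per indicator with
weights copied from configuration; with `p = O/E` from a real checklist the
mean simulated dimension achievement equals the real one.

## Problem sizes used in the checks

The test suite runs the recovery loop once at n = 50,000 respondents (the
size at which a 3-standard-error band is tight enough to be informative for
every configured coefficient), the null-coverage simulation at 120
replicates of n = 300, the screening-level simulation at 400 replicates of
n = 50, the logistic-vs-closed-form equivalence on 1,000 random 2×2 tables,
and the binomial indicator calibration at 500 replicates. All seeds are
fixed in the suite.

## Known limitations

* Published summary tables are reproduced from their printed counts; three
  rows of the published association table (sex, how the provider
  communicated the illness, information source) are internally inconsistent
  as printed and are carried in the bundled data as printed but not
  asserted against.
* The published *adjusted* ORs cannot be reproduced without the raw
  respondent-level data, which is not public; they enter this package only
  as generator defaults.
* No psychometrics (reliability, factor structure) on the Likert battery;
  items are unweighted within the total score.
* No interactions, random effects or multiple-testing adjustment in the
  association analysis — the procedure mirrors the screen-then-fit
  convention it implements.
* The Gaussian-copula hook for correlated covariates is deliberately not
  implemented; covariate independence is a documented modelling choice of
  the generator.
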