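# Methods

This note documents the generative model behind the synthetic cohorts, the
scoring and statistical procedures, the numerical choices, and the known
limits of what the test suite can show about real data.

## The study design being modeled

The pipeline targets a common real-world-evidence design: commercial users
of a cognitive-training program take an online 8-subtest neurocognitive
battery (NCPT-style) and a 7-item attention/mood scale (BAMS-style) at two
or more time points at least 10 weeks apart, train as much as they like in
between, and report lifetime-diagnosed medical conditions on a 32-item
checklist. The analysis asks whether more training between assessments
(the "dose") produces larger improvements, after removing demographic
structure and accounting for retest (practice) gains.

## Synthetic cohort generator

The generator emits four linked tables (participants, long-format sessions,
gameplay events, and a ground-truth side table used only by tests). Its
defaults encode the study conditions the pipeline is meant to analyze:

- **Cohort composition.** ADHD prevalence 13.7%. Ages are truncated normals
  per group — ADHD mean 40.4 (SD 15.9), non-ADHD mean 52.6 (SD 16.4) —
  truncated to [14, 95] so that under-18/over-90 records exist to exercise
  the eligibility filter. The ADHD group is slightly majority-male, the
  rest clearly majority-female.
- **Comorbidity.** Each condition has a logistic model
  `logit P = intercept + β·ADHD`. The four psychiatric comorbidities carry
  ADHD log-odds of log 2.5 (anxiety, depression), log 2.8 (substance use
  disorder), and log 1.8 (sleep disorder) — plausible magnitudes for adult
  ADHD chosen once; the remaining conditions get small coefficients.
- **Battery scores.** Each subtest has a natural raw scale (counts correct,
  spans, completion seconds). A raw score is
  `mean + sign·(age terms + gender offset + ability − deficit·ADHD +
  gains + noise)`, where `sign = −1` for the two completion-time subtests so
  the raw scale keeps its orientation while all performance terms act in
  one direction. Person-level abilities share a general factor (loading
  0.55), so subtests correlate as real batteries do and the composite has
  SD < 15 before re-norming. The ADHD deficits default to ≈ 0.2 of each
  subtest's between-person SD.
- **Scale items.** Items are quintile-discretized latent normals (equal
  mass per response option under the null). Attention items load 0.63 and
  mood items 0.70 on their subscale traits, sized to give Cronbach's α near
  0.72/0.75. ADHD shifts attention item latents by 0.72 SD and mood items
  by 0.35 SD toward the negative pole, reproducing the pattern that
  self-reported attention discriminates ADHD best. 1% of responses are
  "N/A" to exercise missing-data handling.
- **Retest and dose.** The second battery administration gains 0.35
  session-noise SDs regardless of training (the practice effect); the scale
  has no retest gain. Training adds `slope · log1p(intervening gameplays)`
  session-noise SDs. The config declares one retest/dose value
  per instrument; because the eight subtests live on heterogeneous raw
  scales, these are expressed in units of each measure's session-noise SD
  and converted to raw units internally. Default slopes (0.05 for the
  battery, 0.06 for attention items, 0 for mood) are sized so the implied
  high-vs-low standardized effects on the composite (~0.44) and the
  Attention subscale (~0.5) match the magnitudes reported for real cohorts
  of this kind, with no dose effect on mood.
- **Dose mixture.** Intervening gameplays are drawn from a low (0–25,
  uniform) / intermediate (26–399) / high (400–2000) mixture with weights
  0.25/0.45/0.30; counts within the upper strata are log-uniform so heavy
  users are rarer. Both contrast strata are non-empty at default sizes.
- **Schedule.** First assessments fall on days 15–119; the gap to the
  second is 70 days plus an exponential with mean 50 (the 10-week minimum
  is a hard floor; the distribution beyond it is a config knob since real
  designs rarely pin it down). Gameplay events are placed strictly before
  the first assessment (prior plays) or inside the half-open window
  (first, second].

What the generator does **not** emulate: item-level battery responses,
game mechanics, informative dropout (retention is a constant per-instrument
probability), medication status, seasonal or secular trends, and selection
effects in who chooses to train more. Passing tests therefore demonstrate
that the *machinery* is correct and calibrated — not that any real-world
effect exists; conclusions about real cohorts require the real data via the
adapter.

## Norm tables

- **Percentile convention:** weighted mid-ranks — cumulative weight below a
  raw value plus half its tied weight, divided by total weight. Symmetric
  and standard for normative tables.
- **Tail handling:** percentiles are clipped to `[1/2n, 1 − 1/2n]` before
  the inverse-normal transform, and scaled values are clipped at ±5 SD
  (i.e., [25, 175]), so no raw value maps to an infinite scaled score.
- **Weights:** post-stratification ratios over age-bin × education cells,
  rescaled to sum to the sample size; reference cells with zero mass give
  zero weights and the remainder is rescaled. Sample cells absent from the
  reference are an error (the reference must cover the sample).
- **Age bins:** decadal (18–29 … 80–90) by default, configurable.
- **Composite:** the GI table is built from the normative sample's
  subtest-mean values with the same weights (the battery's own published
  description leaves the composite construction ambiguous; subtest means
  are the default here and the alternative is a one-line change since any
  monotone statistic of the scaled means feeds the same table builder).
- **Application:** piecewise-linear interpolation between knots; raw values
  outside the table clamp to the end entries. Tables serialize to JSON and
  are intended to be frozen artifacts: score the study with the tables you
  built, not tables rebuilt per run.

Self-norming is the key invariant: applying a table to its own weighted
normative sample must return weighted mean 100 ± 0.5 and SD 15 ± 0.5 for
n ≥ 5,000 (the SD sits slightly below 15 because mid-ranks compress the
extreme tails; at n = 10,000 the deficit is ≈ 0.01).

## Scale scoring

Recoding follows "0 is always the most negative option": frequency items
describing attention lapses run "Almost every day" → 0 … "Never" → 4;
the positively-worded concentration item scores "Strongly agree" → 4;
negative-affect agreement items score "Strongly agree" → 0. The default
missing-data policy requires every item of a subscale (conservative); a
"≥ half" policy is available because real scoring rules often allow partial
subscales — the choice is configurable and recorded in the output. α is
computed on listwise-complete rows; the Feldt interval uses
`(1 − α̂)/(1 − α) ~ F(n−1, (n−1)(k−1))`.

## Cohorts and dose

Eligibility: age 18–90, a completed condition survey, no condition on the
severe-disorder exclusion list (shipped as a configurable 8-item default),
at least one assessment, and at most 25 gameplays before the first
assessment. Exclusions are logged one reason per participant, checked in a
fixed order (survey, age, excluded condition, no assessment, prior
gameplay), and retained + excluded always sums to the input count.

Dose intervals are inclusive at their printed endpoints (low ≤ 25, high
400–2000). Counts above 2000 are labeled `above_high` and excluded from the
two-stratum contrast (they enter only the dose-curve sensitivity analysis);
such users are rare and outside the range where the dose contrast is
defined. "Gameplays between assessments" counts events in the half-open
window (first-session day, second-session day] — the convention is a
package choice since event-vs-assessment simultaneity is ambiguous in
day-resolution data.

## Statistics

- **Residualization:** ordinary least squares of the outcome on intercept,
  age, age², and gender (3-level categorical, male reference, so
  "not reported" participants remain modelable). Age is mean-centered for
  conditioning. The model is fitted once on all twice-tested participants
  per instrument and its coefficients are applied to the ADHD-SRLD subset —
  this ordering matters and is preserved everywhere. Rank-deficient designs
  raise an error naming the collinear terms (QR with column pivoting).
- **Welch t** with Satterthwaite df; **Hedges g** with `J = 1 − 3/(4N−9)`
  and the standard large-sample variance `N/(n₁n₂) + g²/(2(N−2))` for its
  CI (the asymptotic form; a noncentral-t inversion would change CIs by
  < 1% at the cohort sizes involved).
- **Bonferroni** families: the 8 battery subtests, the 4 attention items,
  the 3 mood items; aggregate measures (GI, subscales) are unadjusted.
- **Comorbidity odds:** GLM with logit link, Wald CIs. Separation is
  detected by exploding coefficients/standard errors and raises (the
  pipeline skips that condition with a warning); penalized fits are
  deliberately out of scope.
- **Responders:** threshold = ½ SD of the baseline scores of the entire
  twice-tested ADHD-SRLD cohort on that measure, instrument-specific, all
  dose strata pooled. Responder = raw change ≥ threshold (scores are
  oriented higher-is-better upstream, so improvement is always an
  increase). Per-stratum odds are r/(n−r) with log-odds normal CIs; the
  between-dose OR comes from a two-group logistic fit (identical point
  estimate to the 2×2 cross-ratio; the CI is the Wald interval from that
  fit). A stratum with zero or all responders reports an unbounded CI with
  a flag rather than failing.
- **Logistic fits** use IRLS with tolerance 1e-8 and at most 100
  iterations; they are deterministic.

## Problem sizes

The test suite and the acceptance script run on scaled-down cohorts chosen
to make Monte-Carlo tolerances meaningful at interactive runtimes: the
self-norming check uses a normative sample of n = 10,000; dose-effect
recovery and calibration use 200–500 replicates of two-stratum cohorts
with n = 616 low / 1,330 high (realistic efficacy-stratum sizes); null
simulations for α and odds use 50,000 observations. These sizes are the
package's reference conditions and are stated wherever a tolerance depends
on them.

## Known limitations

- The reference distribution is a configurable stand-in; the package does
  not ship or reproduce any census microdata.
- Only two assessment time points are modeled; no mixed-effects or
  longitudinal machinery beyond change scores.
- Causal language is avoided throughout: the dose contrast is an
  observational comparison, and the synthetic generator injects effects by
  construction rather than simulating selection into training intensity.
- The published dataset-dependent values shipped in
  `data/published_benchmarks.yaml` describe the real deposited study data
  and can only be checked after downloading it; they are never compared to
  synthetic output.
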