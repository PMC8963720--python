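# Methods

This note documents the models, defaults, and numerical choices behind
`cogcap`, and what the synthetic generator does and does not emulate.

## Information content of majority judgments

A majority-judgment condition with majority:minority split *m:k*
(set size n = m + k odd) is quantified under the grouping-search strategy:
the observer repeatedly samples groups of g = (n+1)/2 arrows, with
replacement of groups, until a group is homogeneous; its direction gives
the majority.  The probability a sampled group is homogeneous is
hypergeometric, `p = [C(m,g) + C(k,g)] / C(n,g)` (the minority term drops
when k < g), so the expected number of samples is `E[S] = 1/p` and the
condition conveys

```
I = log2(g · E[S])   bits.
```

This reproduces the six canonical values 0, 1.00, 2.58, 1.58, 2.91 and
4.91 bits (1:0, 3:0, 2:1, 5:0, 4:1, 3:2) at two-decimal rounding; a
Monte-Carlo sampler of the same process agrees with the closed form to
within 1 % at 10^5 runs (tested).  The single-arrow condition carries zero
information by this definition and anchors the accuracy ceiling.

## Capacity model and estimator

Accuracy in a condition with information amount I at exposure T follows a
piecewise-linear psychometric model with one free parameter, the capacity
C (bits/s):

```
P(correct) = a0                        if I <= C·T
             0.5 + (a0 − 0.5)·C·T/I    otherwise
```

Ceiling while the processable amount C·T covers the load; a linear descent
toward the 0.5 guessing floor in the processed fraction otherwise;
continuous at the knee.  This operationalizes "capacity = the information
rate at which accuracy starts to drop".

**Estimation.** Per subject, the ceiling a0 is fixed at the observed 1:0
accuracy (108 trials on the full schedule), clipped to [0.51, 0.999]; C is
then the only free parameter and maximizes the Bernoulli log-likelihood of
all loaded trials, with no-response trials counted as errors.  The
maximization runs on a 400-point log-spaced grid over [0.05, 10] bits/s,
then an arithmetic refinement at 0.001 resolution between the neighbours
of the coarse optimum.  The estimate matches an exhaustive 0.001-step grid
to within 0.01 whenever the likelihood is unimodal in C — which holds
empirically for model-generated data (tested over seeds); probabilities
are clipped to [1e-9, 1 − 1e-9] before logs.  Estimates within one coarse
step of a bound are flagged (`lower`/`upper`); all-correct data are
unidentified upward (upper flag), exact-chance data collapse to the lower
bound.  Fitting a0 from the zero-information condition rather than jointly
keeps the estimator one-dimensional; a `fixed_a0` override exists for
sensitivity analyses.  Estimator calibration, measured by simulation:
bias +0.01 to +0.06 bits/s across true C in [1, 4] on single 324-trial
schedules, per-subject SD ≈ 0.15–0.57 (growing with C as the knee moves
past more conditions).

## ANT-I scoring

No-response trials count as errors and never enter RT pools.  Outlier
filtering is a single pass per subject × 18-cell design cell on correct
responded trials: values beyond mean ± 3 sample SDs (ddof = 1) of their
own cell are discarded; cells with fewer than two correct trials are left
unfiltered and logged.  Effects are subtraction scores on pooled retained
trial RTs: alerting = no-signal − signal, orienting = invalid − valid,
conflict = incongruent − congruent (larger = worse).  The alerting sign
follows the operational definition whose printed condition means are
consistent (no-signal minus signal, e.g. 726.7 − 676.6 ≈ 50); accuracy
effects mirror the RT directions.  Overall RT averages all retained
trials; neutral-flanker trials are included by default
(`include_neutral_in_overall=False` excludes them, a documented open
choice).  With balanced cells, pooled-trial subtraction equals
cell-mean subtraction (regression-tested).

## Synthetic cohort generator

The generator emulates the *structure* of a three-group school-screening
study, not any individual child:

* **Groups** default to 39 ADHD / 34 subthreshold / 36 TD with the
  study-typical male proportions (29:10, 24:10, 17:19), ages ~ Normal per
  group ((10.6, 1.9), (11.0, 1.9), (11.6, 1.5) years, clipped to 6–13),
  and 12 schools.
* **Symptoms.**  Parent SNAP-IV symptomatic-item counts per subscale are
  drawn from group-conditional discretized Gaussians (ADHD: inattention
  (7.0, 1.0), hyperactivity (5.0, 1.6); subthreshold: (4.0, 0.7),
  (2.4, 1.0); TD: (0.2, 0.4), (0.1, 0.4)), expanded into 0–3 item scores;
  ASQ totals are Gaussian ((18, 3), (15, 2.5), (3, 2.5), clipped 0–30).
  The teacher report is the parent report with per-item ±1 perturbation at
  rate 0.05 and ASQ jitter, so informant agreement is imperfect.
  The opposition/defiance subscale is generated but ignored by diagnosis.
* **Diagnosis.**  A child is ADHD when both raters report ≥ 6 symptomatic
  (≥ 2) items on either subscale and ASQ ≥ 10; subthreshold when both
  raters reach at least the 3–5-item band (ASQ cutoff required of both
  raters by default; an `asq_requirement="either"` switch exists because
  the original rule is ambiguous on this point); otherwise TD.  The
  age-of-onset / two-setting impairment criterion is an always-true flag —
  questionnaires cannot simulate it.  Cohort generation rejection-samples
  reports until the rule reproduces the intended group, so labels arise
  from the reports; applied to raw (non-rejected) draws the rule recovers
  the intended group for ≈ 93–95 % of subjects.
* **Task parameters.**  Condition-mean RTs are ex-Gaussian
  (σ = 60 ms, τ = 120 ms within subject) with additive deltas for no
  alerting signal, invalid cue, and incongruent flankers; per-group latent
  means/SDs follow the study's descriptive table (e.g. TD congruent
  566.5 ± 129.5 ms, conflict 101.4 ± 33.7 ms).  Each subject's base RT is
  backed out of a drawn congruent-condition target so cohort condition
  means land on the configured values.  Error probability is 1.5 %
  (+6.5 % on incongruent trials); lapses (no-response) ~ clipped
  Normal(0.02, 0.01); MFT-M correctness follows the capacity model at the
  subject's true C ~ truncated Normal per group (2.73 ± 0.73,
  2.82 ± 0.71, 3.26 ± 0.61; floor 0.3 bits/s) and ceiling
  ~ Normal(0.985, 0.008).
* **Not emulated:** the population screening funnel and detection rates,
  comorbidity, ADHD subtypes, practice/fatigue effects, feature
  correlations beyond those induced by the shared latent structure, and
  RT–accuracy coupling within a condition.  Passing tests therefore show
  that the *pipeline* recovers the structure this generator encodes, not
  that the original study's effect sizes are reproduced.

A caveat on observed spread: latent between-subject SDs are set to the
published descriptive SDs, and trial-sampling noise adds on top, so
synthetic observed SDs run slightly (~5–10 %) above the published ones.

## Group inference

Chi-square tests of independence are Pearson statistics without continuity
correction — this choice reproduces the published contingency statistics
(6.87, 5.81, 1.18, 1.68, 0.1484, 0.0004) from their printed counts, which
corrected statistics do not.  Group comparisons are one-way ANOVAs with
sex, age, and school (categorical) as covariates, Type-III sums of squares
with sum-coded factors (SPSS-like), η² = SS_group/SS_total, and pairwise
contrasts of covariate-adjusted means (predictions averaged over the
observed covariate distribution) with Bonferroni correction.  Partial
correlations residualize both variables on the covariate design
(categoricals one-hot) and use df = n − 2 − k.  Fisher's z compares
correlations across independent groups using raw group sizes.  Bayes
factors are BIC approximations, `BF10 = exp((BIC0 − BIC1)/2)`, labelled by
the conventional 3 and 1/3 thresholds; they approximate, and do not
reproduce, default JZS Bayes factors.

Deficit cut points are TD deciles by linear interpolation between order
statistics: the 10th percentile of CCC and the 90th percentile of each RT
effect — i.e. the worst decile per measure, since large effects and low
capacity are both deficits.  (A `literal_tenth` switch applies the literal
10th percentile everywhere, as the published wording could also be read;
that tail holds the best performers for effects.)  Strictly-beyond-cut
flags a deficit; at-cut does not.

## Classification

Features (alerting, orienting, conflict RT effects, overall RT, CCC) are
z-scored (ddof = 1) across all subjects entering a classification — the
historical whole-sample convention, which leaks test information into
scaling; per-population scaling is applied separately for the two
cross-classification samples, and fold-wise scaling is the recommended
alternative for new work.  Each of the (default 1,000) repeats draws a
random ⌈N/10⌉ test subset (single-class test sets are resampled and
counted), trains a linear soft-margin SVM (C = 1), and scores test
accuracy; the baseline scores the same predictions against shuffled test
labels.  Significance is a one-sided one-sample t-test of the accuracy
vector against the mean baseline; feature sets are compared with
two-sample t-tests on their accuracy vectors.  A classical shuffled
10-fold partition mode (`mode="kfold"`) is available; the subsampling
mode is the default because it matches the common "1/10 randomly selected
as testing set" description.  Cross-prediction trains once on the full
ADHD+TD (or subthreshold+TD) population and evaluates on random tenths of
the other population.

On default synthetic cohorts both patient-vs-TD classifications exceed
their prevalence baselines decisively (p < 0.001), while ADHD-vs-
subthreshold accuracy sits only a few points above its 53.4 % baseline —
driven by the genuine overall-RT gap between the two clinical groups'
configured means, which is a real (if modest) discriminative signal.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed (package default
20220311); the pipeline derives per-stage sub-seeds from one global seed
via `SeedSequence.spawn`, and reruns are byte-identical.  Test and
recovery runs use full task schedules (144 ANT-I, 324 MFT-M trials per
subject); the capacity-recovery checks use the study-sized 36-subject TD
cohort for the mean-recovery check and 100 subjects per group for the
group-ordering/gap check, where the larger n narrows Monte-Carlo noise
well inside the assessment band.

## Known limitations

* The accuracy-model form is a design commitment; the original estimation
  script could differ in lapse handling or joint fitting of a0.
* The BIC Bayes factors and the Fisher-z inputs (raw n, not
  covariate-adjusted df) are approximations/conventions, flagged above.
* Synthetic cohorts cannot validate real-data effect sizes, correlations,
  or classification accuracies; they validate estimator correctness,
  calibration, and the qualitative group structure the generator encodes.
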