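# Methods

This note documents the models, the generator, the numerical choices, and
the limitations of `tempodisc`, in the order the pipeline runs them.

## Study design being emulated

Each subject completes two intertemporal-choice tasks and two timing tasks.

**Choice tasks.** The later option is one of 25 combinations of delays
{3, 7, 14, 30, 64} (seconds in SV, days in LV; a follow-up-style grid with
6.5 in place of 7 is configurable) and rewards {1, 2, 5, 8, 10} coins; the
sooner option is fixed at 4 coins now.  Each combination repeats
`reps_per_combo` times (default 8 → 200 trials per task), shuffled, with the
first half labelled session 1.  Discount factors are in task units (1/s and
1/day); the pipeline never converts between them — cross-task comparisons
are made on the log scale, where a unit mismatch is a constant offset that
correlations and regressions absorb.

**Timing tasks.** Estimation (report how long a stimulus lasted, typed as an
integer number of seconds) and production (press keys to delimit a named
interval), each over {3, 7, 14, 30, 64} s × 3 repetitions, in random order
(30 observations per subject; 5.9 min of scheduled stimulus time per task).

## Synthetic-data generator

Ground truth is hierarchical:

- $(\log k_{SV}, \log k_{LV})$ per subject from a bivariate normal with
  means (−3, −3), SD `sd_logk` = 1, correlation `rho_logk` = 0.6;
- $\log\tau$ from $\mathcal N(0, 0.3)$;
- one latent internal clock speed per subject,
  $\log ICS \sim \mathcal N(\log 0.9,\ 0.15)$ — the median below 1 reflects
  that most people in this population report time passing slower than a
  stopwatch.

Estimation and production are reciprocal views of the one latent clock:
$\alpha_e = ICS$ (a fast clock over-estimates durations) and
$\alpha_p = 1/ICS$ (a fast clock produces shorter intervals).  Mean reports
follow $ST(t) = \alpha\, t^{\beta}$ with $\beta$ = 0.95 (mildly compressive,
close to the linear regime that real fits mostly land in), multiplied by
$1 + \varepsilon$, $\varepsilon \sim \mathcal N(0, w)$ with Weber fraction
$w$ = 0.2 — multiplicative noise makes SD/mean constant across intervals
(scalar timing) with a single parameter.  Estimation reports are rounded to
the nearest integer ≥ 1 to match the response format; production reports are
floored at 0.1 s.  Choices are Bernoulli draws from the softmax-hyperbolic
probability at the subject's true parameters.

`coupling_gamma` adds $\gamma (ICS - 1)$ to $\log k_{SV}$ only — the
directional hypothesis that a clock can influence only experienced delays.
The default is 0: **the generator is a null world unless a coupling is
requested**, so downstream "no effect" findings on default data are the
correct outcome, not a failure.

What the generator does *not* emulate: session-order effects, payment
conversion, inter-trial dynamics, lapses of attention, counting strategies,
and any real-data violations of the hyperbolic/softmax form.  Passing
recovery tests therefore show the estimator is correct *under the model*,
not that the model is right for any particular human dataset.

## Hierarchical fit

The likelihood is Bernoulli with
$P(\text{later}) = \sigma\big((A/(1 + e^{\log k} D_{\text{eff}}) - s)/e^{\log\tau}\big)$,
using `delay_effective` so the objective and subjective-time variants share
one code path.  Random effects: subject-level $(\log k_{SV}, \log k_{LV})$
bivariate normal with free correlation; a single subject offset on
$\log\tau$ shared by both tasks.  Priors: $\mathcal N(-5, 3)$ on the
$\log k$ population means, $\mathcal N(0, 0.3)$ on the $\log\tau$ means,
half-normal(1) on random-effect SDs, uniform on the correlation.

Sampling is an adaptive Metropolis-within-Gibbs scheme written for this
model:

1. all subjects' 3-parameter blocks are proposed jointly and accepted
   element-wise (valid because subjects are conditionally independent given
   the population parameters) — one vectorised likelihood pass per sweep;
2. the $\log k$ population means are drawn exactly from their conjugate
   bivariate-normal conditional;
3. the random-effect SDs and correlation update by a 4-dimensional
   random-walk step that needs no likelihood;
4. the $\log\tau$ means update by a 2-dimensional random-walk step (these
   do enter the likelihood);
5. a recentering move shifts both $\log\tau$ means and all subject offsets
   in opposite directions — the likelihood is invariant along this ridge,
   which is otherwise the slowest direction of the posterior.

Proposal scales adapt toward ~28% acceptance during warmup only (Robbins–
Monro, $\gamma_t = t^{-0.6}$), so retained draws form a valid chain.
Retained draws = chains × (iterations − warmup); the production setting
(10 × (6000 − 2000) = 40,000) is the default, and reduced settings
(4 × 1500 with 500 warmup, or 2 × 900 with 300 warmup in the replicated
recovery study) are used for testing — draw counts there are a runtime
choice, not a correctness requirement.  Convergence is summarised by
split-R̂ and ESS (via arviz); any population-parameter R̂ > 1.05 raises a
warning and marks the fit unconverged rather than failing silently.

With 26 subjects × 200 trials/task, one reduced fit takes ~10 s on one CPU
core, and the subject-level $\log k$ recovery correlation is ≥ 0.9 per task
across 20 replicate datasets.

**Delay-insensitive subjects.** The operational flag (a within-subject
logistic regression of choice on delay with p > .05 *and* an overall
later-choice rate outside [.05, .95]) is a package decision — studies
typically exclude such subjects without stating a rule.  It is configurable
and not applied automatically by the pipeline.

## Subjective-time variants and model comparison

Per subject and timing task, $ST(t) = \alpha t^{\beta}$ is fit by nonlinear
least squares on the natural scale (log–log regression supplies start
values); the linear form fixes $\beta = 1$ and has the exact through-origin
solution.  Variant `subjTep` substitutes each SV delay by the subject's
estimation-task power fit, `subjTel` the estimation linear fit, and
`subjTpp`/`subjTpl` the production-task analogues; LV delays are never
transformed.  Subject-level (unpooled) fits are the default substitution.

K-fold comparison shares fold assignments across variants, stratified by
subject × task × offer so every fold sees every subject and the repeats of
an offer spread across folds — the comparison targets the functional form of
subjective time, not generalisation to new subjects.  Within each training
fold, each subject-task is fit by bounded maximum likelihood
($\log k \in [-12, 2]$, $\log\tau \in [-4, 3]$, multi-start L-BFGS-B), and
held-out trials are scored at the point estimate with a 1% lapse rate mixed
into the predictions ($p \mapsto 0.01 + 0.98\,p$).  The lapse cap matters:
an overconfident training fit at the $\log\tau$ boundary can otherwise
assign a held-out choice arbitrarily small probability, and a single such
trial can dominate the summed score and flip a ranking.

## Timing analysis

- **Outliers**: within each (task, interval) cell, reports strictly greater
  than 3× the cell mean (pooled across subjects, single pass) are dropped.
  Pooling matches a global outlier count; the boundary case (exactly 3×) is
  kept.
- **Ratios**: per-interval means use all kept repetitions (possibly < 3);
  MTeRatio/MTpRatio are unweighted means of the per-interval ratios, so
  intervals with unequal trial counts contribute equally.
- **ICS proxies**: the three equations are applied exactly.  When
  MTpRatio ≥ 2 the production reflection ($2 -$ ratio) would give a
  non-positive clock speed, so the subject's proxies are withheld
  (`ics_valid = False`) from ICS-based analyses while their data remain in
  everything else.
- **Scalar timing**: within-subject SDs are computed first (one SD per
  subject per cell) and pooled as the root mean square — an arithmetic mean
  of 3-trial SDs would be biased low by the $c_4$ factor (≈ 0.886) and would
  not reproduce the configured Weber fraction.  CV constancy is checked by
  the slope of CV on interval.  The estimation task's integer rounding adds
  ~1/12 of reporting variance, visibly inflating CV at the 3 s interval;
  the scalar-noise check is therefore sharpest on the production task.
- **KDE**: normal kernel at 100 equally spaced points, bandwidth
  $\hat\sigma (4/3n)^{1/5}$ (normal reference), grid extended 3 bandwidths
  past the data range so the density mass is captured.

## Inference

- **Pearson/TLS**: exact t-based p-values; the TLS line is the first
  principal axis of the centred scatter (SVD), symmetric in x and y.
- **Permutation tests**: 10,000 label shuffles by default; two-sided p with
  add-one smoothing, $(1 + \#\{|\text{null}| \ge |\text{obs}|\})/(S+1)$, so
  p > 0 always.  The null is built from the sorted pooled sample and the two
  group sizes, making the p-value invariant to which group is called which.
- **Drop-one regressions**: Gaussian linear models by maximum likelihood
  (not REML) so LR and AIC arithmetic is exact; each predictor is removed in
  turn, LR = 2Δll against χ²(1), ΔAIC = AIC_reduced − AIC_full, significance
  at .05/4 = .0125 (Bonferroni over the four predictors).  Inputs are the
  subjects' posterior-mean log discount factors — point values, unweighted
  by posterior SD.  The χ²(1) reference is asymptotic: its measured size is
  ~9% at n = 30 and reaches the nominal 5% by n ≈ 150, so calibration is
  verified in the asymptotic regime and small-sample use should expect some
  inflation.
- **Dependent correlations**: the Dunn & Clark (1969) z for nonoverlapping
  dependent correlations, with the Fisher-transform covariance determined by
  the six pairwise correlations; two-sided p reported with a one-sided
  companion since "is the subjective-time correlation better?" is
  directional.  This sub-test is a declared default among the family of such
  tests.
- **Power analysis**: smallest n such that the two-sided Fisher-z test of
  $H_0: \rho = 0$ reaches the target power, with the small-sample bias term
  $\operatorname{atanh}(r) + r/(2(n-1))$ and variance $1/(n-3)$.  At 80%
  power and α = .05 this gives n = 29 for r = .5 and n = 84 for r = .3.
- **Subgroup split** for the permutation comparisons: the sign of
  $\log k_{SV} - \log k_{LV}$ in task units (the TLS-residual-sign split is
  an available alternative and typically agrees).

## Pipeline and reproducibility

The master seed fans out to per-stage seeds through
`SeedSequence(master).generate_state(3) % 2^31` (simulate / fit / stats; the
fit stage further offsets by a fixed prime per variant), so a rerun with the
same config is byte-identical CSV for CSV, and single stages can be rerun in
isolation.  Every stage logs one structured line with the SHA-256 of each
file it writes.  Real data can be supplied as `choices.csv`/`timing.csv`
with the documented columns; tables are schema-validated with errors naming
the file, column and row.

## Known limitations

- The sampler is random-walk based; for much larger designs (hundreds of
  subjects) a gradient-based sampler would scale better.  Mixing has been
  verified (R̂, ESS) only for design sizes of the order tested here.
- K-fold comparison uses per-fold maximum-likelihood point estimates, not
  refits of the full hierarchical model; with ~150 training trials per
  subject-task the shrinkage foregone is small, but the comparison is not a
  full Bayesian cross-validation.
- The drop-one χ²(1) p-values inherit the asymptotic inflation noted above.
- Bayesian r² uses the residual-variance-on-probability-scale definition;
  other definitions exist and give slightly different values.
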