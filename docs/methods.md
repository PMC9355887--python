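# Methods

## Task protocol

A session consists of an optional practice block (32 trials) followed by 4
experimental blocks of 128 trials: 96 go trials (75%) and 32 stop trials
(25%), the stop trials split equally between two stop-stimulus conditions
(*emotional*, *neutral*). Trial order within a block is a seeded uniform
shuffle constrained to at most 4 consecutive stop trials (no ordering rule
is standard; the constraint only rules out degenerate runs). Arrow
directions are balanced 50/50 within each trial type and within each stop
condition per block. Fixation (800 ms), stop-signal duration (70 ms) and
ITI (1600 ms) are stored as metadata and never enter any computation.

Each condition owns an independent one-up/one-down staircase on its SSD:
start 150 ms, ±50 ms steps, clamped to [50, 650] ms. State persists across
all blocks of a session, practice included — the practice block therefore
pre-converges the tracks before the analyzed blocks begin, as a warm-up
block does in practice. Two invariants are enforced and tested: a track
never leaves the clamp range and stays on the `150 + k·50` grid, and
permuting one condition's outcomes never perturbs the other's trajectory.

## Race-model simulator

Trial outcomes follow the independent horse race. Go finish times are
ex-Gaussian with per-subject `mu` and shared `sigma = 60`, `tau = 115` ms;
the default `mu = 430` ms puts the mean go RT at ~545 ms. The stop process
finishes at `SSD + ssrt_true + Normal(0, 20)` ms. A stop-trial response is
emitted iff the go process wins; responses with `rt < SSD` are flagged
premature. Go trials omit a response with probability 0.005 and press the
wrong key with probability 0.015 (so ~98.5% of go trials are correct).
Trigger failures (the stop process never starting) are supported through
`p_trigger_failure` but default to 0. Go omissions are not applied to stop
trials: an omitted go process would be recorded as a successful stop, and
at the 0.5% default rate the distinction is negligible.

### Cohorts

The default cohort is 3 groups × 30 subjects with two conditions per
subject. Per group, the neutral-condition true SSRT is drawn around the
group mean (defaults 242.46 / 235.07 / 242.41 ms with between-subject SDs
35.12 / 52.68 / 46.06 ms), and the emotional-condition truth follows

```
ssrt_emotional = ssrt_neutral − advantage + slope · (BIS_np − cohort mean) + noise
```

with `advantage = 8.3` ms, `slope = 1.192` ms per BIS non-planning point,
and `noise ~ Normal(0, 15)` ms. Questionnaire covariates (STAI-Y2, HADS
anxiety/depression, BIS-11 motor/attentional/non-planning) are truncated
normals rounded to integers within instrument ranges, with per-group means
and SDs matching the modelled cohort; the BIS total is the sum of its three
subscales. Between-subject go-RT heterogeneity enters through
`go_mu ~ Normal(430, 120)` ms (floored at 150 ms).

**Empirical moments.** By default the generator rescales its between-subject
draws so the *realized* cohort moments equal the specified population
values exactly, and residualizes the index-noise vector against the four
regression covariates (the approach of `MASS::mvrnorm(empirical = TRUE)`).
A simulated cohort therefore realizes the stated study conditions rather
than one random draw from them, which is what parameter-recovery checks
measure; `empirical=False` restores fully random sampling. Trial-level
randomness is always genuine.

**Seeding.** One master seed; cohort-level parameters come from one spawned
stream and each subject's session from its own deterministic child stream,
so cohorts reproduce subject by subject and trial logs are byte-identical
across runs.

**Choice of the index-noise SD (15 ms).** No source specifies the latent
between-subject dispersion of the emotional-minus-neutral SSRT difference.
Reported paired t statistics for such contrasts at n = 30 imply a total
observed index SD near 20 ms; in this simulator the estimation noise alone
(below) contributes ~27 ms, so the latent term was fixed at 15 ms — the
same order as the moderation term across the BIS range — and not revisited.
A consequence worth knowing: the default cohort's *observed* index
dispersion exceeds what those t statistics imply, so a 2×3 mixed ANOVA on
full default-cohort pipelines detects the 8.3 ms stimulus effect in only
about two-thirds of replicates; the ANOVA op itself has >90% power at the
effect size those statistics imply (dz ≈ 0.41, n = 90), which is what the
sensitivity test checks.

## SSRT estimation

The integration method with go-omission replacement, blocks pooled per
session (the staircase runs across blocks, so condition-level pooling is
the natural unit): all responded go trials (choice errors and premature go
responses included) form the go-RT pool; each omission contributes one copy
of the subject's maximum observed go RT; `p(respond|signal)` counts
premature stop responses as failures to stop; the nth RT is the
`rank = ceil(N·p)`-th smallest pooled RT (rank clamped to [1, N]; `floor`
and `round` variants are switchable via `rank_mode`); SSRT = nth RT − mean
SSD over all stop trials of the condition, premature trials' SSDs included.
Estimation is undefined at `p ∈ {0, 1}` and raises; cohort summaries record
such conditions as missing rather than failing. Practice trials are
excluded from estimation by default.

The race-model check requires the mean unsuccessful-stop RT to be strictly
below the mean go RT (a censoring consequence of the independent race);
subjects with no unsuccessful stop trial are reported as undetermined.

### Known bias under the adaptive staircase

With the SSD *fixed*, the estimator recovers the generative stop latency
within 3 ms at large trial counts (tested). Under the one-up/one-down
staircase the SSD oscillates one to three steps around its equilibrium
while the go-RT quantile function is convex near the median of a
right-skewed distribution, so the single-quantile-minus-mean-SSD
construction sits a few milliseconds below the generative value (Jensen's
inequality applied to `q(p)` over the visited SSDs). With the default
ex-Gaussian parameters and 64 staircase-tracked stop trials per condition
this shows up as a ~5–8 ms shortfall in the recovered group mean — visible
in the acceptance recomputation of the generative-mean recovery target,
which lands below its nominal ±5 ms window for most seeds. Field estimates
derived from tracking designs carry the same property, so a published
group-mean SSRT is itself ~5 ms below the latent latency this simulator
would need to reproduce it exactly.

Estimation noise at the protocol's trial counts is ~19 ms SD per condition
(dominated by the mean-SSD random-walk average, with a smaller
order-statistic term from the 384-trial go pool), hence ~27 ms SD on the
index; per-condition errors are essentially uncorrelated because the two
staircases are independent.

## Statistical battery

* **Mixed 2×3 ANOVA** (stimulus within × group between) and the generic
  two-way fully-within ANOVA are delegated to pingouin; partial eta squared
  is `SS_effect/(SS_effect + SS_error)` (recovered through
  `F·df1/(F·df1 + df2)` where pingouin reports generalized eta squared).
  Zero-variance effects report `F = 0, p = 1` rather than NaN. Post hocs
  are Bonferroni-adjusted pairwise tests. Both routes are verified against
  brute-force cell-means sums-of-squares oracles on small balanced designs;
  designs here are balanced, so sums-of-squares types coincide.
* **JZS t Bayes factor**: `BF10 = ∫ nct(t; ν, √n·δ) Cauchy(δ; 0, r) dδ /
  t(t; ν)` by adaptive quadrature, default `r = 0.707`; cross-checked
  against an independent implementation to 1e−6.
* **Default g-prior ANOVA BF**: sum-to-zero fixed-effect projection with
  iid `N(0, g·σ²)` effects and `g ~ InvGamma(1/2, r²/2)` (`r = 0.5`), μ and
  σ² integrated under flat/Jeffreys priors; Monte Carlo over g (50,000
  seeded draws, vectorized through the eigendecomposition of X′X) with the
  Monte-Carlo SE reported. A two-level within design reduces exactly to the
  one-sample problem with effective Cauchy width `r·√2`, which is how the
  Monte-Carlo route is validated against the quadrature route.
* **Correlation BF**: exact reduced likelihood of the sample correlation
  (Gaussian-hypergeometric form) integrated against a stretched-beta prior
  (width 1 = uniform on (−1, 1)); validated against a 200,001-point
  Riemann grid and an independent implementation.
* **Repeated-measures power**: `P(F′ > F_crit(α; m−1, (n−1)(m−1)))` with
  noncentral F. Default noncentrality convention is the G*Power
  within-factors effect-size correction `λ = n·m²·f²/(1−ρ)` (i.e.
  `f′² = f²·m/(1−ρ)`, `λ = f′²·n·m`), which reproduces the sample-size
  claims this battery is meant to mirror; the textbook
  `λ = n·m·f²/(1−ρ)` is exposed as `convention="classical"` and is
  distinctly more conservative. Sample-size search is monotone bisection.
* **SSRT-index regression**: full-entry OLS of the per-subject index on
  STAI-Y2 and the three BIS subscales, then a one-shot outlier pass —
  standardize residuals by the initial fit's residual σ, drop |z| > 2,
  refit once. Standardized (not raw) residuals are used, and removal is not
  iterated. A classic p-to-enter/p-to-remove stepwise mode (.05/.10) exists
  behind a flag but is off by default, since a full-entry model is the
  transparent default for four predictors.

## Numerical and degenerate-input conventions

Durations are milliseconds throughout. Quadrature failures raise with
diagnostics instead of returning garbage. `BF10·BF01 = 1` holds to 1e−9 by
construction. Chi-square uses no continuity correction. Paired t with
zero-variance differences, correlations of constant input, single-group
ANOVAs, rank-deficient regressions and unknown staircase conditions all
raise typed errors (`ZeroVarianceError`, `ValueError`, `ProtocolError`);
the CLI maps schema violations to exit code 2 and undefined estimation
(under `--strict`) to exit code 3.

## What the synthetic cohorts do and do not show

The generator emulates the study design this package models: ex-Gaussian
go RTs (~545 ms), ~98.5% go accuracy, staircase-driven ~50% inhibition
(grand means land at 50–51% with the practice warm-up; slightly above 50%
without it because the track climbs from 150 ms), a small emotional
stopping advantage moderated by non-planning impulsivity, and group-matched
covariates. It does not model sequential effects (post-stop slowing),
proactive inhibition, trigger failures (off by default), fatigue or
block-order effects, or any dependence of go RT on the emotional content of
stop stimuli. Passing recovery tests therefore show the estimator and
battery are faithful to this generative model — not that real SST data meet
its assumptions.

## Problem sizes

Cohort-level checks use full sessions (544 trials/subject). The convergence
and recovery checks use 30-subject groups; replicate-based checks
(regression coverage, type-I calibration, ANOVA sensitivity) use 100–1000
replicates at the subject-summary level and 100 full-pipeline cohorts for
the regression coverage — sizes chosen to keep Monte-Carlo error well below
each test's tolerance.
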