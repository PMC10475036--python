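# Methods

## Scientific setting

`sociallearn` models how people revise their self-perception after social
feedback, and how that revision is biased by valence in social anxiety.
The emulated task is a speech-feedback paradigm: a participant prepares and
gives a speech, then over 52 trials rates themself on short evaluative cues
(visual-analogue scale, VAS, coded 0–1), sees judges' feedback on the same
scale, and rates their momentary state self-esteem. About 20 minutes later
they re-rate every cue (T2). Two groups are simulated: a social-anxiety-like
(SAD) group and a non-anxious control-like (HC) group.

Because no public trial-level dataset exists for this design, the package
pairs every estimator with a synthetic-cohort generator whose ground truth
is known, so the whole pipeline can be validated by parameter recovery
rather than by reproducing any specific dataset.

## Valence coding

Cues are positively or negatively worded ("I was convincing" vs. "I looked
anxious"). All ratings on negatively worded cues are recoded to a
favourability scale (`1 − rating`) before analysis, so that the feedback
mismatch

    ΔEval = feedback_val − self_eval_t1_val

is uniformly signed: ΔEval > 0 always means "the judges saw me more
favourably than I saw myself". Both raw and recoded values are stored in
the trial table. This recoding is a modelling choice the analysis requires;
without it the sign of ΔEval would mean different things for the two cue
wordings.

## Models

### Valence-split social influence (T2 re-evaluation)

    SelfEval(T2) = SelfEval(T1) + β_pos·ΔEval   if ΔEval > 0
    SelfEval(T2) = SelfEval(T1) + β_neg·ΔEval   if ΔEval < 0

Per subject this is OLS of the change `T2 − T1` on the two sign-gated
mismatch regressors. The T1 coefficient is fixed at 1 and there is no
intercept by default (the model above has none); an opt-in intercept flag
exists. Trials with ΔEval exactly 0 carry no valence information and are
excluded (the generator avoids them). The **social influence bias** is
`β_pos − β_neg`.

### Asymmetric Rescorla–Wagner updating (state self-esteem)

    Feeling(t) = Feeling(t−1) + α_pos·APE   if APE > 0
               = Feeling(t−1) + α_neg·APE   if APE < 0
    APE        = V_feedback(t) − Feeling(t−1)

with free parameters `prior` (the pre-task state; the first observed
self-esteem rating is compared against the model's post-update value for
trial 1), `α_pos`, `α_neg`, all constrained to [0, 1]. Each update is a
convex move toward a value in [0, 1], so trajectories are provably bounded.
`V_feedback` is the valence-recoded feedback value, which puts the
prediction error and the state on the same scale. The **affective updating
bias** is `α_pos − α_neg`.

Fitting minimises the SSE between the observed and modelled self-esteem
time course with L-BFGS-B under box constraints. Local optima are real for
this model, so the optimiser is launched from every point of a
{0.1, 0.5, 0.9}^k start grid (27 starts for the 2-rate model, 9 for
1-rate; convergence tolerance 1e−8) and the best SSE wins; a test checks
the result against an exhaustive 0.02-step grid scan. Missing self-esteem
ratings are dropped from the SSE while the recursion still advances on
their feedback. An all-constant series is returned as a degenerate
zero-learning fit with a flag, not an error.

Model comparison uses the Gaussian least-squares BIC,
`n·ln(SSE/n) + k·ln(n)` with k = 2 (1-rate) or 3 (2-rate); the profiled-out
noise variance is omitted from k identically in both models, so only the
difference is meaningful. A perfect fit returns −∞ as an explicit sentinel.
Both per-subject counts of BIC preference and summed-across-subjects BIC
are reported, since either aggregation is defensible.

### Group-level inference

Second-level analysis uses the summary-statistics approach: per-subject
estimates are carried into Student's paired t-tests (within group) and
Welch's unequal-variance t-tests (between groups), two-sided, α = 0.05,
uncorrected — matching standard practice for this design. Effect sizes are
derived from the t statistics: independent-samples
`d = t·√(1/n₁ + 1/n₂)`, paired `d_z = |t|/√n`. These conversions reproduce
most reported (t, d) pairs for this design exactly at two decimals; a few
published pairs deviate by ~0.01 (probably computed from raw SDs, which a
t-statistic conversion cannot recover), which is why the acceptance checks
carry a small tolerance for those.

The bias intercorrelation is tested by Pearson correlation and by partial
correlation controlling for group (residualising both biases on the group
indicator with an intercept; p from t with n − 3 df). Robust regression is
IRLS with Huber weights (tuning constant 1.345, MAD scale, max 50
iterations, tolerance 1e−8; Tukey bisquare available by flag), delegated to
statsmodels' RLM.

### Multilevel mediation

For each subject and mediator region, three OLS regressions (with
intercepts, variables z-scored within subject by default) give paths
a (X→M), b (M→Y|X), c (X→Y), c′ (X→Y|M), and ab = a·b. The OLS identity
c = c′ + ab holds exactly per subject and is asserted to 1e−10. At the
second level each path gets a one-sample t-test across subjects, and the
mean ab a bias-corrected percentile bootstrap CI (default 5,000 resamples
of subjects; bias-corrected because the product term is non-normal). A
significant ab whose sign opposes c is classified as *suppression*. The
conjunction operation returns regions significant on a, b and ab
simultaneously. This is a deliberate simplification of weighted multilevel
mediation estimators: transparent, desk-scale and directly testable.

One calibration fact worth knowing: the one-sample t-test on the product
term is conservative in small samples (empirical type-I rate ≈ 0.017 at 20
subjects/cohort) and near-nominal at the study's cohort size (≈ 0.04 at 44
subjects). Calibration suites therefore run at 44 subjects per cohort.

### Network-mask similarity

A subject's contrast vector over a common parcel grid is scored by its
Pearson correlation with a binary network mask, Fisher-z transformed
(`arctanh`). Up to a monotone transform this equals the standardized
in-mask vs out-of-mask mean difference (point-biserial identity). A map
exactly equal to the mask gives |r| = 1 and raises a domain error rather
than returning an infinite z. The default grid is an abstract 1,000-parcel
vector with 20% of parcels in-network; volumetric masks can be flattened to
the same representation upstream without changing the operation.

## The synthetic-cohort generator

Defaults mirror the emulated study: 52 trials, 21 SAD-like and 23
control-like subjects, cue wordings split exactly half positive / half
negative per subject.

* **T1 self-evaluation**: subject trait mean + N(0, 0.05), clipped to [0, 1].
* **Feedback**: centred on the subject's own rating with a Gaussian
  mismatch, SD 0.15 VAS (a value that keeps most feedback within the scale
  while making mismatches clearly visible on it). The cohort path draws
  sign-balanced mismatches — half-normal magnitudes with an exactly
  half/half sign permutation, which leaves the marginal distribution
  unchanged — so every subject has the positive-mismatch count within ±2 of
  26, as the task design intends ("approximately half of trials" each
  sign). Mismatches zeroed by clipping at the scale bounds are redrawn.
  The standalone `draw_feedback` operation is the unconditioned draw with a
  single redraw of exact-zero mismatches.
* **State self-esteem**: the asymmetric RW trajectory plus N(0, 0.05),
  clipped. Generated ratings are clipped at the VAS bounds; the fitted
  models themselves are never clipped (they mirror the printed equations).
* **T2 re-evaluation**: the valence-split influence model plus N(0, 0.05),
  clipped.
* **Group parameter distributions** (configurable, truncated normal with
  SD 0.1): SAD-like β = (0.3, 0.5), α = (0.2, 0.4), prior 0.4, trait 0.4;
  control-like the mirror image (β = (0.5, 0.3), α = (0.4, 0.2), prior 0.6,
  trait 0.6). This puts the mean influence and updating biases at −0.2
  (SAD) and +0.2 (HC) — opposite-signed group biases of the size needed to
  produce group-by-valence interactions of roughly the reported magnitude
  at n = 21/23.
* **Latent bias coupling**: a shared standard-normal factor loads with
  √0.3 on the positive member and −√0.3 on the negative member of both the
  β and α pairs, leaving marginal means/SDs unchanged while making the two
  valence biases intercorrelate within group (population r = 2ρ/(1+ρ) ≈ 0.46
  at ρ = 0.3) — matching the empirical observation that the two biases
  covary beyond the group split.
* **Mediators**: region r gets `M_r(t) = a_r·z(ΔEval) + e_r` with
  e_r ~ N(0, 1); the noise component feeds into the T2 outcome as
  `0.02·Σ b_r·e_r` (VAS units). Routing only the noise component through
  the b-path keeps the zero-noise cohort exactly identified while giving
  the mediator genuine outcome variance beyond X; the OLS paths recover
  a_r on the a-side and a b-effect proportional to b_r. Default region
  paths (a, b): (0.5, 0.5), (0.5, 0), (0, 0.5), (0, 0) — a true mediator,
  an a-only region, a b-only region, and a null region.
* **FPN stage**: per-subject synthetic contrast maps put a mean shift of
  0.05 (HC) vs 0.00 (SAD) plus 0.08 × (subject influence bias) on in-mask
  parcels over unit noise. These scales were chosen so the default pipeline
  produces group differences (d ≈ 0.8) and bias correlations (ρ ≈ 0.4) of
  the magnitude reported for this design, rather than caricature effects.
* **RNG discipline**: one master seed; each subject draws from an
  independent `SeedSequence` substream, so cohorts are reproducible under
  subject-level parallelism and byte-identical across re-runs.

### What the generator does *not* emulate

No BOLD time series, HRF convolution or scanner artefacts (mediator
amplitudes stand in for single-trial GLM betas); no actual cue texts or
cue-specific semantics; no within-wording balancing of mismatch sign (only
overall balance); no missingness, attention lapses, response-time
structure, or scale-use idiosyncrasies (anchoring, digit preference).
Passing recovery tests therefore show the estimators are correct and
well-calibrated *for data generated under the models' own assumptions* —
they do not certify robustness to the violations real rating data contain.

## Problem sizes and numerical choices

Simulation suites run at sizes chosen to give stable rates while keeping a
full validation run in a few minutes on one CPU: 100 subjects for recovery
and BIC selection, 500 cohorts for the mediation type-I rate, 100 cohorts
(40 subjects, 2,000 bootstrap resamples) for CI coverage, 100 cohorts for
interaction power, 10,000 replicates for t-test calibration. The
Monte-Carlo oracle for the true standardized indirect effect uses 300
subjects × 2,000 trials. Optimiser tolerances are stated above; exact-OLS
solutions use `numpy.linalg.lstsq`. Ties: APE = 0 updates nothing (both
branches agree); ΔEval = 0 trials are excluded from the influence model.

## Known limitations

* The mediation second level is a summary-statistics t-test + subject
  bootstrap, not a weighted hierarchical estimator; with very noisy
  first-level paths it is less efficient.
* The BIC form assumes Gaussian residuals on a bounded scale; with heavy
  clipping (extreme priors or feedback) the approximation degrades.
* Cohen's d conversions cannot reproduce published values computed from
  raw SDs; discrepancies at the second decimal are expected for those.
* The generator's group parameter distributions are plausible, not
  estimated from data; absolute simulated effect sizes should be read as
  design-scale illustrations, not predictions.
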