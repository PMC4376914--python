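# Methods

This note documents the statistical models the package implements, the
choices made where several defensible options existed, and what the
synthetic-data generators do and do not emulate.

## Crossed random-intercept mixed models

Every rating model has the form

    y_ij = x_ij' β + u_s(i) + v_t(j) + e_ij,
    u ~ N(0, σ_s²), v ~ N(0, σ_i²), e ~ N(0, σ_e²),

with subjects and items (risky scenarios or risk domains) as *crossed*
random intercepts — both groupings offset every observation additively,
which is the appropriate structure when each subject rates every item.

**Estimation.** The solver maximizes the profiled (RE)ML deviance over the
two log variance ratios log(σ_s²/σ_e²), log(σ_i²/σ_e²); β and σ_e² have
closed-form profiles.  Because the random-effects design is a two-block
indicator matrix, the Woodbury identity reduces each deviance evaluation to
a Cholesky factorization of the (n_subjects + n_items)-square capacitance
matrix, so a Study-1-size fit (600 rows) takes ~10 ms and the calibration
simulations below re-fit thousands of models comfortably.  The optimizer is
seeded from the best point of a fixed 5×5 grid and refined by L-BFGS-B
(with a short simplex polish on failure); optimizing log-ratios handles the
σ² → 0 boundary smoothly, so no fallback to a simplified random structure
is ever needed.  Fixed-effect covariances come from σ̂²(X'V̂⁻¹X)⁻¹.  The
implementation reproduces statsmodels `MixedLM` (variance-components
formulation) to ~1e-6 on fixed effects and ML log-likelihood; the test
suite checks this and, independently, a brute-force GLS oracle that inverts
the marginal covariance directly.

**Coefficients vs. model comparison.** Reported path coefficients come from
REML fits.  Likelihood-ratio tests compare models with different fixed
effects, where REML likelihoods are not comparable, so both models are
refit by ML on identical rows.  The profiled deviance is nearly flat when
the added terms contribute nothing; χ² values within optimizer noise of
zero (|χ²| < 0.01) are clamped to zero, and a nested full model that still
scores below its baseline is refit warm-started from the baseline's
variance ratios before any error is raised.

## Serial two-mediator mediation

The chain X → M₁ → M₂ → Y is estimated by three mixed models (see README).
Subject-level covariates (trait anxiety, risk propensity) enter only the Y
model, because they are outcome-side confounds of risk-taking propensity.
The three-path indirect effect a₁·d₂₁·b₂ gets a Monte-Carlo percentile CI:
k independent draws per path from N(estimate, SE²), default k = 100 000,
2.5th/97.5th percentiles with linear interpolation.  Draws for the three
paths are independent — they come from three separately fitted models — and
the interval is reproducible bit-for-bit given (seed, k).  Effects are
unstandardized throughout.

## Blood-pressure reduction

MAP = ⅔·diastolic + ⅓·systolic per cuff reading.  Of the canonical 20
readings (8 pre-baseline, 1 training, 5 scenario visualizations, 6
post-baseline), the first three pre-baseline readings (laboratory
habituation), the training reading, and the first post-baseline reading
(post-stress recovery) are discarded; the remaining 15 are z-scored within
subject using the sample SD (n−1) — the conventional choice in
psychophysiology.  Within-subject z-scoring removes stable individual
differences in absolute pressure, so the five visualization z-scores are
comparable stress indicators across subjects.  The phase contrast is a
3-level repeated-measures ANOVA on the per-subject phase means with
uncorrected paired t follow-ups.  A series whose retained MAPs are all
identical has no defined z-score and is rejected explicitly.

## EEG processing and the Imagery Alpha Index

* **Filter**: the signal mean is removed, then a linear-phase FIR band-pass
  (0.1–35 Hz, Hamming window, default 801 taps = 4 s at 200 Hz) is applied
  with group-delay compensation, i.e. zero phase.  Explicit demeaning is
  needed because no practical-length FIR can null DC when the high-pass
  edge sits at 0.1 Hz; the analysis consumes only 8–13 Hz power, far above
  the <1 Hz transition band.  The filter's edge response smears ~4 s across
  segment boundaries, which perturbs alpha power by ~1e-4 relative — the
  tests' "exact" IAI recovery tolerances reflect that.
* **Epochs**: consecutive non-overlapping 2 s windows per event segment
  (400 samples at 200 Hz; 0.5 Hz spectral resolution); partial trailing
  windows are discarded and no sample is used twice.
* **Artifacts**: an epoch is rejected iff any |amplitude| exceeds 70 µV
  (the amplitude criterion; a peak-to-peak variant is available via
  `criterion="peak_to_peak"`).  Because the threshold is absolute, IAI
  scale invariance holds in the form IAI(c·x, c·threshold) = IAI(x,
  threshold).
* **Alpha power**: rectangular-window periodogram per epoch; mean spectral
  density over the bins in [8, 13] Hz inclusive (11 bins); mean over kept
  epochs.  For a pure sinusoid of amplitude A at an exact bin this equals
  A²/11, the Parseval oracle the tests use.
* **IAI**: mean alpha power of the two baseline (weather) segments —
  averaged with equal weight regardless of epoch counts, full segment
  duration — divided by the mean power of the two scenarios of a risk
  domain, per subject × electrode × domain × phase.  Listening-phase IAIs
  are computed identically to support the phase contrast.  Moderation uses
  the visualization-phase IAI averaged over the imagery electrodes O1, O2,
  P3, P4.

## Moderation and Johnson–Neyman

Step 1 fits risk taking on risk perception and mean IAI (crossed random
intercepts); step 2 adds their product; the interaction is tested by an ML
likelihood-ratio χ²(1).  Predictors are not mean-centered, keeping
coefficients on the raw rating/IAI scales.  The conditional slope is
θ(w) = b₁ + b₃w with SE(w) = √(v₁₁ + 2w·v₁₃ + w²·v₃₃); pick-a-point values
default to the moderator mean ± 1 SD computed across analysis rows (the
modeling unit).  Johnson–Neyman boundaries are the real roots of
(b₃² − t²v₃₃)w² + 2(b₁b₃ − t²v₁₃)w + (b₁² − t²v₁₁) = 0 inside the observed
moderator range; at each boundary the pointwise CI touches zero to 1e-8,
and a 1e-4-step grid scan agrees with the analytic roots (tested on 100
random coefficient/covariance draws).  The critical value is Student t with
df = n_obs − p by default (`df_method="z"` switches to 1.96); mixed models
admit several df conventions and this one is recorded in the output.

## Synthetic-data generators

The generators draw from exactly the models above, so recovery tests are
well-posed; all randomness flows from one integer-seeded generator and
identical (config, seed) gives byte-identical output.

* **Study 1** (60 subjects × 10 scenarios in 5 risk domains): recoded
  thought valence x from a truncated normal on [−2, 2] (mean 0.83, SD 0.98,
  matching the observed valence distribution), default paths a₁ = 1.0,
  a₂ = 0.3, d₂₁ = 0.5, b₁ = 0.1, b₂ = −0.6, c′ = −0.15; variance
  components 0.25/0.09/1.0 (subject/item/residual).  Trait anxiety loads on
  the subject-level mean of x (r ≈ 0.5 at the subject level) and risk
  propensity on the outcome, mirroring the covariate structure the analyses
  adjust for.  Residual SDs can be overridden per response; a response with
  zero residual noise is exactly linear in its predictors (the basis of the
  exactness tests), but a noiseless *mediator* makes downstream designs
  rank deficient, which the fitter reports rather than hides.
* **Study 2** (22 subjects × 5 domains): vividness on [1, 10], paths
  0.64/0.52/−0.64/0.10 as in the vividness-driven chain.  Blood pressure:
  subject resting MAP ~ N(90, 7²) mmHg, reading noise SD 3 mmHg (cuff
  error), visualization elevation 4.6 mmHg scaled by the subject's relative
  vividness — calibrated so the mean visualization z-score is ≈ +0.8 — and
  systolic/diastolic reconstructed from MAP and a drawn pulse pressure so
  the MAP formula inverts exactly.  PANAS: pre-test PA ≈ 30, NA ≈ 15,
  shifts −2.5/+2.67 with change SD 5, clipped to [10, 50].
* **Study 3** (16 subjects, 10 scenarios, 5 domains): imagery factor
  g ~ truncated N(1.06, 0.06²) on [0.85, 1.35] (the true IAI); ratings from
  y = 31 − 3.5·risk − 25·g + 3·risk·g + effects, which puts the simple
  slopes near −0.5/−0.4/−0.25 across the g range.  EEG: 10 Hz alpha carrier
  of 20 µV with white noise (SD 5 µV), baselines 120 s (4× a risky
  scenario), listening and visualization 30 s; during risky visualization
  the parieto-occipital amplitude is A/√g so the measured power ratio is
  exactly g, while prefrontal channels stay unmodulated as control sites.
  5% of epochs receive a 150 µV artifact pulse, reproducing the expected
  rejection rate.

**What the generators do not emulate**: real EEG morphology (1/f background,
eye blinks, spindles, alpha non-stationarity), discreteness of rating
scales (off by default; `discretize=True` rounds and clips), beat-to-beat
blood-pressure dynamics, and item-content effects beyond additive item
intercepts.  Passing tests therefore establish the correctness and
calibration of the *statistical machinery* under the assumed models, not
robustness to violations such as heavy-tailed noise or informative
missingness.

## Simulation sizes and calibration results

The acceptance-style checks run at the default study scales: path recovery
over 200 cohorts (each path's mean within 2 Monte-Carlo SEs of truth),
Monte-Carlo CI coverage over 500 replicates (93–97% band around the nominal
95%), and type-I error of both likelihood-ratio tests over 500 null
replicates each (3–7% band around α = 5%).  `scripts/acceptance.py` uses
100/300/300 replicates for its summary numbers, which keeps the whole
script near one minute; the reported rates carry binomial noise of roughly
±1.3 percentage points at those sizes.

## Known limitations

* Degrees of freedom for simple-slope t-tests use the residual df
  convention n_obs − p; Satterthwaite/Kenward–Roger approximations are not
  implemented.
* The Monte-Carlo CI treats the three path estimates as independent; a
  joint-normal variant using each model's covariance would only matter if
  paths shared a model, which they do not here.
* Listwise deletion per model is the only missing-data strategy.
* No bootstrap CIs, moderated mediation, categorical mediators, or
  between-subject factors.
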