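# Methods

## The score

CMEA is the fraction of a frame's endoscopy view occupied by clearly
exposed mucosa; CCMEA is its sum over all qualified frames of a withdrawal.
Three modelling commitments follow directly from the definitions:

* **Normalization by the view, not the frame.** Different endoscope
  manufacturers crop the optical field differently; dividing by the view
  area makes CMEA comparable across devices. Consequently an empty view is
  an error, never a zero — such frames must be filtered as unqualified
  before the metric is reached.
* **Dimensionless accumulation.** CMEA is a ratio, so pixel scale cancels
  and CCMEA carries no physical units. It does, however, scale linearly
  with the *frame rate*: the same withdrawal sampled at twice the rate
  accumulates twice the CCMEA. The qualification threshold (2000 under the
  bundled calibration, at 25 frames/s for synthetic fixtures) is therefore
  only meaningful at its calibration rate. Every `ProcedureRecord` stores
  `sampling_rate`, and the accumulator takes it explicitly rather than
  hiding it.
* **Chromoendoscopy suspends, others zero.** Dye-spray imaging is
  diagnostic, not inspectional, so those frames are counted separately and
  contribute nothing; accumulation resumes automatically when white-light
  frames reappear (per-frame classification is stateless, so no explicit
  re-entry logic exists to get wrong). All other unqualified classes also
  contribute exactly zero. A CCMEA exactly at threshold counts as
  qualified.

Invariants the test suite enforces: `0 ≤ CCMEA ≤ n_qualified`; additivity
over stream concatenation; monotonicity under appending frames; exact
equality with the generator's analytic CCMEA when truth-oracle backends are
used.

## Backends instead of networks

The clinical implementations of frame filtering (a ResNet-class
classifier) and view/exposure segmentation (UNet-class models) are not
reproducible without their weights and training data. The pipeline
therefore defines *backend contracts* — anything with
`classify(frame) -> Classification` or `predict(frame[, view]) -> mask` —
and ships:

* **Photometric baselines.** Frame QC: mean luminance below
  `dark_frame_max` (0.08) → in-vitro; blue-hue coverage (hue in
  [0.50, 0.78], saturation ≥ 0.25, over ≥ 40% of in-body pixels) →
  chromoendoscopy; Laplacian-energy variance below `sharpness_min`
  (8e-5) → blurred; otherwise qualified. View segmentation: luminance
  threshold (0.05) above near-black, hole filling, largest connected
  component, convex closure (computed without half-pixel corner offsets,
  which would systematically overshoot a discretized disk). Exposure
  segmentation removes, inside the view: specular pixels (luminance ≥ 0.9,
  saturation ≤ 0.15), dark pixels (luminance ≤ 0.1), fecal/occlusion
  pixels (hue 0.04–0.14, saturation ≥ 0.3, value ≤ 0.65) and desaturated
  instrument-gray pixels, then removes objects/holes below 16 px.
* **Truth oracles** returning the generator's labels and masks, used to
  isolate stages downstream of perception.

The three unqualified classes without a photometric signature (flushing,
instrument, operation) remain in the taxonomy but are never emitted by the
baseline; only a stronger backend can produce them.

All thresholds live in config dataclasses (`QcConfig`, `SegConfig`), were
calibrated once on the phantom fixture set at its default 128×128 rendering
(the sharpness threshold sits at the geometric midpoint of the Laplacian
energies on either side of the blur-label bound), and are logged per run.
They are resolution-dependent: rescale before applying the baselines to
frames of a very different size.

## Synthetic phantoms

A phantom frame reproduces the *photometric structure* the baselines key
on, not endoscopic appearance: a bright textured pink-red disk (or rounded
rectangle) on a near-black background, with artifact blobs colored so each
class is separable in HSV space (white desaturated specular, brown fecal,
near-black dark, gray instrument), optional global blue tint for
chromoendoscopy, and Gaussian blur. The ground-truth exposure mask is the
view minus the artifact union *by construction* — the generator renders
exactly what it reports, which is what makes exact oracle-equivalence
tests possible. Artifact budgets are requested area fractions of the view;
random disk placement overshoots them slightly (the truth masks always
reflect what was actually rendered), and a budget sum of 1 sweeps the
remaining view pixels into the largest class so full occlusion is exact.

What phantoms do **not** emulate: real mucosal texture, folds and haustral
shadows, lighting gradients, motion artifacts other than isotropic blur,
or the flushing/instrument/operation classes. Passing tests therefore
demonstrate pipeline correctness (metric arithmetic, suspension logic,
streaming, calibration machinery) and baseline self-consistency on
separable imagery — not segmentation performance on real endoscopy, which
is explicitly out of reach without the trained models.

## Synthetic cohorts

`CohortGenSpec` generates per-patient tables with an explicit generative
model: CCMEA ~ Gamma(2.4, scale 1000) per center (right-skewed, spanning
several 1000-wide bins, ~53% of patients above 2000); adenoma presence is
Bernoulli with logit

```
β₀ + β_c (CCMEA − c_half) + β_sex·male + β_ind[indication] + u_center
```

with defaults β₀ = logit(0.25), β_c = 8e-4, c_half = 2000 (so the
*baseline-covariate* 25% point sits exactly at 2000; with the default
covariate mix the *marginal* ADR curve crosses 25% near CCMEA ≈ 1600,
inside the [1000, 2000) bin), β_sex = 0.35, indication effects 0/0.15/0.40,
u_center ~ N(0, 0.3). Covariate marginals (46.7% male; indications
21.8/61.9/16.3%) match the validation study's screening population. Lesion
counts: the adenoma count is 0 or 1 plus a CCMEA-dependent Poisson
overcount; non-adenomatous polyps are Poisson with a gamma frailty
(shape 0.6) making counts overdispersed like real lesion counts (SD >
mean) — without the frailty a marginal Poisson cannot match the observed
mean counts and detection rates simultaneously. Polyp count ≥ adenoma
count ≥ 0 holds structurally. The generating probability is stored per
patient (`p_adenoma`) so calibration tests compare empirical bin ADRs to
the model's own expectation rather than to a hand-waved constant.

At these defaults a 2000-split yields group-level rates near the
validation study's: ADR ≈ 56% vs 20%, mean polyps ≈ 5.8 vs 1.3. The
two-group recovery generator (`generate_two_group_cohort`) is anchored the
same way: baseline logit(0.142) for the binary outcome and log(1.3) for
the count outcome, the unqualified group's observed ADR and mean polyp
count.

## Threshold calibration

Patients are binned by CCMEA in half-open 1000-wide intervals (a value of
exactly 2000 falls in [2000, 3000)); the per-bin ADR is fitted with a
saturating logistic `L / (1 + exp(−k(c − c₀)))`, weighted by bin size
(σ ∝ 1/√n), bounds L ∈ (0, 1], k > 0. The logistic is the minimal bounded
increasing dose-response family; when `curve_fit` fails the fit falls back
to size-weighted isotonic regression (flagged), and bins sharing a single
ADR yield a flagged constant curve. The threshold is the smallest
bin-width multiple at which the *fitted* curve exceeds the ADR target
everywhere up to the top of the binned range (raw-bin mode is available;
raw bins can be non-monotone from sampling noise, which is why the fitted
curve is the default). An unreachable target returns an explicit
no-qualifying-threshold result, never a silent maximum. Thresholds are
restricted to bin-edge multiples deliberately: the calibration procedure
reads a coarse binned curve, and finer granularity would over-read it.

## Cohort statistics

* **Rates** are exact integer ratios; display rounding is half-away-from-
  zero (clinical tables print 3/240 as 1.3%, which banker's rounding would
  not produce).
* **Absolute rate differences** use the Newcombe hybrid-score CI by
  default (asymmetric, valid near the extremes; a Wald option exists). The
  point estimate is method-independent.
* **Adjusted ratios** come from GLMMs with fixed effects for group, sex
  and indication and a random intercept per healthcare center, estimated
  by MAP with a Laplace approximation (statsmodels Bayesian mixed GLMs).
  The fixed-effect prior is widened to N(0, 10²): the library default of
  N(0, 2²) visibly shrinks log-ratios of the magnitude this domain
  produces (log 8 ≈ 2.1). Estimation is a contract, not a commitment to
  one algorithm: a failed mixed fit falls back to a fixed-effects GLM with
  center dummies, flagged `fallback_fixed_effects`; a group with zero
  events is flagged `separation` and returns NaN rather than a runaway
  ratio. Wald-type CIs `exp(b ± 1.96·se)` are reported; on replicated
  synthetic cohorts (n=510, 3 centers) they cover generating effects of
  log 8 (logit) and log 4 (Poisson) in ≳94% of replicates.
* **Counts** are compared with Poisson GLMMs per the original design even
  though lesion counts are overdispersed; the aIRR point estimate is
  consistent under overdispersion but its CI is anti-conservative —
  documented rather than silently swapped for a negative binomial, since
  the comparison target is the published analysis.
* **Multiplicity**: 11 outcome tests (1 primary + 10 secondary), Bonferroni
  level α/11; 0.05/11 displays as 0.0045.
* **Power** uses the two-sided normal approximation with unpooled
  variance; the original computation used a commercial package whose exact
  routine is unknown, so only band-level agreement (≈70% at 247/group for
  33% vs 23%) is claimed.
* **Baseline tables** select Welch t vs Mann-Whitney by a sample-skewness
  bound (|skew| ≤ 1) and chi-squared vs Fisher by the expected-cell-count
  rule; the chosen test is reported per variable.

## Problem sizes and determinism

Test and acceptance workloads are sized for laptop-class runs: phantoms
render at 48–128 px, oracle-equivalence sweeps use 100 procedures of
20–40 frames, calibration replicates use the original threshold-dataset
size (n=716, 20 replicates), and mixed-model coverage uses 50 replicates
at the validation-study size (n=510). Every stochastic component is a pure
function of an integer seed: generators take seeds in their specs,
per-frame seeds derive from a `SeedSequence`, and `scripts/acceptance.py`
derives all of its seeds from `--seed`.

## Known limitations

* Baseline perception is photometric and calibrated to the phantom
  palette; no claim transfers to real endoscopy frames.
* Withdrawal-phase detection is out of scope — inputs are assumed to be
  withdrawal footage, with an optional start/end frame window.
* The 2000 threshold is specific to the calibration frame rate and to the
  bundled generative calibration; recalibrate for any other acquisition
  setup.
* Adjusted ratios from the original study are reproducible only as
  parameter-recovery experiments on synthetic cohorts, because per-patient
  covariates were never published; the published aggregate counts bundled
  in `ccmea.datasets` support exact reproduction of rates and differences
  only.
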