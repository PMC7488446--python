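# Methods

## Signal model and T2 mapping

Each voxel of a multi-echo spin-echo acquisition is modelled as a
mono-exponential decay, S(TE) = s0 · exp(−TE/T2), with T2 in
milliseconds. Estimation is by unweighted ordinary least squares of
log S on TE ("log-space fitting"): T2 = −1/slope, s0 = exp(intercept).
This is the standard fast estimator for multi-echo relaxometry; it
assumes a single compartment per voxel and does not model stimulated
echoes, B1 inhomogeneity or multi-exponential (e.g. myelin-water)
decay.

Two echo-train presets are built in: a 10-echo CPMG train at TE = 12,
24, …, 120 ms and a 3-echo TSE variant at TE = 9.1, 72, 136 ms. The
first echo of a CPMG train is biased relative to the rest of the train
(stimulated-echo contamination), so the default policy excludes the
first echo whenever the train has ≥ 10 echoes and keeps all echoes
otherwise; the policy is always overridable. Whether short TSE trains
should also drop their first echo is genuinely open; the default keeps
it, because a 3-echo fit cannot afford to lose a point.

A voxel is flagged invalid — NaN in the map, excluded downstream —
when any used signal is non-positive, the fitted slope is non-negative
(non-decaying), or fewer than two usable echoes remain. Weighted
fitting variants are deliberately out of scope.

ROI samples are the valid in-mask T2 values inside a physiological cap
interval, default [30, 200] ms for brain tissue at 3T. "Capping" is
implemented as exclusion (truncation), not clipping: clipping would
pile probability mass at the bounds and corrupt any maximum-likelihood
fit. The interval is closed — values exactly 30 or 200 ms are kept —
an arbitrary but fixed choice. Caps are configurable.

Grids are assumed co-registered (true for the synthetic data);
registration and segmentation are outside the package's scope, which
is why masks are inputs.

## Distribution modelling

The T2 values of an ROI are modelled by the log-logistic distribution

f(x | μ, σ) = (1/σ)(1/x) e^z / (1 + e^z)², z = (log x − μ)/σ,

whose two parameters are the regional metrics: μ is the log-median
("midpoint", log-ms; the median T2 is e^μ) and σ the shape
("heterogeneity", dimensionless). Equivalently, log T2 is
logistic(μ, σ).

The MLE is computed on (μ, log σ) — the log transform enforces σ > 0 —
from the quantile start μ₀ = median(log x), σ₀ = IQR(log x)/(2 ln 3)
(the logistic-IQR identity). The scalar path uses L-BFGS-B with
analytic gradients (objective tolerance 1e−12, ≤ 500 iterations); a
vectorised damped-Newton path fits thousands of ROIs in parallel for
simulation studies (gradient tolerance 1e−7 per observation, step
halving, fallback to the scalar path for stragglers; the two paths
agree to ~1e−8 in the parameters). Zero-spread samples are degenerate:
σ collapses to a floor of 1e−8 and the fit is flagged non-informative.
Fits require n ≥ 10 samples.

The log-density is evaluated overflow-safely via
log f = −log σ − log x + z − 2·softplus(z).

### Family competition

The log-logistic fit competes against a registry of 18 candidate
families fitted by maximum likelihood, mirroring a general-purpose
distribution-fitting catalogue: log-logistic, log-normal, logistic,
normal, gamma, Weibull, exponential, Rayleigh, inverse Gaussian,
Birnbaum–Saunders, generalised extreme value, generalised Pareto,
Nakagami, Rician, t location-scale, uniform, half-normal and
beta-prime. Families with closed-form MLEs (normal, log-normal,
exponential, Rayleigh, uniform) use them; the rest use numerical MLE
with the shift parameter fixed at zero for positive-support families
(the fixed shift is not counted in the AIC penalty). Families whose
support a sample violates are skipped with the reason recorded; fit
failures are reported as non-converged, never raised.

The best family per ROI is the lowest AIC = 2k − 2 log L among
converged fits, ties broken by fewer parameters and then registry
order; the modal best family is tracked across a cohort. Only the
log-logistic parameters feed the headline metrics, so the registry
composition is a reporting choice, not a results-critical one, and is
configurable.

Two further deliberate choices: fits use raw voxel values, not binned
histogram counts (strictly more informative); and no truncation
correction is applied for the [30, 200] ms capping — the likelihood of
the untruncated family is maximised on the truncated sample. The
latter biases σ̂ downward, increasingly so for wider distributions: at
σ = 0.113 about 0.4% of the genuine upper tail lies beyond 200 ms,
at σ = 0.135 about 1% (computable from the logistic CDF at
z = (log 200 − μ)/σ). Group *differences* in σ̂ are therefore
attenuated by capping; this is a known, documented bias, and
simulation-based validity checks of effect recovery match the
estimator's support to the generator's range so estimator noise is
assessed separately from truncation bias.

Hemispheres are fitted separately and combined into one region value
by an unweighted mean of the parameter estimates (default);
voxel-count-weighted averaging and pooled refitting on the
concatenated samples are available, since no single convention is
canonical.

## Cohort statistics

Metrics are z-normalised within study against a reference group
(healthy controls): z = (x − mean_ref)/sd_ref with the sample SD
(n − 1), computed per study and then pooled, so each study's reference
group has mean 0 and sample SD 1 exactly. Regional volumes may be
ICV-corrected by ratio (default) or by residualising on ICV.

Group comparisons use ANCOVA — outcome ~ group + covariates (default
covariate: age) by least squares with sum-to-zero (effects) coding for
the group factor. The group F statistic is the nested-model (Type-III)
comparison ((RSS₀ − RSS₁)/df₁)/(RSS₁/df₂) with df₁ = g − 1 and
df₂ = N − g − c. Estimated marginal means are adjusted group means at
the grand covariate mean, with standard errors from the fit's error
variance; pairwise comparisons are pooled-variance t tests on EMM
differences with Sidak correction p′ = 1 − (1 − p)^m over the m = 3
group pairs. Levene's test (classic, mean-centred; Brown–Forsythe
median variant optional) accompanies every comparison. Further
covariates (education, study, sex) are accepted but off by default,
matching the convention of reporting age-corrected models only.

The follow-up-cognition model is OLS of follow-up cognition on age,
baseline cognition and one structural marker, all four variables
standardised before fitting so coefficients are standardised βs;
reported are R², the overall F(3, n − 4) test and per-coefficient
two-tailed p values. Partial-residual (added-variable) pairs
residualise both follow-up cognition and the marker on age + baseline;
by the Frisch–Waugh theorem the residual-on-residual slope equals the
marker's full-model coefficient. Age effects in the reference group
use simple OLS with two-tailed p.

A calibration caveat found during validation: running the group ANCOVA
on metrics z-scored to a per-study reference inflates the type-I error
when a small group is concentrated in a single study (each study's
scale is divided by a noisy reference-sample SD, and that scale noise
propagates into the group contrast — in the default cohort layout the
smallest group exists in one study only). The ANCOVA on the metric
itself is well calibrated; calibration checks therefore target the
un-normalised metric, and z-scored group tests with very small
single-study groups should be interpreted with care.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
as a pure function of (spec, seed):

* **Cohort** — default 97 HC / 49 MCI / 10 AD across two studies
  (50/47, 30/19, 10/0), group-wise age distributions Normal(69.3, 8.58),
  (72.2, 9.03), (77.9, 9.94) years redrawn into [40, 100], fixed
  male/female counts per group (46:51, 27:22, 2:8), years of education
  and ICV ~ Normal(1.5e6, 1.5e5) mm³.
* **Regional truth** — μ_true = μ₀ + Δμ(group) + β_μ·(age − 70),
  σ_true analogous. Defaults: μ₀ = 4.68, σ₀ = 0.113 with an age slope
  of 0.001/year on σ (so a 69-year-old control has exactly
  (μ, σ) = (4.68, 0.112), the worked healthy-control example) and no
  age slope on μ; Δσ = +0.02 for MCI and AD (wider distributions),
  Δμ = +0.03 for AD (longer midpoint). Regional volumes are
  Normal(3200, 300) mm³; the volume–age slope defaults to zero with
  its sign exposed as a parameter, since the direction of the
  volume–age association in older reference samples is disputable.
* **Phantom** — per-region left/right ellipsoids on a 32×32×16 grid
  (voxel 0.34 × 0.34 × 1.7 mm); in-ROI voxels draw
  T2 ~ log-logistic(μ_true, σ_true) by inverse CDF,
  x = exp(μ + σ·logit(u)), with draws outside (1, 1000) ms redrawn
  (never clipped); background voxels carry a fixed background T2.
* **Noise** — the default noise model is Rician, the physics of
  magnitude MRI: the observed signal is |S + n₁ + i·n₂| with
  independent Normal(0, noise_sd) channels, so signals stay
  non-negative and the SNR is s0/noise_sd. Additive-Gaussian and
  noiseless variants exist for oracle tests (noiseless simulation
  followed by mapping recovers every voxel's T2 to < 1e−6 relative).
* **Cognition** — baseline is group mean + age slope + noise on a
  z-like scale (group means 0, −4.08, −8.50; SDs 1.00, 2.09, 3.15);
  follow-up is generated exactly by
  followup = β₀ + β_age·age + β_bl·baseline + β_σ·σ_true + ε,
  with defaults β₀ = 6.3, β_age = −0.05, β_bl = 0.9, β_σ = −30
  (units: cognition points per unit σ; σ varies by ~0.01–0.02 across
  subjects, so the marker contributes on the order of half a point),
  ε ~ Normal(0, 1). These generative coefficient values are the
  package's own choices of a plausible effect size — the regression
  *form* is the modelling commitment, the numbers are not.

What the generator does **not** emulate: anatomical shapes and
partial-volume mixing at ROI boundaries, slice gaps, motion, k-space
/ parallel-imaging reconstruction artefacts, spatial noise
correlation, and multi-compartment T2 decay. Passing tests therefore
demonstrate that the estimation and statistics chain is correct and
calibrated under its stated model — not that the model captures every
property of in-vivo data.

## Problem sizes used in validation

The test suite validates at sizes chosen to give tight Monte-Carlo
error at interactive runtimes: parameter recovery at n = 10⁵ samples;
estimator consistency at n ∈ {10², 10³, 10⁴} × 50 replicates; AIC
selection frequency at n = 5000 × 100 replicates; type-I calibration
on 2000 simulated cohorts of 156 subjects with per-subject σ̂ measured
by MLE on 200 rendered T2 samples; and effect recovery
(Δσ = 0.02, 97 vs 49 subjects) through the full imaging chain —
3000-voxel ROIs, 10-echo CPMG, Rician SNR 50 — over 200 replicates.
End-to-end pipeline runs use an 18-subject cohort on the default grid.

## Known limitations

* No truncation-corrected likelihood for capped samples (bias
  documented above).
* The mono-exponential, single-compartment signal model; no EPG or B1
  corrections.
* Hemisphere combination by parameter averaging is one of several
  defensible conventions; alternatives are provided but results can
  differ slightly.
* The z-then-ANCOVA chain's type-I inflation with small single-study
  groups (documented above).
* The family registry is a stand-in catalogue; AIC winners among the
  17 competitors depend on its composition, though the headline
  metrics do not.
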