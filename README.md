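# t2het — T2 heterogeneity analysis of multi-echo MRI

`t2het` turns multi-echo T2-weighted MRI into regional markers of tissue
microstructure. Quantitative T2 relaxation time in brain tissue reflects
water content and mobility, macromolecules and iron; in early
neurodegeneration, processes that *lengthen* T2 (membrane breakdown,
oedema) and processes that *shorten* it (amyloid, iron) coexist in the
same region, so the regional *average* T2 can stay flat while the
*spread* of voxel T2 values widens. The package therefore models the
full within-region T2 distribution and reports two scalars per subject
and region:

* **T2μ** — the log-median ("midpoint", log-ms) and
* **T2σ** — the shape ("heterogeneity", dimensionless)

of a log-logistic fit to the voxelwise T2 values,

```
f(x | μ, σ) = (1/σ) (1/x) e^z / (1 + e^z)²,   z = (log x − μ) / σ,
```

i.e. log T2 follows a logistic(μ, σ) law and the regional median T2 is
e^μ. A wider distribution (larger σ) in a memory-clinic group, and its
ability to predict one-year cognitive decline, is the scientific use
case the pipeline supports.

It is aimed at quantitative-MRI researchers who have multi-echo
spin-echo acquisitions (e.g. a 10-echo CPMG train at 12 ms spacing, or a
3-echo TSE at 9.1/72/136 ms) and per-region masks, and who want a
tested, reproducible path from raw echoes to cohort statistics. Because
clinical MRI cohorts are rarely shareable, the package also ships a
synthetic cohort/phantom generator with the same statistical structure,
so every stage is validated end-to-end without any data download.

## What the pipeline does

1. **T2 mapping** (`t2het.mapping`) — voxelwise log-space
   mono-exponential fits, `log S = log s0 − TE/T2`; the first echo of
   long CPMG trains is excluded by default; sum-of-echoes structural
   images; mask union, ROI volumes.
2. **ROI extraction** — valid in-mask T2 values inside physiological
   caps (default 30–200 ms; values outside are excluded, not clipped).
3. **Distribution modelling** (`t2het.distributions`) — a maximum-
   likelihood log-logistic fit per hemisphere (damped Newton on
   (μ, log σ), with a batched vectorised path for simulation studies),
   competing against a configurable registry of 18 candidate families;
   the best family per ROI is chosen by lowest AIC = 2k − 2 log L.
4. **Cohort statistics** (`t2het.cohort_stats`) — per-study
   z-normalisation to a healthy-control reference, group ANCOVA with age
   as covariate (Type-III F, estimated marginal means, Sidak-corrected
   pairwise tests, Levene's test), the follow-up-cognition regression
   with standardised coefficients, partial-residual plots data, and
   simple age regressions.
5. **Synthetic data** (`t2het.synthetic`) — cohort tables, ground-truth
   log-logistic T2 fields rendered into ellipsoid ROIs, multi-echo
   signals under Rician (magnitude) noise, and longitudinal cognition
   generated by a linear model in age, baseline cognition and T2σ.

A `t2het` command-line tool (`simulate`, `t2map`, `extract`, `fitdist`,
`stats`, `run-all`) orchestrates the stages from one YAML config with
deterministic per-stage seeding and checksum-based stage caching.

## Worked example

```python
import numpy as np
from t2het import (CohortSpec, generate_ground_truth, measure_roi_params,
                   ancova_group, zscore_to_reference,
                   fit_loglogistic_mle, loglogistic_ppf)

# fit one subject's hippocampal ROI (3000 voxels, healthy-control truth)
rng = np.random.default_rng(0)
t2 = loglogistic_ppf(rng.uniform(size=3000), 4.68, 0.112)
mu, sigma, loglik, ok = fit_loglogistic_mle(t2)
print(f"mu = {mu:.3f} (median T2 = {np.exp(mu):.1f} ms), sigma = {sigma:.4f}")

# simulate a 156-subject two-study cohort and compare groups on T2sigma
truth = generate_ground_truth(CohortSpec(seed=1))
_, sigma_hat, _ = measure_roi_params(
    truth["hippocampus_mu_true"].to_numpy(),
    truth["hippocampus_sigma_true"].to_numpy(),
    n_voxels=3000, seed=np.random.default_rng(2), snr=50.0)
z = zscore_to_reference(sigma_hat, (truth["group"] == "HC").to_numpy(),
                        truth["study"].to_numpy())
res = ancova_group(z, truth["group"], covariates=truth["age"].to_numpy())
print(f"T2sigma ANCOVA: F({res.df1}, {res.df2}) = {res.F:.2f}, p = {res.p:.2e}")
```

prints

```
mu = 4.678 (median T2 = 107.6 ms), sigma = 0.1126
T2sigma ANCOVA: F(2, 152) = 1481.41, p = 2.09e-100
```

The single-ROI fit recovers the generating parameters (μ = 4.68,
σ = 0.112) to within Monte-Carlo error at 3000 voxels. In the cohort,
the generator injects a wider T2 distribution in the MCI and AD groups
(Δσ = 0.02); with 3000-voxel ROIs at SNR 50 the group effect on the
z-scored heterogeneity is overwhelming (the denominator df of 152 is
156 subjects − 3 groups − 1 age covariate), while the Sidak-corrected
MCI-vs-AD comparison is null by construction (both groups share the
same σ offset).

Or from the shell:

```bash
t2het run-all --config examples/toy.yaml --out runs/toy   # or no config for defaults
```

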