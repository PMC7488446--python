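"""Cohort-level statistics for regional T2 metrics.

The analysis chain for a combined multi-study cohort:

1. z-normalise each metric within study to that study's healthy-control
   reference (so the pooled HC group has mean 0, SD 1 by construction);
2. compare groups by ANCOVA with age as covariate, reporting the group
   F test, estimated marginal means at the grand covariate mean, and
   Sidak-corrected pairwise comparisons; homogeneity of variance is
   checked with Levene's test;
3. in the MCI follow-up subsample, regress follow-up cognition on age,
   baseline cognition and one structural marker (all standardised), and
   display the marker's contribution through partial residuals;
4. simple age regressions of each metric in healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AncovaResult:
    """Group ANCOVA: F test, marginal means, pairwise and Levene tests."""

    F: float
    df1: int
    df2: int
    p: float
    emmeans: dict  # group -> (emm, se)
    pairwise: list  # (group_a, group_b, p_raw, p_sidak)
    levene_w: float
    levene_p: float
    groups: tuple = ()


@dataclass
class RegressionResult:
    """Multiple regression summary with standardised coefficients."""

    r2: float
    F: float
    df1: int
    df2: int
    p: float
    beta: dict = field(default_factory=dict)  # predictor -> standardised beta
    coef_p: dict = field(default_factory=dict)  # predictor -> two-tailed p


def zscore_to_reference(
    values: Sequence[float],
    is_reference: Sequence[bool],
    study: Optional[Sequence] = None,
) -> np.ndarray:
    """Z scores computed against a reference subgroup, per study.

    z = (x - mean_ref) / sd_ref within each study (sample SD, n-1), then
    pooled. The reference subgroup of every study has mean 0 and sample
    SD 1 by construction.
    """
    x = np.asarray(values, dtype=float)
    ref = np.asarray(is_reference, dtype=bool)
    if x.shape != ref.shape:
        raise ValueError("values and reference flags must align")
    study = np.zeros(x.shape, dtype=int) if study is None else np.asarray(study)
    out = np.empty_like(x)
    for s in pd.unique(study):
        sel = study == s
        r = sel & ref
        if r.sum() < 2:
            raise ValueError(f"study '{s}': reference group needs n >= 2")
        mean = x[r].mean()
        sd = x[r].std(ddof=1)
        if sd == 0:
            raise ValueError(f"study '{s}': zero reference SD")
        out[sel] = (x[sel] - mean) / sd
    return out


def icv_correct(
    volume: Sequence[float],
    icv: Sequence[float],
    method: str = "ratio",
) -> np.ndarray:
    """Intracranial-volume correction of a regional volume.

    ``ratio``: volume / ICV (default). ``residual``: residuals of volume
    regressed on ICV plus the mean volume, removing the linear ICV trend.
    """
    v = np.asarray(volume, dtype=float)
    i = np.asarray(icv, dtype=float)
    if np.any(i <= 0):
        raise ValueError("ICV must be positive")
    if method == "ratio":
        return v / i
    if method == "residual":
        slope, intercept = np.polyfit(i, v, 1)
        return v - (intercept + slope * i) + v.mean()
    raise ValueError(f"unknown ICV correction method '{method}'")


def _design(group_codes: np.ndarray, groups: Sequence, covariates: np.ndarray):
    """Full design matrix with intercept, effects-coded group, covariates."""
    n = group_codes.size
    g = len(groups)
    G = np.zeros((n, g - 1))
    for j, grp in enumerate(groups[:-1]):
        G[group_codes == j, j] = 1.0
    G[group_codes == g - 1, :] = -1.0  # sum-to-zero (effects) coding
    return np.column_stack([np.ones(n), G, covariates])


def ancova_group(
    outcome: Sequence[float],
    group: Sequence,
    covariates=None,
    groups: Optional[Sequence] = None,
) -> AncovaResult:
    """ANCOVA of an outcome on a group factor plus covariates.

    The group F statistic is the nested-model (Type III) comparison of
    the full model against the model without the group factor. Estimated
    marginal means are adjusted group means at the grand covariate mean,
    with SEs from the fit's error variance. Pairwise comparisons are
    pooled-variance t tests on EMM differences, Sidak-corrected over the
    group pairs. Levene's test (mean-centred) accompanies the F test.
    """
    y = np.asarray(outcome, dtype=float)
    grp = pd.Series(group)
    if groups is None:
        groups = list(pd.unique(grp))
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    codes = grp.map({g: i for i, g in enumerate(groups)}).to_numpy()
    if np.any(pd.isna(codes)):
        raise ValueError("group labels outside the declared groups")
    codes = codes.astype(int)
    counts = np.bincount(codes, minlength=len(groups))
    if np.any(counts < 2):
        raise ValueError("every group needs n >= 2")

    if covariates is None:
        C = np.empty((y.size, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    n, g, c = y.size, len(groups), C.shape[1]

    X1 = _design(codes, groups, C)
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("rank-deficient design matrix")
    X0 = np.column_stack([np.ones(n), C])

    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss1 = float(((y - X1 @ beta1) ** 2).sum())
    rss0 = float(((y - X0 @ beta0) ** 2).sum())
    df1 = g - 1
    df2 = n - g - c
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss1 / df2
    F = ((rss0 - rss1) / df1) / mse if mse > 0 else 0.0
    p = float(sps.f.sf(F, df1, df2)) if mse > 0 else 1.0

    xtx_inv = np.linalg.inv(X1.T @ X1)
    cov_beta = mse * xtx_inv
    cbar = C.mean(axis=0) if c else np.empty(0)

    def emm_row(j: int) -> np.ndarray:
        row = np.zeros(X1.shape[1])
        row[0] = 1.0
        if j < g - 1:
            row[1 + j] = 1.0
        else:
            row[1 : g] = -1.0
        row[g:] = cbar
        return row

    emmeans = {}
    for j, name in enumerate(groups):
        r = emm_row(j)
        emmeans[name] = (float(r @ beta1), float(np.sqrt(r @ cov_beta @ r)))

    m = g * (g - 1) // 2
    pairwise = []
    for (i_a, a), (i_b, b) in combinations(enumerate(groups), 2):
        d = emm_row(i_a) - emm_row(i_b)
        diff = float(d @ beta1)
        se = float(np.sqrt(d @ cov_beta @ d))
        if se == 0.0:  # zero residual variance: degenerate exact fit
            p_raw = 1.0 if diff == 0.0 else 0.0
        else:
            p_raw = float(2.0 * sps.t.sf(abs(diff / se), df2))
        pairwise.append((a, b, p_raw, sidak_pairwise(p_raw, m)))

    w, pl = levene_test(y, grp)
    return AncovaResult(
        F=float(F), df1=df1, df2=df2, p=p, emmeans=emmeans,
        pairwise=pairwise, levene_w=w, levene_p=pl, groups=tuple(groups),
    )


def sidak_pairwise(p_raw, m: int):
    """Sidak multiple-comparison correction: p' = 1 - (1 - p)^m."""
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("raw p values must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    with np.errstate(divide="ignore"):
        out = -np.expm1(m * np.log1p(-p))
    out = np.minimum(np.where(p == 1.0, 1.0, out), 1.0)
    return out if out.ndim else float(out)


def levene_test(
    outcome: Sequence[float],
    group: Sequence,
    center: str = "mean",
) -> tuple[float, float]:
    """Levene's homogeneity-of-variance test.

    Classic Levene uses deviations from the group mean; ``center='median'``
    gives the Brown-Forsythe variant.
    """
    y = np.asarray(outcome, dtype=float)
    grp = pd.Series(group)
    samples = [y[(grp == g).to_numpy()] for g in pd.unique(grp)]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >= 2 groups with n >= 2 each")
    w, p = sps.levene(*samples, center=center)
    return float(w), float(p)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardise a constant column")
    return (x - x.mean()) / sd


def followup_regression(
    cohort: pd.DataFrame,
    marker: str,
    age_col: str = "age",
    baseline_col: str = "cog_baseline",
    followup_col: str = "cog_followup",
) -> RegressionResult:
    """Follow-up cognition regressed on age, baseline cognition and a
    structural marker.

    All four variables are standardised before the fit, so the
    coefficients are standardised betas. Reports R^2, the overall
    F(p, n - p - 1) test, and per-coefficient two-tailed p values.
    """
    cols = [followup_col, age_col, baseline_col, marker]
    data = cohort[cols].dropna()
    n = len(data)
    p_pred = 3
    if n <= p_pred + 1:
        raise ValueError(f"n = {n} too small for {p_pred} predictors")
    Z = np.column_stack([_standardize(data[c].to_numpy(dtype=float)) for c in cols])
    y, X = Z[:, 0], np.column_stack([np.ones(n), Z[:, 1:]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design (collinear predictors)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df1, df2 = p_pred, n - p_pred - 1
    r2 = 1.0 - rss / tss
    if rss > 0:
        F = (tss - rss) / df1 / (rss / df2)
        p_overall = float(sps.f.sf(F, df1, df2))
        cov = rss / df2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2.0 * sps.t.sf(np.abs(tvals), df2)
    else:  # exact fit
        F, p_overall = float("inf"), 0.0
        pvals = np.zeros_like(beta)
    names = [age_col, baseline_col, marker]
    return RegressionResult(
        r2=float(r2), F=float(F), df1=df1, df2=df2, p=p_overall,
        beta={nm: float(b) for nm, b in zip(names, beta[1:])},
        coef_p={nm: float(pv) for nm, pv in zip(names, pvals[1:])},
    )


def partial_residuals(
    cohort: pd.DataFrame,
    marker: str,
    age_col: str = "age",
    baseline_col: str = "cog_baseline",
    followup_col: str = "cog_followup",
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Added-variable (partial-residual) pairs for one marker.

    y residuals: follow-up cognition regressed on age and baseline;
    x residuals: the marker regressed on the same covariates. By the
    Frisch-Waugh identity the slope of y-res on x-res equals the marker's
    coefficient in the full model. Residuals are standardised to SD 1
    when ``standardize`` (matching added-variable plots).
    """
    data = cohort[[followup_col, age_col, baseline_col, marker]].dropna()
    n = len(data)
    X = np.column_stack(
        [np.ones(n), data[age_col].to_numpy(float), data[baseline_col].to_numpy(float)]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design")

    def resid(v):
        b, *_ = np.linalg.lstsq(X, v, rcond=None)
        return v - X @ b

    y_res = resid(data[followup_col].to_numpy(float))
    x_res = resid(data[marker].to_numpy(float))
    if standardize:
        if y_res.std(ddof=1) == 0 or x_res.std(ddof=1) == 0:
            raise ValueError("residuals are identically zero; cannot standardise")
        y_res = y_res / y_res.std(ddof=1)
        x_res = x_res / x_res.std(ddof=1)
    return x_res, y_res


def age_regression(
    metric: Sequence[float],
    age: Sequence[float],
) -> tuple[float, float, float]:
    """Simple OLS of a metric on age (reference-group rows).

    Returns (R^2, slope, two-tailed p).
    """
    m = np.asarray(metric, dtype=float)
    a = np.asarray(age, dtype=float)
    if m.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(a) == 0:
        raise ValueError("age is constant")
    res = sps.linregress(a, m)
    return float(res.rvalue**2), float(res.slope), float(res.pvalue)
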