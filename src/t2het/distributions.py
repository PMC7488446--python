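"""Distribution modelling of regional T2 samples.

The headline metrics are the two parameters of a log-logistic fit to the
T2 values of an ROI: mu, the log-median ("midpoint", log-ms), and sigma,
the shape ("heterogeneity", dimensionless). The log-logistic density is

    f(x | mu, sigma) = (1/sigma) (1/x) exp(z) / (1 + exp(z))^2,
    z = (log x - mu) / sigma,

i.e. log x follows a logistic(mu, sigma) law and the median of x is
exp(mu). The log-logistic fit competes against a registry of 17 other
families fitted by maximum likelihood; the best family per ROI is the one
with the lowest AIC = 2k - 2 loglik.

The log-logistic MLE is implemented here directly (damped Newton on
(mu, log sigma), with a quasi-Newton fallback); generic families use
closed-form estimators where they exist and ``scipy.stats`` fits
otherwise.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .types import DistributionFit, RegionT2Summary, ROISampleVector

_MIN_SAMPLES_LOGLOGISTIC = 10
_SIGMA_FLOOR = 1e-8


class SupportError(ValueError):
    """Sample lies outside a family's support; the family is skipped."""


# ---------------------------------------------------------------------------
# log-logistic primitives
# ---------------------------------------------------------------------------

def loglogistic_logpdf(x, mu: float, sigma: float):
    """Log-density of the log-logistic distribution.

    Overflow-safe: the (1 + e^z)^-2 factor is computed via log1p of the
    exponential on the negative side.
    """
    x = np.asarray(x, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if np.any(x <= 0):
        raise ValueError("log-logistic support is x > 0")
    z = (np.log(x) - mu) / sigma
    # log f = -log sigma - log x + z - 2 softplus(z)
    out = -math.log(sigma) - np.log(x) + z - 2.0 * np.logaddexp(0.0, z)
    return out if out.ndim else float(out)


def loglogistic_pdf(x, mu: float, sigma: float):
    return np.exp(loglogistic_logpdf(x, mu, sigma))


def loglogistic_cdf(x, mu: float, sigma: float):
    x = np.asarray(x, dtype=float)
    z = (np.log(np.maximum(x, np.finfo(float).tiny)) - mu) / sigma
    out = np.where(x <= 0, 0.0, special.expit(z))
    return out if out.ndim else float(out)


def loglogistic_ppf(u, mu: float, sigma: float):
    """Inverse CDF: x = exp(mu + sigma * logit(u))."""
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    out = np.exp(mu + sigma * special.logit(u))
    return out if out.ndim else float(out)


def _loglogistic_negll_and_grad(theta, y):
    """Negative log-likelihood and gradient in (mu, s = log sigma).

    ``y`` are log-samples; the -sum(y) data term is constant and included
    so the value matches the full log-density.
    """
    mu, s = theta
    sigma = math.exp(s)
    z = (y - mu) / sigma
    softplus = np.logaddexp(0.0, z)
    ll = -y.size * s - y.sum() + z.sum() - 2.0 * softplus.sum()
    p = special.expit(z)
    g_mu = (2.0 * p - 1.0).sum() / sigma
    g_s = (z * (2.0 * p - 1.0)).sum() - y.size
    return -ll, np.array([-g_mu, -g_s])


def _loglogistic_init(y: np.ndarray) -> tuple[float, float]:
    """Quantile start: mu = median(log x); sigma from the logistic IQR
    identity IQR = 2 sigma ln 3."""
    mu0 = float(np.median(y))
    q75, q25 = np.percentile(y, [75.0, 25.0])
    sigma0 = float(q75 - q25) / (2.0 * math.log(3.0))
    if sigma0 <= 0:
        sigma0 = float(np.std(y)) * math.sqrt(3.0) / math.pi
    return mu0, max(sigma0, _SIGMA_FLOOR)


def fit_loglogistic_mle(
    samples: Sequence[float],
    min_samples: int = _MIN_SAMPLES_LOGLOGISTIC,
) -> tuple[float, float, float, bool]:
    """Maximum-likelihood log-logistic fit.

    Parameters
    ----------
    samples : sequence of float
        Positive T2 values (ms).
    min_samples : int
        Minimum sample size for a meaningful two-parameter fit.

    Returns
    -------
    (mu_hat, sigma_hat, loglik, converged)
        ``converged`` is False for optimizer failure or zero-spread
        (non-informative) input, where sigma collapses to its floor.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("samples must be positive and finite")
    y = np.log(x)
    mu0, sigma0 = _loglogistic_init(y)
    if np.ptp(y) == 0.0:  # degenerate: all samples equal
        ll = float(-_loglogistic_negll_and_grad((mu0, math.log(_SIGMA_FLOOR)), y)[0])
        return mu0, _SIGMA_FLOOR, ll, False

    res = optimize.minimize(
        _loglogistic_negll_and_grad,
        x0=np.array([mu0, math.log(sigma0)]),
        args=(y,),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    mu_hat = float(res.x[0])
    sigma_hat = float(math.exp(res.x[1]))
    return mu_hat, sigma_hat, float(-res.fun), bool(res.success)


def fit_loglogistic_mle_batch(
    samples: np.ndarray,
    mask: Optional[np.ndarray] = None,
    max_iter: int = 60,
    grad_tol: float = 1e-7,
):
    """Vectorised log-logistic MLE over many ROIs at once.

    Damped Newton iterations on (mu, log sigma), run in parallel over the
    rows of ``samples``; rows that fail to converge fall back to the
    scalar quasi-Newton fit. Used by the simulation-heavy calibration and
    power analyses where tens of thousands of fits are needed.

    Parameters
    ----------
    samples : ndarray, shape (n_rois, n_voxels)
        Positive values; disable entries with ``mask``.
    mask : ndarray of bool, optional
        True where a sample is to be used (for ragged ROIs).

    Returns
    -------
    (mu, sigma, loglik, converged) : arrays of shape (n_rois,)
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("samples must be 2D (rois, voxels)")
    if mask is None:
        mask = np.ones_like(x, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if np.any((x <= 0) & mask):
        raise ValueError("samples must be positive")
    y = np.where(mask, np.log(np.where(mask, x, 1.0)), 0.0)
    n = mask.sum(axis=1).astype(float)
    if np.any(n < 2):
        raise ValueError("every row needs at least 2 usable samples")

    ymask = np.where(mask, y, np.nan)
    mu = np.nanmedian(ymask, axis=1)
    q75 = np.nanpercentile(ymask, 75.0, axis=1)
    q25 = np.nanpercentile(ymask, 25.0, axis=1)
    sigma = np.maximum((q75 - q25) / (2.0 * math.log(3.0)), 1e-4)
    s = np.log(sigma)

    def negll(mu_v, s_v):
        sig = np.exp(s_v)
        z = np.where(mask, (y - mu_v[:, None]) / sig[:, None], 0.0)
        sp = np.where(mask, np.logaddexp(0.0, z), 0.0)
        ysum = (y * mask).sum(axis=1)
        ll = -n * s_v - ysum + (z * mask).sum(axis=1) - 2.0 * sp.sum(axis=1)
        return -ll

    f = negll(mu, s)
    active = np.ones(mu.shape, dtype=bool)
    converged = np.zeros(mu.shape, dtype=bool)
    for _ in range(max_iter):
        sig = np.exp(s)
        z = np.where(mask, (y - mu[:, None]) / sig[:, None], 0.0)
        p = special.expit(z)
        w = np.where(mask, p * (1.0 - p), 0.0)
        tp = np.where(mask, 2.0 * p - 1.0, 0.0)
        sum_tp = tp.sum(axis=1)
        sum_ztp = (z * tp).sum(axis=1)
        sum_w = w.sum(axis=1)
        sum_zw = (z * w).sum(axis=1)
        sum_z2w = (z * z * w).sum(axis=1)

        g_mu = sum_tp / sig
        g_s = sum_ztp - n
        h_mm = -2.0 * sum_w / sig**2
        h_ms = -(sum_tp + 2.0 * sum_zw) / sig
        h_ss = -sum_ztp - 2.0 * sum_z2w

        gnorm = np.maximum(np.abs(g_mu) * sig, np.abs(g_s)) / n
        newly = active & (gnorm < grad_tol)
        converged |= newly
        active &= ~newly
        if not active.any():
            break

        det = h_mm * h_ss - h_ms**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        d_mu = -(h_ss * g_mu - h_ms * g_s) / det
        d_s = -(-h_ms * g_mu + h_mm * g_s) / det
        bad = ~np.isfinite(d_mu) | ~np.isfinite(d_s)
        # fall back to a scaled gradient step where the Hessian is unusable
        d_mu = np.where(bad, g_mu * sig**2 / n, d_mu)
        d_s = np.where(bad, g_s / n, d_s)

        step = np.where(active, 1.0, 0.0)
        for _half in range(8):
            mu_new = mu + step * d_mu
            s_new = np.clip(s + step * d_s, math.log(_SIGMA_FLOOR), 10.0)
            f_new = negll(mu_new, s_new)
            worse = active & ~(f_new <= f + 1e-12)
            if not worse.any():
                break
            step = np.where(worse, step * 0.5, step)
        improve = active & (f_new < f)
        mu = np.where(improve, mu_new, mu)
        s = np.where(improve, s_new, s)
        f = np.where(improve, f_new, f)

    sigma = np.exp(s)
    loglik = -f
    # salvage stragglers with the scalar path
    if not converged.all():
        for i in np.flatnonzero(~converged):
            xi = x[i][mask[i]]
            if np.ptp(xi) == 0.0:
                continue
            try:
                m, sg, ll, ok = fit_loglogistic_mle(xi, min_samples=2)
            except ValueError:
                continue
            if ok and ll >= loglik[i] - 1e-9:
                mu[i], sigma[i], loglik[i], converged[i] = m, sg, ll, True
    return mu, sigma, loglik, converged


# ---------------------------------------------------------------------------
# family registry
# ---------------------------------------------------------------------------

@dataclass
class DistributionFamily:
    """A candidate family: name, number of free parameters, MLE fit and
    log-pdf contracts."""

    name: str
    n_params: int
    fit: Callable[[np.ndarray], tuple[tuple[float, ...], float]]
    logpdf: Callable[[np.ndarray, tuple[float, ...]], np.ndarray]
    positive_support: bool = True


def _scipy_family(
    name: str,
    dist,
    n_params: int,
    positive_support: bool = True,
    fit_kwargs: Optional[dict] = None,
) -> DistributionFamily:
    fit_kwargs = fit_kwargs or {}

    def fit(x: np.ndarray):
        params = dist.fit(x, **fit_kwargs)
        ll = float(dist.logpdf(x, *params).sum())
        return tuple(float(p) for p in params), ll

    def logpdf(x: np.ndarray, params):
        return dist.logpdf(x, *params)

    return DistributionFamily(name, n_params, fit, logpdf, positive_support)


def _closed_form(name, n_params, fit, logpdf, positive_support=True):
    return DistributionFamily(name, n_params, fit, logpdf, positive_support)


def _fit_normal(x):
    mu, sd = float(x.mean()), float(x.std())
    ll = float(stats.norm.logpdf(x, mu, sd).sum())
    return (mu, sd), ll


def _fit_lognormal(x):
    y = np.log(x)
    mu, sd = float(y.mean()), float(y.std())
    ll = float(stats.lognorm.logpdf(x, sd, 0.0, math.exp(mu)).sum())
    return (mu, sd), ll


def _fit_exponential(x):
    scale = float(x.mean())
    ll = float(stats.expon.logpdf(x, 0.0, scale).sum())
    return (scale,), ll


def _fit_rayleigh(x):
    scale = float(math.sqrt((x**2).mean() / 2.0))
    ll = float(stats.rayleigh.logpdf(x, 0.0, scale).sum())
    return (scale,), ll


def _fit_uniform(x):
    lo, hi = float(x.min()), float(x.max())
    ll = -x.size * math.log(hi - lo) if hi > lo else math.inf
    return (lo, hi), ll


def _fit_loglogistic_family(x):
    mu, sigma, ll, ok = fit_loglogistic_mle(x, min_samples=2)
    if not ok:
        raise RuntimeError("log-logistic fit did not converge")
    return (mu, sigma), ll


def default_registry() -> list[DistributionFamily]:
    """The default catalogue of 18 candidate families.

    A general-purpose MLE fitting catalogue for positive-valued samples;
    the log-logistic entry is the one the headline T2 metrics rely on.
    Fixed shift parameters (floc=0 for positive-support families) are not
    counted as free parameters in the AIC.
    """
    return [
        _closed_form(
            "loglogistic", 2, _fit_loglogistic_family,
            lambda x, p: loglogistic_logpdf(x, *p),
        ),
        _closed_form(
            "lognormal", 2, _fit_lognormal,
            lambda x, p: stats.lognorm.logpdf(x, p[1], 0.0, math.exp(p[0])),
        ),
        _scipy_family("logistic", stats.logistic, 2, positive_support=False),
        _closed_form(
            "normal", 2, _fit_normal,
            lambda x, p: stats.norm.logpdf(x, *p),
            positive_support=False,
        ),
        _scipy_family("gamma", stats.gamma, 2, fit_kwargs={"floc": 0.0}),
        _scipy_family("weibull", stats.weibull_min, 2, fit_kwargs={"floc": 0.0}),
        _closed_form(
            "exponential", 1, _fit_exponential,
            lambda x, p: stats.expon.logpdf(x, 0.0, p[0]),
        ),
        _closed_form(
            "rayleigh", 1, _fit_rayleigh,
            lambda x, p: stats.rayleigh.logpdf(x, 0.0, p[0]),
        ),
        _scipy_family("inverse_gaussian", stats.invgauss, 2, fit_kwargs={"floc": 0.0}),
        _scipy_family("birnbaum_saunders", stats.fatiguelife, 2, fit_kwargs={"floc": 0.0}),
        _scipy_family("gev", stats.genextreme, 3, positive_support=False),
        _scipy_family("gpd", stats.genpareto, 3, positive_support=False),
        _scipy_family("nakagami", stats.nakagami, 2, fit_kwargs={"floc": 0.0}),
        _scipy_family("rician", stats.rice, 2, fit_kwargs={"floc": 0.0}),
        _scipy_family("t_locscale", stats.t, 3, positive_support=False),
        _closed_form(
            "uniform", 2, _fit_uniform,
            lambda x, p: stats.uniform.logpdf(x, p[0], p[1] - p[0]),
            positive_support=False,
        ),
        _scipy_family("halfnormal", stats.halfnorm, 1, fit_kwargs={"floc": 0.0}),
        _scipy_family("betaprime", stats.betaprime, 3, fit_kwargs={"floc": 0.0}),
    ]


def registry_by_name(name: str = "default18") -> list[DistributionFamily]:
    full = default_registry()
    if name == "default18":
        return full
    if name == "loglogistic":
        return [f for f in full if f.name == "loglogistic"]
    if name == "core":
        keep = {"loglogistic", "lognormal", "normal", "gamma", "weibull", "logistic"}
        return [f for f in full if f.name in keep]
    raise ValueError(f"unknown family registry '{name}'")


def aic(n_params: int, loglik: float) -> float:
    return 2.0 * n_params - 2.0 * loglik


def fit_family(samples: Sequence[float], family: DistributionFamily) -> DistributionFit:
    """MLE fit of one family with its log-likelihood and AIC.

    Raises
    ------
    SupportError
        When the sample violates the family's support (e.g. non-positive
        values under a positive-support family).
    ValueError
        When the sample is smaller than the family's parameter count.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < family.n_params:
        raise ValueError(
            f"{family.name}: n={x.size} below parameter count {family.n_params}"
        )
    if family.positive_support and np.any(x <= 0):
        raise SupportError(f"{family.name} requires positive samples")
    try:
        params, ll = family.fit(x)
        converged = bool(np.isfinite(ll))
        message = ""
    except Exception as exc:  # fit failures are recorded, not raised
        return DistributionFit(
            family=family.name, params=(), loglik=-math.inf, aic=math.inf,
            n=int(x.size), n_params=family.n_params, converged=False,
            message=str(exc),
        )
    return DistributionFit(
        family=family.name, params=params, loglik=ll,
        aic=aic(family.n_params, ll), n=int(x.size),
        n_params=family.n_params, converged=converged, message=message,
    )


def fit_all_families(
    samples: Sequence[float],
    families: Optional[Sequence[DistributionFamily]] = None,
) -> tuple[list[DistributionFit], dict[str, str]]:
    """Fit every family in the registry; support violations are skipped
    and the reason recorded."""
    if families is None:
        families = default_registry()
    fits: list[DistributionFit] = []
    skipped: dict[str, str] = {}
    for fam in families:
        try:
            fits.append(fit_family(samples, fam))
        except (SupportError, ValueError) as exc:
            skipped[fam.name] = str(exc)
    return fits, skipped


def select_best(fits: Sequence[DistributionFit]) -> str:
    """Lowest-AIC family among converged fits.

    Ties are broken by fewer parameters, then by the order the fits were
    supplied in (the registry order).
    """
    ranked = [
        (f.aic, f.n_params, i, f.family)
        for i, f in enumerate(fits)
        if f.converged and np.isfinite(f.aic)
    ]
    if not ranked:
        raise ValueError("no converged fits to select from")
    ranked.sort()
    return ranked[0][3]


def modal_best_family(
    best_families: Sequence[str],
    registry_order: Optional[Sequence[str]] = None,
) -> tuple[str, dict[str, int], bool]:
    """Most frequent best-fitting family across ROI fits.

    Returns (modal family, frequency table, tie flag); ties resolve to the
    earliest family in registry order.
    """
    names = list(best_families)
    if not names:
        raise ValueError("no best-family records")
    counts = Counter(names)
    top = max(counts.values())
    contenders = [k for k, v in counts.items() if v == top]
    tie = len(contenders) > 1
    if registry_order is None:
        registry_order = [f.name for f in default_registry()]
    order = {name: i for i, name in enumerate(registry_order)}
    contenders.sort(key=lambda k: order.get(k, len(order)))
    return contenders[0], dict(counts), tie


def summarize_region(
    left: Optional[ROISampleVector],
    right: Optional[ROISampleVector],
    families: Optional[Sequence[DistributionFamily]] = None,
    combine: str = "mean",
) -> RegionT2Summary:
    """Per-region log-logistic summary from the two hemisphere samples.

    A log-logistic fit is always computed per hemisphere; when a family
    registry is supplied, the AIC winner per hemisphere is reported
    alongside. Region-level (T2mu, T2sigma) combine the hemisphere
    estimates: unweighted mean (default), voxel-count-weighted mean, or a
    pooled refit on the concatenated samples.
    """
    hemis = {
        h: v for h, v in (("left", left), ("right", right))
        if v is not None and v.n > 0
    }
    if not hemis:
        raise ValueError("both hemispheres empty")
    if combine not in {"mean", "weighted", "pooled"}:
        raise ValueError(f"unknown combine mode '{combine}'")

    fits: dict[str, DistributionFit] = {}
    best: dict[str, str] = {}
    for h, vec in hemis.items():
        mu, sigma, ll, ok = fit_loglogistic_mle(vec.values)
        fits[h] = DistributionFit(
            family="loglogistic", params=(mu, sigma), loglik=ll,
            aic=aic(2, ll), n=vec.n, n_params=2, converged=ok,
        )
        if families is not None:
            all_fits, _ = fit_all_families(vec.values, families)
            best[h] = select_best(all_fits)
        else:
            best[h] = "loglogistic"

    region = next(iter(hemis.values())).region
    subject = next(iter(hemis.values())).subject_id
    if combine == "pooled" or len(hemis) == 1:
        if combine == "pooled":
            pooled = np.concatenate([v.values for v in hemis.values()])
            t2_mu, t2_sigma, _, _ = fit_loglogistic_mle(pooled)
        else:
            (only,) = fits.values()
            t2_mu, t2_sigma = only.params
    else:
        mus = np.array([fits[h].params[0] for h in hemis])
        sigmas = np.array([fits[h].params[1] for h in hemis])
        if combine == "weighted":
            w = np.array([float(hemis[h].n) for h in hemis])
            w = w / w.sum()
        else:
            w = np.full(len(hemis), 1.0 / len(hemis))
        t2_mu = float(mus @ w)
        t2_sigma = float(sigmas @ w)

    return RegionT2Summary(
        subject_id=subject,
        region=region,
        t2_mu=float(t2_mu),
        t2_sigma=float(t2_sigma),
        hemispheres=fits,
        best_family=best,
        n_voxels={h: v.n for h, v in hemis.items()},
        single_hemisphere=len(hemis) == 1,
    )
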