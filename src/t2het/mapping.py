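"""Voxelwise T2 estimation from multi-echo series and ROI extraction.

T2 maps are computed by unweighted least squares of log(signal) on echo
time (a logarithmic-space mono-exponential fit): log S = log s0 - TE/T2,
so T2 = -1/slope. For long CPMG echo trains the first echo is excluded
by default because it is biased by stimulated-echo contamination; short
TSE trains use all echoes.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import MultiEchoImage, ROISampleVector, T2Map

#: Physiological T2 bounds for brain tissue at 3T (ms); values outside are
#: excluded from distribution fits.
DEFAULT_LOWER_CAP_MS = 30.0
DEFAULT_UPPER_CAP_MS = 200.0

#: Echo count at or above which the first echo is dropped by default
#: (CPMG-like trains); shorter trains (TSE-like) keep every echo.
_EXCLUDE_FIRST_MIN_ECHOES = 10


def resolve_exclude_first(n_echoes: int, exclude_first: Optional[bool]) -> bool:
    """Default first-echo policy: drop it for trains of >= 10 echoes."""
    if exclude_first is None:
        return n_echoes >= _EXCLUDE_FIRST_MIN_ECHOES
    return bool(exclude_first)


def _ols_log_fit(log_s: np.ndarray, te: np.ndarray):
    """Vectorised OLS of log-signal on TE.

    Parameters
    ----------
    log_s : ndarray, shape (n_echoes, n_voxels)
    te : ndarray, shape (n_echoes,)

    Returns
    -------
    slope, intercept, r2 : ndarray, shape (n_voxels,)
    """
    te = te[:, None]
    te_mean = te.mean()
    y_mean = log_s.mean(axis=0)
    dte = te - te_mean
    dy = log_s - y_mean
    ss_te = float((dte**2).sum())
    slope = (dte * dy).sum(axis=0) / ss_te
    intercept = y_mean - slope * te_mean
    ss_tot = (dy**2).sum(axis=0)
    ss_reg = slope**2 * ss_te
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, ss_reg / ss_tot, 1.0)
    return slope, intercept, r2


def log_linear_fit(
    signals: Sequence[float],
    echo_times: Sequence[float],
    exclude_first: Optional[bool] = None,
) -> tuple[float, float, float, bool]:
    """Fit one voxel's echo series with a log-space mono-exponential.

    Parameters
    ----------
    signals : sequence of float
        Signal magnitude at each echo.
    echo_times : sequence of float
        Echo times (ms), strictly increasing, same length as ``signals``.
    exclude_first : bool, optional
        Drop the first echo before fitting. Default: True for >= 10
        echoes, False otherwise.

    Returns
    -------
    (t2_ms, s0, r2, valid)
        ``valid`` is False (no exception) when any used signal is <= 0,
        the fitted slope is non-negative, or fewer than 2 usable echoes
        remain; ``t2_ms`` is NaN in that case.
    """
    s = np.asarray(signals, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if s.shape != te.shape:
        raise ValueError(
            f"signals ({s.size}) and echo_times ({te.size}) length mismatch"
        )
    drop = resolve_exclude_first(te.size, exclude_first)
    if drop:
        s, te = s[1:], te[1:]
    if te.size < 2:
        raise ValueError("need at least 2 echoes after first-echo exclusion")
    if not np.all(np.isfinite(s)):
        return float("nan"), float("nan"), float("nan"), False
    if np.any(s <= 0):
        return float("nan"), float("nan"), float("nan"), False
    slope, intercept, r2 = _ols_log_fit(np.log(s)[:, None], te)
    slope, intercept, r2 = float(slope[0]), float(intercept[0]), float(r2[0])
    if not np.isfinite(slope) or slope >= 0:
        return float("nan"), float(np.exp(intercept)), r2, False
    return -1.0 / slope, float(np.exp(intercept)), r2, True


def compute_t2_map(
    image: MultiEchoImage,
    exclude_first: Optional[bool] = None,
    compute_r2: bool = True,
) -> T2Map:
    """Apply the log-linear T2 fit to every voxel of a multi-echo image.

    Voxels with any non-positive used signal or a non-decaying fit are
    flagged invalid and carry NaN.
    """
    drop = resolve_exclude_first(image.n_echoes, exclude_first)
    sig = image.signal
    te = image.echo_times
    if drop:
        sig, te = sig[1:], te[1:]
    if te.size < 2:
        raise ValueError("fewer than 2 echoes remain after first-echo exclusion")

    spatial = sig.shape[1:]
    flat = sig.reshape(sig.shape[0], -1)
    usable = np.all(np.isfinite(flat), axis=0) & np.all(flat > 0, axis=0)

    log_s = np.full_like(flat, np.nan)
    log_s[:, usable] = np.log(flat[:, usable])
    slope = np.full(flat.shape[1], np.nan)
    r2 = np.full(flat.shape[1], np.nan)
    if usable.any():
        sl, _ic, rr = _ols_log_fit(log_s[:, usable], te)
        slope[usable] = sl
        r2[usable] = rr

    valid = usable & np.isfinite(slope) & (slope < 0)
    t2 = np.full(flat.shape[1], np.nan)
    t2[valid] = -1.0 / slope[valid]
    return T2Map(
        t2=t2.reshape(spatial),
        valid=valid.reshape(spatial),
        fit_r2=r2.reshape(spatial) if compute_r2 else None,
        voxel_size=image.voxel_size,
    )


def sum_of_echoes(image: MultiEchoImage) -> np.ndarray:
    """Sum the signal across all echoes, yielding one structural volume."""
    return image.signal.sum(axis=0)


def combine_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise union of binary masks on a common grid.

    Used e.g. to merge hippocampal subfield masks into a whole-structure
    mask.
    """
    if len(masks) == 0:
        raise ValueError("no masks to combine")
    first = np.asarray(masks[0])
    out = first.astype(bool).copy()
    for m in masks[1:]:
        m = np.asarray(m)
        if m.shape != first.shape:
            raise ValueError(f"mask grid mismatch: {m.shape} vs {first.shape}")
        out |= m.astype(bool)
    return out


def extract_roi_samples(
    t2map: T2Map,
    mask: np.ndarray,
    lower_cap: float = DEFAULT_LOWER_CAP_MS,
    upper_cap: float = DEFAULT_UPPER_CAP_MS,
    region: str = "",
    hemisphere: str = "",
    subject_id: str = "",
) -> ROISampleVector:
    """Collect valid in-mask T2 values inside the physiological caps.

    Values outside the closed interval [lower_cap, upper_cap] are
    excluded (not clipped) and counted; invalid voxels are counted
    separately. Boundary values are kept.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != t2map.t2.shape:
        raise ValueError(f"mask grid {mask.shape} != map grid {t2map.t2.shape}")
    if lower_cap >= upper_cap:
        raise ValueError("lower_cap must be below upper_cap")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("empty ROI mask")

    vals = t2map.t2[mask]
    ok = t2map.valid[mask]
    n_invalid = int((~ok).sum())
    vals = vals[ok]
    low = vals < lower_cap
    high = vals > upper_cap
    kept = vals[~(low | high)]
    return ROISampleVector(
        values=kept,
        region=region,
        hemisphere=hemisphere,
        subject_id=subject_id,
        n_excluded_low=int(low.sum()),
        n_excluded_high=int(high.sum()),
        n_invalid=n_invalid,
    )


def roi_volume(mask: np.ndarray, voxel_size: Sequence[float]) -> float:
    """ROI volume in mm^3: voxel count times voxel volume."""
    mask = np.asarray(mask).astype(bool)
    vol = float(np.prod(np.asarray(voxel_size, dtype=float)))
    return float(mask.sum()) * vol
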