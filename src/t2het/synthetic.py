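"""Synthetic cohorts, ground-truth T2 fields and multi-echo phantoms.

Real multi-echo MRI of ageing cohorts is rarely shareable, so every
downstream stage is validated against simulated data with the same
statistical structure the analysis assumes:

* per-voxel mono-exponential echo decay S(TE) = s0 exp(-TE/T2) under
  magnitude (Rician) noise;
* subject-level regional T2 values drawn from a log-logistic(mu, sigma)
  law, with additive group offsets on mu and sigma and linear age slopes
  (MCI: wider distributions; AD: longer midpoint);
* longitudinal cognition linear in age, baseline cognition and the
  regional heterogeneity sigma.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .mapping import compute_t2_map
from .distributions import fit_loglogistic_mle_batch
from .types import MultiEchoImage

GROUPS = ("HC", "MCI", "AD")

#: Echo-time presets (ms). The CPMG train is 10 echoes at 12 ms spacing
#: (first echo conventionally excluded from fits); the TSE variant has 3
#: echoes at 9.1, 72 and 136 ms.
ECHO_PRESETS: dict[str, tuple[float, ...]] = {
    "cpmg10": tuple(12.0 * k for k in range(1, 11)),
    "tse3": (9.1, 72.0, 136.0),
}

#: Log-logistic example parameters for a healthy-control and an MCI
#: hippocampus (log-median mu in log-ms, shape sigma dimensionless); used
#: as simulator anchors and in parameter-recovery checks.
EXAMPLE_HC_PARAMS = (4.68, 0.112)
EXAMPLE_MCI_PARAMS = (4.71, 0.135)

_T2_SAMPLE_RANGE_MS = (1.0, 1000.0)
_AGE_RANGE = (40.0, 100.0)


class SpecValidationError(ValueError):
    """A cohort/phantom spec field failed validation."""


@dataclass(frozen=True)
class CognitionCoeffs:
    """Generating model for longitudinal cognition.

    Baseline cognition is group mean + age slope + noise on a z-like
    scale (healthy controls centred at 0). Follow-up cognition is the
    linear form

        followup = intercept + b_age * age + b_baseline * baseline
                   + b_sigma * sigma_true + Normal(0, error_sd),

    so a negative ``beta_sigma`` makes higher T2 heterogeneity predict
    steeper one-year cognitive decline.
    """

    baseline_mean: dict = field(
        default_factory=lambda: {"HC": 0.0, "MCI": -4.08, "AD": -8.50}
    )
    baseline_sd: dict = field(
        default_factory=lambda: {"HC": 1.00, "MCI": 2.09, "AD": 3.15}
    )
    baseline_age_slope: float = -0.03
    beta_intercept: float = 6.3
    beta_age: float = -0.05
    beta_baseline: float = 0.9
    beta_sigma: float = -30.0
    error_sd: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generating parameters.

    Group sizes, age and sex structure default to a two-study memory
    cohort of 97 healthy controls, 49 MCI and 10 AD participants. Group
    effects enter as additive offsets on the regional log-logistic
    parameters: ``mu_true = baseline_mu0 + delta_mu[group] +
    slope_mu_age * (age - 70)`` and analogously for sigma.
    """

    group_sizes: tuple[int, int, int] = (97, 49, 10)
    age_mean: dict = field(
        default_factory=lambda: {"HC": 69.3, "MCI": 72.2, "AD": 77.9}
    )
    age_sd: dict = field(
        default_factory=lambda: {"HC": 8.58, "MCI": 9.03, "AD": 9.94}
    )
    male_fraction: dict = field(
        default_factory=lambda: {"HC": 46 / 97, "MCI": 27 / 49, "AD": 2 / 10}
    )
    yoe_mean: dict = field(
        default_factory=lambda: {"HC": 15.8, "MCI": 14.2, "AD": 13.1}
    )
    yoe_sd: dict = field(
        default_factory=lambda: {"HC": 3.16, "MCI": 2.81, "AD": 2.60}
    )
    study_labels: tuple[str, ...] = ("study1", "study2")
    #: per-group subject counts per study; None = split proportionally
    study_counts: Optional[dict] = field(
        default_factory=lambda: {"HC": (50, 47), "MCI": (30, 19), "AD": (10, 0)}
    )
    regions: tuple[str, ...] = ("hippocampus",)
    baseline_mu0: float = 4.68  # log-ms at age 70 in healthy controls
    baseline_sigma0: float = 0.113
    delta_mu: dict = field(
        default_factory=lambda: {"HC": 0.0, "MCI": 0.0, "AD": 0.03}
    )
    delta_sigma: dict = field(
        default_factory=lambda: {"HC": 0.0, "MCI": 0.02, "AD": 0.02}
    )
    slope_mu_age: float = 0.0  # log-ms per year
    slope_sigma_age: float = 0.001  # per year
    volume_mean: float = 3200.0  # mm^3
    volume_sd: float = 300.0
    slope_vol_age: float = 0.0  # mm^3 per year; sign deliberately open
    icv_mean: float = 1.5e6  # mm^3
    icv_sd: float = 1.5e5
    cognition: CognitionCoeffs = field(default_factory=CognitionCoeffs)
    seed: int = 0

    def validate(self) -> None:
        if len(self.group_sizes) != len(GROUPS):
            raise SpecValidationError("group_sizes must have 3 entries (HC, MCI, AD)")
        if any(n < 0 for n in self.group_sizes):
            raise SpecValidationError("group_sizes must be non-negative")
        for g in GROUPS:
            if self.age_sd[g] <= 0:
                raise SpecValidationError(f"age_sd[{g}] must be positive")
            if not 0.0 <= self.male_fraction[g] <= 1.0:
                raise SpecValidationError(f"male_fraction[{g}] outside [0, 1]")
        if self.baseline_sigma0 <= 0:
            raise SpecValidationError("baseline_sigma0 must be positive")
        lo, hi = _AGE_RANGE
        for g in GROUPS:
            for age in (lo, hi):
                s = (
                    self.baseline_sigma0
                    + self.delta_sigma[g]
                    + self.slope_sigma_age * (age - 70.0)
                )
                if s <= 0:
                    raise SpecValidationError(
                        f"sigma_true non-positive for group {g} at age {age}"
                    )
        if not self.study_labels:
            raise SpecValidationError("study_labels must name at least one study")
        if self.study_counts is not None:
            for g, n in zip(GROUPS, self.group_sizes):
                counts = self.study_counts.get(g)
                if counts is None or len(counts) != len(self.study_labels):
                    raise SpecValidationError(
                        f"study_counts[{g}] must give one count per study"
                    )
                if sum(counts) != n:
                    raise SpecValidationError(
                        f"study_counts[{g}] sums to {sum(counts)}, expected {n}"
                    )
        if self.icv_mean <= 0 or self.icv_sd < 0:
            raise SpecValidationError("icv_mean must be positive, icv_sd >= 0")


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def mask(self, grid_shape: Sequence[int]) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=float)
        d = sum(
            ((idx[k] - self.center[k]) / self.semiaxes[k]) ** 2 for k in range(3)
        )
        return d <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and acquisition parameters of the synthetic phantom."""

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (0.34, 0.34, 1.7)
    #: region -> {"left": Ellipsoid, "right": Ellipsoid}
    roi_geometry: dict = field(default_factory=dict)
    echo_times: tuple[float, ...] = ECHO_PRESETS["cpmg10"]
    s0: float = 1.0
    noise_sd: float = 0.02
    noise_model: str = "rician"
    background_t2: float = 80.0  # ms

    def validate(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 2 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise SpecValidationError("echo_times must be >0 and strictly increasing")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd must be non-negative")
        if self.noise_model not in {"rician", "gaussian", "none"}:
            raise SpecValidationError(f"unknown noise_model '{self.noise_model}'")
        if not self.roi_geometry:
            raise SpecValidationError("roi_geometry must define at least one region")
        occupied = np.zeros(self.grid_shape, dtype=bool)
        for region, hemis in self.roi_geometry.items():
            for hemi in ("left", "right"):
                ell = hemis[hemi]
                for k in range(3):
                    if (
                        ell.center[k] - ell.semiaxes[k] < 0
                        or ell.center[k] + ell.semiaxes[k] > self.grid_shape[k] - 1
                    ):
                        raise SpecValidationError(
                            f"{region}/{hemi} ellipsoid exceeds the grid"
                        )
                m = ell.mask(self.grid_shape)
                if not m.any():
                    raise SpecValidationError(f"{region}/{hemi} ROI has 0 voxels")
                if (occupied & m).any():
                    raise SpecValidationError(f"{region}/{hemi} overlaps another ROI")
                occupied |= m


def make_phantom(
    regions: Sequence[str] = ("hippocampus",),
    echo_preset: str = "cpmg10",
    **overrides,
) -> PhantomSpec:
    """Build a phantom with a simple default layout.

    Each region gets a left/right ellipsoid pair on its own y-slab of a
    32 x (32 per region) x 16 grid.
    """
    ny = 32 * len(regions)
    grid = overrides.pop("grid_shape", (32, ny, 16))
    geometry = {}
    for i, region in enumerate(regions):
        y0 = (grid[1] / len(regions)) * (i + 0.5)
        geometry[region] = {
            "left": Ellipsoid((9.0, y0, 7.5), (5.0, 7.0, 5.0)),
            "right": Ellipsoid((22.0, y0, 7.5), (5.0, 7.0, 5.0)),
        }
    spec = PhantomSpec(
        grid_shape=tuple(grid),
        roi_geometry=geometry,
        echo_times=ECHO_PRESETS[echo_preset] if echo_preset != "custom"
        else tuple(overrides.pop("echo_times")),
        **overrides,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Normal draws with redraw (not clipping) outside [lo, hi]."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _study_assignment(spec: CohortSpec, group: str, n: int) -> list[str]:
    labels = spec.study_labels
    if spec.study_counts is not None:
        counts = spec.study_counts[group]
    else:  # largest-remainder proportional split
        base = [n // len(labels)] * len(labels)
        for k in range(n - sum(base)):
            base[k % len(labels)] += 1
        counts = base
    out: list[str] = []
    for label, c in zip(labels, counts):
        out.extend([label] * int(c))
    return out


def generate_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject: id, study, group, sex, age, YOE, ICV.

    Ages are Normal(group mean, sd) redrawn into [40, 100]; sex counts per
    group follow the configured male fraction deterministically.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for group, n in zip(GROUPS, spec.group_sizes):
        if n == 0:
            continue
        ages = _truncated_normal(
            rng, spec.age_mean[group], spec.age_sd[group], *_AGE_RANGE, size=n
        )
        yoe = rng.normal(spec.yoe_mean[group], spec.yoe_sd[group], size=n)
        icv = _truncated_normal(
            rng, spec.icv_mean, spec.icv_sd, 0.5 * spec.icv_mean,
            1.5 * spec.icv_mean, size=n,
        )
        n_male = int(round(n * spec.male_fraction[group]))
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sexes)
        studies = _study_assignment(spec, group, n)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"sub-{sid:04d}",
                    "study": studies[i],
                    "group": group,
                    "sex": sexes[i],
                    "age": float(ages[i]),
                    "yoe": float(yoe[i]),
                    "icv_mm3": float(icv[i]),
                }
            )
            sid += 1
    columns = ["subject_id", "study", "group", "sex", "age", "yoe", "icv_mm3"]
    return pd.DataFrame(rows, columns=columns)


def sample_subject_t2_params(row, spec: CohortSpec) -> dict[str, tuple[float, float]]:
    """True regional (mu, sigma) for one subject: baseline + group offset
    + linear age slope centred at 70 years."""
    group = row["group"]
    age = float(row["age"])
    mu = spec.baseline_mu0 + spec.delta_mu[group] + spec.slope_mu_age * (age - 70.0)
    sigma = (
        spec.baseline_sigma0
        + spec.delta_sigma[group]
        + spec.slope_sigma_age * (age - 70.0)
    )
    if sigma <= 0:
        raise SpecValidationError(
            f"sigma_true = {sigma:.4g} <= 0 for group {group}, age {age:.1f}"
        )
    return {region: (float(mu), float(sigma)) for region in spec.regions}


def generate_ground_truth(spec: CohortSpec) -> pd.DataFrame:
    """Cohort table augmented with per-region true (mu, sigma) and volume.

    Volumes are Normal(volume_mean, volume_sd) plus the configured age
    slope; the T2 parameters are the deterministic group/age model of
    :func:`sample_subject_t2_params`.
    """
    cohort = generate_cohort_table(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    for region in spec.regions:
        mus, sigmas = [], []
        for _, row in cohort.iterrows():
            mu, sigma = sample_subject_t2_params(row, spec)[region]
            mus.append(mu)
            sigmas.append(sigma)
        cohort[f"{region}_mu_true"] = mus
        cohort[f"{region}_sigma_true"] = sigmas
        vol = (
            rng.normal(spec.volume_mean, spec.volume_sd, size=len(cohort))
            + spec.slope_vol_age * (cohort["age"].to_numpy() - 70.0)
        )
        cohort[f"{region}_volume_mm3"] = np.maximum(vol, 1.0)
    return cohort


# ---------------------------------------------------------------------------
# imaging simulation
# ---------------------------------------------------------------------------

def sample_loglogistic(
    mu: float,
    sigma: float,
    size,
    rng: np.random.Generator,
    valid_range: tuple[float, float] = _T2_SAMPLE_RANGE_MS,
) -> np.ndarray:
    """Inverse-CDF log-logistic draws, x = exp(mu + sigma logit(u)).

    Samples outside ``valid_range`` (default 1-1000 ms) are redrawn, not
    clipped, to avoid density spikes at the bounds.
    """
    lo, hi = valid_range
    out = np.exp(mu + sigma * special.logit(rng.uniform(size=size)))
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        redraw = np.exp(mu + sigma * special.logit(rng.uniform(size=int(bad.sum()))))
        out[bad] = redraw
        bad = (out <= lo) | (out >= hi)
    return out


def render_t2_field(
    truth_params: dict,
    phantom: PhantomSpec,
    seed,
) -> tuple[np.ndarray, dict]:
    """Realise a ground-truth T2 field on the phantom grid.

    In-ROI voxels draw T2 ~ log-logistic(mu_true, sigma_true) for their
    region; background voxels carry a fixed background T2. Returns the
    field and binary masks per region/hemisphere (plus a combined mask
    per region).
    """
    phantom.validate()
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    field_arr = np.full(phantom.grid_shape, phantom.background_t2, dtype=float)
    masks: dict[str, dict[str, np.ndarray]] = {}
    for region, hemis in phantom.roi_geometry.items():
        mu, sigma = truth_params[region]
        masks[region] = {}
        for hemi in ("left", "right"):
            m = hemis[hemi].mask(phantom.grid_shape)
            field_arr[m] = sample_loglogistic(mu, sigma, int(m.sum()), rng)
            masks[region][hemi] = m
    return field_arr, masks


def simulate_multi_echo(
    t2_field: np.ndarray,
    phantom: PhantomSpec,
    seed,
) -> MultiEchoImage:
    """Mono-exponential multi-echo signal with optional magnitude noise.

    Noiseless signal is S(TE) = s0 exp(-TE/T2) per voxel. Rician noise
    takes the magnitude of (S + n1, n2) with independent Normal(0,
    noise_sd) channels — the physics of magnitude MRI — so all signals
    stay non-negative; ``gaussian`` adds n1 only; ``none`` is exact.
    """
    if phantom.noise_sd < 0:
        raise SpecValidationError("noise_sd must be non-negative")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t2 = np.asarray(t2_field, dtype=float)
    te = np.asarray(phantom.echo_times, dtype=float)
    shape = (te.size,) + t2.shape
    s = phantom.s0 * np.exp(-te.reshape((-1,) + (1,) * t2.ndim) / t2)
    if phantom.noise_model == "none" or phantom.noise_sd == 0:
        signal = s
    elif phantom.noise_model == "gaussian":
        signal = s + rng.normal(0.0, phantom.noise_sd, size=shape)
    elif phantom.noise_model == "rician":
        n1 = rng.normal(0.0, phantom.noise_sd, size=shape)
        n2 = rng.normal(0.0, phantom.noise_sd, size=shape)
        signal = np.hypot(s + n1, n2)
    else:
        raise SpecValidationError(f"unknown noise_model '{phantom.noise_model}'")
    return MultiEchoImage(
        signal=signal, echo_times=te, voxel_size=phantom.voxel_size
    )


def simulate_cognition(
    cohort: pd.DataFrame,
    sigma_true: Sequence[float],
    coeffs: CognitionCoeffs,
    seed,
) -> pd.DataFrame:
    """Append baseline and follow-up cognition columns.

    Baseline: group mean + age slope + Normal noise. Follow-up: the
    linear generating model in age, baseline and true regional sigma.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sigma_true = np.asarray(sigma_true, dtype=float)
    if sigma_true.shape[0] != len(cohort):
        raise SpecValidationError(
            "sigma_true must supply one value per cohort row"
        )
    out = cohort.copy()
    age = out["age"].to_numpy(dtype=float)
    gmean = out["group"].map(coeffs.baseline_mean).to_numpy(dtype=float)
    gsd = out["group"].map(coeffs.baseline_sd).to_numpy(dtype=float)
    baseline = (
        gmean
        + coeffs.baseline_age_slope * (age - 70.0)
        + rng.normal(0.0, 1.0, size=len(out)) * gsd
    )
    followup = (
        coeffs.beta_intercept
        + coeffs.beta_age * age
        + coeffs.beta_baseline * baseline
        + coeffs.beta_sigma * sigma_true
        + (rng.normal(0.0, coeffs.error_sd, size=len(out)) if coeffs.error_sd > 0
           else 0.0)
    )
    out["cog_baseline"] = baseline
    out["cog_followup"] = followup
    return out


# ---------------------------------------------------------------------------
# fast flat-ROI measurement chain (for calibration / power simulations)
# ---------------------------------------------------------------------------

def measure_roi_params(
    mu_true: np.ndarray,
    sigma_true: np.ndarray,
    n_voxels: int,
    seed,
    echo_times: Sequence[float] = ECHO_PRESETS["cpmg10"],
    snr: Optional[float] = 50.0,
    exclude_first: Optional[bool] = None,
    caps: tuple[float, float] = (30.0, 200.0),
    noise_model: str = "rician",
):
    """Simulate the full measurement chain for flat (geometry-free) ROIs.

    For each subject: draw ``n_voxels`` T2 values from the subject's
    log-logistic law, synthesise the multi-echo decay at SNR = s0 /
    noise_sd, refit T2 voxelwise in log space, apply the physiological
    caps, and re-estimate (mu, sigma) by MLE. ``snr=None`` skips the
    imaging chain (the MLE sees the rendered T2 values directly).

    Returns
    -------
    (mu_hat, sigma_hat, converged) : arrays, one entry per subject
    """
    mu_true = np.atleast_1d(np.asarray(mu_true, dtype=float))
    sigma_true = np.atleast_1d(np.asarray(sigma_true, dtype=float))
    if mu_true.shape != sigma_true.shape:
        raise ValueError("mu_true and sigma_true must align")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_sub = mu_true.size
    lo, hi = _T2_SAMPLE_RANGE_MS
    u = rng.uniform(size=(n_sub, n_voxels))
    t2 = np.exp(mu_true[:, None] + sigma_true[:, None] * special.logit(u))
    bad = (t2 <= lo) | (t2 >= hi)
    while bad.any():
        redraw = rng.uniform(size=int(bad.sum()))
        t2[bad] = np.exp(
            (np.broadcast_to(mu_true[:, None], t2.shape)[bad])
            + np.broadcast_to(sigma_true[:, None], t2.shape)[bad]
            * special.logit(redraw)
        )
        bad = (t2 <= lo) | (t2 >= hi)

    if snr is not None:
        phantom = PhantomSpec(
            roi_geometry={},  # geometry-free: flat voxel vectors
            echo_times=tuple(echo_times),
            s0=1.0,
            noise_sd=1.0 / snr,
            noise_model=noise_model,
        )
        image = simulate_multi_echo(t2, phantom, rng)
        t2map = compute_t2_map(image, exclude_first=exclude_first, compute_r2=False)
        est = t2map.t2
        ok = t2map.valid & (est >= caps[0]) & (est <= caps[1])
        vals = np.where(ok, est, 1.0)
    else:
        vals = t2
        ok = np.ones_like(t2, dtype=bool)
    mu_hat, sigma_hat, _ll, conv = fit_loglogistic_mle_batch(vals, mask=ok)
    return mu_hat, sigma_hat, conv


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """A copy of the spec with a different root seed."""
    return replace(spec, seed=int(seed))
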