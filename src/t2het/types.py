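"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class MultiEchoImage:
    """A multi-echo T2-weighted acquisition.

    Parameters
    ----------
    signal : ndarray
        Non-negative signal magnitudes with the echo axis first,
        shape ``(n_echoes, *spatial)``. Spatial shape is arbitrary
        (a full 3D grid or a flat vector of ROI voxels).
    echo_times : ndarray
        Echo times in milliseconds, strictly increasing, one per echo.
    voxel_size : tuple of float
        Voxel dimensions in millimetres.
    """

    signal: np.ndarray
    echo_times: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.echo_times.ndim != 1 or self.echo_times.size < 2:
            raise ValueError("echo_times must be a 1D list of at least 2 times")
        if self.signal.shape[0] != self.echo_times.size:
            raise ValueError(
                f"signal has {self.signal.shape[0]} echoes but "
                f"{self.echo_times.size} echo times were given"
            )
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if np.any(self.echo_times <= 0):
            raise ValueError("echo_times must all be positive")

    @property
    def n_echoes(self) -> int:
        return int(self.signal.shape[0])

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return tuple(self.signal.shape[1:])


@dataclass
class T2Map:
    """Voxelwise T2 estimates (ms) with a validity mask.

    Invalid voxels (non-positive signal at a used echo, non-decaying fit,
    or too few usable echoes) carry NaN in ``t2`` and False in ``valid``;
    they are excluded from all downstream sampling.
    """

    t2: np.ndarray
    valid: np.ndarray
    fit_r2: Optional[np.ndarray] = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.t2 = np.asarray(self.t2, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.t2.shape != self.valid.shape:
            raise ValueError("t2 and valid must share a shape")


@dataclass
class ROISampleVector:
    """Physiologically capped T2 samples from one ROI.

    ``values`` holds valid in-mask T2 values inside the closed interval
    [lower_cap, upper_cap]; the exclusion counters account for every
    other in-mask voxel.
    """

    values: np.ndarray
    region: str = ""
    hemisphere: str = ""
    subject_id: str = ""
    n_excluded_low: int = 0
    n_excluded_high: int = 0
    n_invalid: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class DistributionFit:
    """One distribution family fitted by MLE to one ROI sample."""

    family: str
    params: tuple[float, ...]
    loglik: float
    aic: float
    n: int
    n_params: int
    converged: bool = True
    message: str = ""


@dataclass
class RegionT2Summary:
    """Per subject/region log-logistic summary.

    T2mu is the log-median (log-ms) and T2sigma the shape (heterogeneity)
    of the regional T2 distribution; region values combine the two
    hemisphere fits (unweighted mean by default).
    """

    subject_id: str
    region: str
    t2_mu: float
    t2_sigma: float
    hemispheres: dict = field(default_factory=dict)  # hemi -> DistributionFit
    best_family: dict = field(default_factory=dict)  # hemi -> family name
    n_voxels: dict = field(default_factory=dict)  # hemi -> sample size
    single_hemisphere: bool = False
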