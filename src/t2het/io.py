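"""File I/O: NIfTI volumes with YAML echo-time sidecars, masks, tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import MultiEchoImage, ROISampleVector, T2Map

COHORT_COLUMNS = [
    "subject_id", "study", "group", "sex", "age", "yoe", "icv_mm3",
    "cog_baseline", "cog_followup",
]


def _affine(voxel_size: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_multi_echo(image: MultiEchoImage, path, sidecar_path=None) -> None:
    """Write a multi-echo image as 4D NIfTI-1 (x, y, z, echo) plus a YAML
    sidecar listing echo times in ms."""
    path = Path(path)
    data = np.moveaxis(image.signal, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(image.voxel_size)), str(path))
    if sidecar_path is None:
        sidecar_path = path.with_suffix("").with_suffix("")  # strip .nii.gz
        sidecar_path = Path(str(sidecar_path) + ".yaml")
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(
            {"echo_times_ms": [float(t) for t in image.echo_times]}, fh
        )


def load_multi_echo(path, sidecar_path=None) -> MultiEchoImage:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D multi-echo volume")
    if sidecar_path is None:
        base = path.with_suffix("").with_suffix("")
        sidecar_path = Path(str(base) + ".yaml")
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MultiEchoImage(
        signal=np.moveaxis(data, -1, 0),
        echo_times=np.asarray(meta["echo_times_ms"], dtype=float),
        voxel_size=voxel,
    )


def save_t2_map(t2map: T2Map, path) -> None:
    """Float32 NIfTI-1 T2 map; invalid voxels carry NaN."""
    data = np.where(t2map.valid, t2map.t2, np.nan).astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(t2map.voxel_size)), str(path))


def load_t2_map(path) -> T2Map:
    img = nib.load(str(path))
    t2 = np.asarray(img.dataobj, dtype=float)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return T2Map(t2=t2, valid=np.isfinite(t2) & (t2 > 0), voxel_size=voxel)


def save_mask(mask: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size)),
        str(path),
    )


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_roi_samples(vectors: Sequence[ROISampleVector], path) -> None:
    """Tidy CSV of ROI T2 samples (one row per voxel)."""
    frames = []
    for v in vectors:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": v.subject_id,
                    "region": v.region,
                    "hemisphere": v.hemisphere,
                    "t2_ms": v.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_roi_samples(path) -> list[ROISampleVector]:
    df = pd.read_csv(path)
    out = []
    for (sid, region, hemi), g in df.groupby(
        ["subject_id", "region", "hemisphere"], sort=True
    ):
        out.append(
            ROISampleVector(
                values=g["t2_ms"].to_numpy(dtype=float),
                region=str(region), hemisphere=str(hemi), subject_id=str(sid),
            )
        )
    return out


def save_ground_truth(truth: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(orient="list"), fh, indent=1)


def load_ground_truth(path) -> pd.DataFrame:
    with open(path) as fh:
        return pd.DataFrame(json.load(fh))
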