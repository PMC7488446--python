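"""End-to-end orchestration: simulate -> t2map -> extract -> fitdist -> stats.

A single YAML config drives all five stages. Every stochastic stage
derives its seed deterministically from the global seed plus the stage
name, so two runs from the same config are byte-identical. Stages are
cached: a stage is skipped when its config-section hash and upstream
hashes are unchanged and its outputs still match their recorded
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as t2io
from .cohort_stats import (
    age_regression,
    ancova_group,
    followup_regression,
    icv_correct,
    zscore_to_reference,
)
from .distributions import registry_by_name, summarize_region
from .mapping import compute_t2_map, extract_roi_samples, roi_volume
from .synthetic import (
    ECHO_PRESETS,
    CohortSpec,
    CognitionCoeffs,
    PhantomSpec,
    SpecValidationError,
    generate_ground_truth,
    make_phantom,
    render_t2_field,
    simulate_cognition,
    simulate_multi_echo,
)

log = logging.getLogger("t2het")

STAGES = ("simulate", "t2map", "extract", "fitdist", "stats")

_DEFAULTS: dict = {
    "seed": 0,
    "log_level": "INFO",
    "caps": [30.0, 200.0],
    "exclude_first": None,  # auto: True for >= 10 echoes
    "families": "loglogistic",
    "combine": "mean",
    "metrics": ["t2_sigma", "t2_mu", "volume"],
    "cohort": {},  # overrides applied to CohortSpec defaults
    "phantom": {
        "echo_preset": "cpmg10",
        "noise_sd": 0.02,
        "noise_model": "rician",
    },
}

_KNOWN_KEYS = set(_DEFAULTS)
_KNOWN_PHANTOM_KEYS = {
    "echo_preset", "echo_times", "noise_sd", "noise_model", "s0",
    "grid_shape", "voxel_size", "background_t2",
}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    caps: tuple[float, float]
    exclude_first: Optional[bool]
    families: str
    combine: str
    metrics: list
    cohort_spec: CohortSpec
    phantom_spec: PhantomSpec
    log_level: str = "INFO"
    raw: dict = dataclasses.field(default_factory=dict)


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def validate_config(raw_text: str = "") -> RunConfig:
    """Parse and validate a YAML config, applying defaults.

    An empty document yields the full default configuration. All
    problems (unknown keys, wrong types, bad orderings) are reported
    together.
    """
    data = yaml.safe_load(raw_text) if raw_text.strip() else {}
    if data is None:
        data = {}
    errors: list[str] = []
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])

    for key in data:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown config key '{key}'")
    merged = {**_DEFAULTS, **{k: v for k, v in data.items() if k in _KNOWN_KEYS}}

    caps = merged["caps"]
    if (
        not isinstance(caps, (list, tuple)) or len(caps) != 2
        or not all(isinstance(c, (int, float)) for c in caps)
    ):
        errors.append("caps must be two numbers")
    elif caps[0] >= caps[1]:
        errors.append(f"caps must be increasing, got {caps}")

    phantom_over = dict(_DEFAULTS["phantom"])
    if not isinstance(merged["phantom"], dict):
        errors.append("phantom must be a mapping")
    else:
        for key in merged["phantom"]:
            if key not in _KNOWN_PHANTOM_KEYS:
                errors.append(f"unknown phantom key '{key}'")
        phantom_over.update(merged["phantom"])
    preset = phantom_over.pop("echo_preset", "cpmg10")
    if preset not in set(ECHO_PRESETS) | {"custom"}:
        errors.append(f"unknown echo preset '{preset}'")
        preset = "cpmg10"
    if preset == "custom":
        te = phantom_over.get("echo_times")
        if not te or list(te) != sorted(te) or len(set(te)) != len(te):
            errors.append("custom preset needs strictly increasing echo_times")

    cohort_over = merged["cohort"]
    if not isinstance(cohort_over, dict):
        errors.append("cohort must be a mapping")
        cohort_over = {}
    cohort_fields = {f.name for f in dataclasses.fields(CohortSpec)}
    for key in cohort_over:
        if key not in cohort_fields:
            errors.append(f"unknown cohort key '{key}'")

    if merged["combine"] not in {"mean", "weighted", "pooled"}:
        errors.append(f"unknown combine mode '{merged['combine']}'")
    try:
        registry_by_name(merged["families"])
    except ValueError as exc:
        errors.append(str(exc))

    cohort_spec = None
    phantom_spec = None
    if not errors:
        try:
            over = {
                k: v for k, v in cohort_over.items() if k in cohort_fields
            }
            if "group_sizes" in over:
                over["group_sizes"] = tuple(over["group_sizes"])
                if over["group_sizes"] != (97, 49, 10) and "study_counts" not in over:
                    over["study_counts"] = None
            if "regions" in over:
                over["regions"] = tuple(over["regions"])
            if "cognition" in over:
                over["cognition"] = CognitionCoeffs(**over["cognition"])
            cohort_spec = dataclasses.replace(
                CohortSpec(seed=int(merged["seed"])), **over
            )
            cohort_spec.validate()
            regions = cohort_spec.regions
            if "grid_shape" in phantom_over:
                phantom_over["grid_shape"] = tuple(phantom_over["grid_shape"])
            if "voxel_size" in phantom_over:
                phantom_over["voxel_size"] = tuple(phantom_over["voxel_size"])
            phantom_spec = make_phantom(
                regions=regions, echo_preset=preset, **phantom_over
            )
        except (SpecValidationError, TypeError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigError(errors)
    return RunConfig(
        seed=int(merged["seed"]),
        caps=(float(caps[0]), float(caps[1])),
        exclude_first=merged["exclude_first"],
        families=merged["families"],
        combine=merged["combine"],
        metrics=list(merged["metrics"]),
        cohort_spec=cohort_spec,
        phantom_spec=phantom_spec,
        log_level=str(merged["log_level"]),
        raw=merged,
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _file_sha(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_config(config: RunConfig, stage: str) -> dict:
    """The config subset a stage's outputs depend on."""
    c = config.raw
    if stage == "simulate":
        return {
            "seed": config.seed, "cohort": c["cohort"], "phantom": c["phantom"],
        }
    if stage == "t2map":
        return {"exclude_first": config.exclude_first}
    if stage == "extract":
        return {"caps": list(config.caps)}
    if stage == "fitdist":
        return {"families": config.families, "combine": config.combine}
    if stage == "stats":
        return {"metrics": config.metrics}
    raise ValueError(stage)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    spec = config.cohort_spec
    phantom = config.phantom_spec
    truth = generate_ground_truth(spec)
    rng = np.random.default_rng(stage_seed(config.seed, "simulate"))
    region0 = spec.regions[0]
    truth = simulate_cognition(
        truth, truth[f"{region0}_sigma_true"].to_numpy(), spec.cognition, rng
    )
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    paths = []
    masks_written = False
    for _, row in truth.iterrows():
        sid = row["subject_id"]
        params = {
            r: (row[f"{r}_mu_true"], row[f"{r}_sigma_true"]) for r in spec.regions
        }
        field_arr, masks = render_t2_field(params, phantom, rng)
        image = simulate_multi_echo(field_arr, phantom, rng)
        img_path = out / "images" / f"{sid}_t2w.nii.gz"
        t2io.save_multi_echo(image, img_path)
        paths += [img_path, out / "images" / f"{sid}_t2w.yaml"]
        if not masks_written:  # shared geometry: one mask set per run
            for region, hemis in masks.items():
                for hemi, m in hemis.items():
                    mp = out / "masks" / f"{region}_{hemi}.nii.gz"
                    t2io.save_mask(m, mp, phantom.voxel_size)
                    paths.append(mp)
            masks_written = True
    cohort_path = out / "cohort.csv"
    truth_path = out / "truth.json"
    cohort_cols = t2io.COHORT_COLUMNS + [
        f"{r}_volume_mm3" for r in spec.regions
    ]
    truth.to_csv(truth_path.with_suffix(".csv"), index=False)
    t2io.save_ground_truth(truth, truth_path)
    truth[cohort_cols].to_csv(cohort_path, index=False)
    return paths + [cohort_path, truth_path, truth_path.with_suffix(".csv")]


def _stage_t2map(config: RunConfig, out: Path) -> list[Path]:
    (out / "maps").mkdir(exist_ok=True)
    paths = []
    for img_path in sorted((out / "images").glob("*_t2w.nii.gz")):
        image = t2io.load_multi_echo(img_path)
        t2map = compute_t2_map(image, exclude_first=config.exclude_first)
        map_path = out / "maps" / img_path.name.replace("_t2w", "_t2map")
        t2io.save_t2_map(t2map, map_path)
        paths.append(map_path)
    return paths


def _stage_extract(config: RunConfig, out: Path) -> list[Path]:
    (out / "samples").mkdir(exist_ok=True)
    masks = {}
    for mp in sorted((out / "masks").glob("*.nii.gz")):
        region, hemi = mp.name.replace(".nii.gz", "").rsplit("_", 1)
        masks[(region, hemi)] = t2io.load_mask(mp)
    vectors = []
    vol_rows = []
    voxel = config.phantom_spec.voxel_size
    for map_path in sorted((out / "maps").glob("*_t2map.nii.gz")):
        sid = map_path.name.replace("_t2map.nii.gz", "")
        t2map = t2io.load_t2_map(map_path)
        for (region, hemi), m in masks.items():
            vectors.append(
                extract_roi_samples(
                    t2map, m, *config.caps,
                    region=region, hemisphere=hemi, subject_id=sid,
                )
            )
            vol_rows.append(
                {
                    "subject_id": sid, "region": region, "hemisphere": hemi,
                    "roi_volume_mm3": roi_volume(m, voxel),
                }
            )
    samples_path = out / "samples" / "samples.csv"
    t2io.save_roi_samples(vectors, samples_path)
    vol_path = out / "samples" / "roi_volumes.csv"
    pd.DataFrame(vol_rows).to_csv(vol_path, index=False)
    return [samples_path, vol_path]


def _stage_fitdist(config: RunConfig, out: Path) -> list[Path]:
    (out / "fits").mkdir(exist_ok=True)
    vectors = t2io.load_roi_samples(out / "samples" / "samples.csv")
    families = registry_by_name(config.families)
    by_subject_region: dict = {}
    for v in vectors:
        by_subject_region.setdefault((v.subject_id, v.region), {})[v.hemisphere] = v
    fit_rows, summary_rows = [], []
    for (sid, region), hemis in sorted(by_subject_region.items()):
        summary = summarize_region(
            hemis.get("left"), hemis.get("right"),
            families=families if config.families != "loglogistic" else None,
            combine=config.combine,
        )
        for hemi, fit in summary.hemispheres.items():
            fit_rows.append(
                {
                    "subject_id": sid, "region": region, "hemisphere": hemi,
                    "family": fit.family, "mu": fit.params[0],
                    "sigma": fit.params[1], "loglik": fit.loglik,
                    "aic": fit.aic, "n": fit.n, "converged": fit.converged,
                    "best_family": summary.best_family[hemi],
                }
            )
        summary_rows.append(
            {
                "subject_id": sid, "region": region,
                "t2_mu": summary.t2_mu, "t2_sigma": summary.t2_sigma,
            }
        )
    fits_path = out / "fits" / "fits.csv"
    pd.DataFrame(fit_rows).to_csv(fits_path, index=False)
    summaries_path = out / "fits" / "summaries.csv"
    pd.DataFrame(summary_rows).to_csv(summaries_path, index=False)
    return [fits_path, summaries_path]


def _metric_column(df: pd.DataFrame, metric: str, region: str) -> np.ndarray:
    if metric == "volume":
        return icv_correct(
            df[f"{region}_volume_mm3"].to_numpy(), df["icv_mm3"].to_numpy()
        )
    return df[f"{region}_{metric}"].to_numpy(dtype=float)


def _stage_stats(config: RunConfig, out: Path) -> list[Path]:
    (out / "stats").mkdir(exist_ok=True)
    cohort = pd.read_csv(out / "cohort.csv")
    summaries = pd.read_csv(out / "fits" / "summaries.csv")
    wide = summaries.pivot(index="subject_id", columns="region")
    wide.columns = [f"{region}_{metric}" for metric, region in wide.columns]
    df = cohort.merge(wide, on="subject_id")

    results: dict = {"regions": {}, "followup": {}, "age_regressions": {}}
    hc = (df["group"] == "HC").to_numpy()
    study = df["study"].to_numpy()
    groups_present = [g for g in ("HC", "MCI", "AD") if (df["group"] == g).sum() >= 2]
    for region in config.cohort_spec.regions:
        region_res = {}
        for metric in config.metrics:
            vals = _metric_column(df, metric, region)
            z = zscore_to_reference(vals, hc, study)
            df[f"{region}_{metric}_z"] = z
            anc = ancova_group(
                z, df["group"], covariates=df["age"].to_numpy(),
                groups=groups_present,
            )
            region_res[metric] = {
                "F": anc.F, "df": [anc.df1, anc.df2], "p": anc.p,
                "emmeans": {g: list(v) for g, v in anc.emmeans.items()},
                "pairwise": [
                    {"pair": f"{a}|{b}", "p_raw": pr, "p_sidak": ps}
                    for a, b, pr, ps in anc.pairwise
                ],
                "levene": {"W": anc.levene_w, "p": anc.levene_p},
            }
            if hc.sum() >= 3:
                r2, slope, p = age_regression(vals[hc], df.loc[hc, "age"])
                results["age_regressions"][f"{region}_{metric}"] = {
                    "r2": r2, "slope": slope, "p": p,
                }
        results["regions"][region] = region_res

        mci = df[df["group"] == "MCI"].copy()
        if len(mci) >= 6 and {"cog_baseline", "cog_followup"} <= set(df.columns):
            follow = {}
            for metric in config.metrics:
                vals = _metric_column(mci, metric, region)
                try:
                    mci["_marker"] = zscore_to_reference(
                        vals, np.ones(len(mci), bool), mci["study"].to_numpy()
                    )
                    reg = followup_regression(mci, "_marker")
                except ValueError as exc:
                    follow[metric] = {"error": str(exc)}
                    continue
                follow[metric] = {
                    "r2": reg.r2, "F": reg.F, "df": [reg.df1, reg.df2],
                    "p": reg.p, "beta_marker": reg.beta["_marker"],
                    "p_marker": reg.coef_p["_marker"],
                }
            results["followup"][region] = follow

    path = out / "stats" / "results.json"
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1)
    return [path]


_STAGE_FUNCS: dict[str, Callable[[RunConfig, Path], list[Path]]] = {
    "simulate": _stage_simulate,
    "t2map": _stage_t2map,
    "extract": _stage_extract,
    "fitdist": _stage_fitdist,
    "stats": _stage_stats,
}


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages in order, reusing cached outputs when the
    relevant config sections are unchanged. Returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh).get("stages", {})

    manifest = {"config_hash": _hash_obj(config.raw), "stages": {}}
    upstream_key = ""
    for stage in STAGES:
        key = _hash_obj({"stage": _stage_config(config, stage), "up": upstream_key})
        prev = previous.get(stage)
        cached = (
            prev is not None
            and prev.get("key") == key
            and all(
                Path(p).exists() and _file_sha(Path(p)) == sha
                for p, sha in prev.get("outputs", {}).items()
            )
        )
        if cached:
            log.info("stage %s: cached, skipping", stage)
            manifest["stages"][stage] = {**prev, "cached": True}
        else:
            log.info("stage %s: running", stage)
            t0 = time.time()
            try:
                outputs = _STAGE_FUNCS[stage](config, out)
            except Exception:
                with open(manifest_path, "w") as fh:
                    json.dump(manifest, fh, indent=1)
                log.error("stage %s failed; partial outputs retained", stage)
                raise
            manifest["stages"][stage] = {
                "key": key,
                "outputs": {str(p): _file_sha(Path(p)) for p in outputs},
                "seconds": round(time.time() - t0, 3),
                "cached": False,
            }
        upstream_key = key
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
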