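"""End-to-end orchestration: volumes + config in, CSV results out.

A run processes every sample through the fixed stage order

    read -> standard Gaussian filter -> fixed-threshold segmentation
         -> ROI construction -> morphometry -> erosion scores

then pools all samples into group statistics.  Per-sample failures are
recorded (sample id + stage) and the run continues with the remaining
samples.  A provenance record stores every parameter, the package and
library versions and the SHA-256 of each input volume, and numeric CSV
output uses a fixed 10-significant-digit format so identical runs are
byte-identical.

Configuration (YAML or JSON)::

    samples:
      - {id: s1, group: CTR, volume: vols/s1.mha, landmark_slice: 8}
    rois:
      - {label: tibial_metaphysis_trab, kind: slab, offset_mm: 0.0,
         extent_mm: 0.5, direction: 1, analysis: trabecular}
      - {label: tibial_midshaft_cort, kind: slab, offset_mm: 0.5,
         extent_mm: 0.5, direction: 1, analysis: cortical}
      - {label: ankle_joint, kind: centered, center_slice: 132,
         n_slices: 48, analysis: joint}
    filter: {sigma: 0.8, support: 1}
    strong_filter: {sigma: 2.5, support: 5}
    segment: {threshold: 500}
    output_dir: out

Slab ROIs are anchored at the per-sample ``landmark_slice`` (falling
back to a ``landmark_slice`` given in the ROI block); ``kind: mask``
ROIs read a mask file instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .erosion import smoothness_estimator
from .groupstats import anova_tukey, summarise
from .morphometry import (
    cortical_thickness,
    marrow_and_total_volume,
    total_volume,
    trabecular_thickness,
)
from .preprocess import FilterParams, SegmentationParams, gaussian_filter, segment
from .roi import (
    RoiMask,
    SlabSpec,
    cortical_shell_mask,
    joint_roi,
    slab_mask,
    slab_to_slices,
    trabecular_compartment_mask,
)
from .volio import BinaryVolume, read_mask, read_volume

__all__ = ["RunConfig", "RunResult", "load_config", "run", "validate"]

logger = logging.getLogger("bonemorph")

_ANALYSES = {"trabecular", "cortical", "joint"}
_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """Validated run configuration; paths are resolved against the config dir."""

    samples: list[dict]
    rois: list[dict]
    filter_params: FilterParams = FilterParams(0.8, 1)
    strong_params: FilterParams = FilterParams(2.5, 5)
    seg_params: SegmentationParams = SegmentationParams(500.0)
    output_dir: Path = Path("bonemorph_out")
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class RunResult:
    per_sample: pd.DataFrame
    stats: pd.DataFrame
    errors: list[dict] = field(default_factory=list)
    output_dir: Path | None = None


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    base = path.parent

    def _resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    samples = []
    for s in raw.get("samples", []):
        s = dict(s)
        s["volume"] = _resolve(s["volume"])
        samples.append(s)
    rois = []
    for r in raw.get("rois", []):
        r = dict(r)
        if r.get("kind") == "mask":
            r["path"] = _resolve(r["path"])
        rois.append(r)
    filt = raw.get("filter", {})
    strong = raw.get("strong_filter", {})
    seg = raw.get("segment", {})
    return RunConfig(
        samples=samples,
        rois=rois,
        filter_params=FilterParams(filt.get("sigma", 0.8), filt.get("support", 1)),
        strong_params=FilterParams(strong.get("sigma", 2.5), strong.get("support", 5)),
        seg_params=SegmentationParams(seg.get("threshold", 500.0)),
        output_dir=_resolve(raw.get("output_dir", "bonemorph_out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _build_roi(roi_spec: dict, vol, sample: dict) -> RoiMask:
    kind = roi_spec.get("kind", "slab")
    label = roi_spec.get("label", "custom")
    if kind == "slab":
        landmark = sample.get("landmark_slice", roi_spec.get("landmark_slice"))
        if landmark is None:
            raise ValueError(f"ROI {label!r}: no landmark_slice in sample or ROI block")
        spec = SlabSpec(
            landmark_slice=int(landmark),
            offset_mm=float(roi_spec.get("offset_mm", 0.0)),
            extent_mm=float(roi_spec["extent_mm"]),
            direction=int(roi_spec.get("direction", 1)),
        )
        slices = slab_to_slices(spec, vol.voxel_size_um, n_slices_total=vol.shape[0])
        return slab_mask(vol, slices, label=label)
    if kind == "centered":
        return joint_roi(
            vol,
            center_slice=int(roi_spec["center_slice"]),
            n_slices=int(roi_spec["n_slices"]),
            label=label,
        )
    if kind == "mask":
        m = read_mask(roi_spec["path"], voxel_size_um=vol.voxel_size_um)
        return RoiMask(mask=m, label=label)
    raise ValueError(f"ROI {label!r}: unknown kind {kind!r}")


def _analyse_sample(sample: dict, config: RunConfig) -> list[dict]:
    raw = read_volume(sample["volume"])
    filt = gaussian_filter(raw, config.filter_params)
    bone = segment(filt, config.seg_params)
    vox = raw.voxel_volume_mm3
    rows = []
    for roi_spec in config.rois:
        analysis = roi_spec.get("analysis", "joint")
        if analysis not in _ANALYSES:
            raise ValueError(f"unknown analysis kind {analysis!r}")
        roi = _build_roi(roi_spec, raw, sample)
        row: dict = {
            "sample_id": sample["id"],
            "group": sample.get("group", ""),
            "roi_label": roi.label,
        }
        slab_bone = BinaryVolume(
            mask=bone.mask & roi.mask.mask, voxel_size_um=bone.voxel_size_um
        )
        if analysis == "trabecular":
            slices = _roi_slice_range(roi)
            shell = cortical_shell_mask(slab_bone, slices)
            compartment = trabecular_compartment_mask(shell)
            trab = BinaryVolume(
                mask=slab_bone.mask & compartment.mask.mask,
                voxel_size_um=bone.voxel_size_um,
            )
            row["TV"] = total_volume(compartment)
            row["BV"] = int(trab.mask.sum()) * vox
            row["BVTV"] = row["BV"] / row["TV"]
            row["TbTh"] = trabecular_thickness(trab, compartment)
        elif analysis == "cortical":
            slices = _roi_slice_range(roi)
            shell = cortical_shell_mask(slab_bone, slices)
            row["BV"] = int(shell.mask.sum()) * vox
            row["CtTh"] = cortical_thickness(shell, roi)
            marrow, total = marrow_and_total_volume(shell, roi)
            row["marrow_volume"] = marrow
            row["total_diaphysis_volume"] = total
        else:  # joint
            scores = smoothness_estimator(
                raw,
                roi,
                standard=config.filter_params,
                strong=config.strong_params,
                seg=config.seg_params,
            )
            row["BV"] = scores.BV
            row["TV"] = total_volume(roi)
            row["BS"] = scores.BS
            row["BS_over_BV"] = scores.BS_over_BV
            row["BS_smooth"] = scores.BS_smooth
            row["smoothness"] = scores.smoothness
        rows.append(row)
    return rows


def _roi_slice_range(roi: RoiMask) -> range:
    ks = np.flatnonzero(roi.mask.mask.any(axis=(1, 2)))
    return range(int(ks[0]), int(ks[-1]) + 1)


_MEASUREMENTS = [
    "BV",
    "TV",
    "BVTV",
    "BS",
    "TbTh",
    "CtTh",
    "marrow_volume",
    "total_diaphysis_volume",
    "BS_over_BV",
    "smoothness",
]


def _group_statistics(per_sample: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    if per_sample.empty:
        return pd.DataFrame(rows)
    for roi_label, df in per_sample.groupby("roi_label", sort=False):
        for meas in _MEASUREMENTS:
            if meas not in df.columns:
                continue
            sub = df[["group", meas]].dropna().rename(columns={meas: "value"})
            counts = sub.groupby("group").size()
            if len(counts) < 2 or (counts < 2).any():
                continue
            res = anova_tukey(sub, alpha=alpha)
            for pc in res.pairwise:
                rows.append(
                    {
                        "roi_label": roi_label,
                        "measurement": meas,
                        "F": res.statistic,
                        "p_anova": res.p_value,
                        "group_a": pc.group_a,
                        "group_b": pc.group_b,
                        "difference": pc.difference,
                        "p_tukey": pc.p_adjusted,
                        "significant": pc.significant,
                    }
                )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the result bundle.

    Writes ``per_sample.csv``, ``stats.csv``, ``summary.csv``,
    ``provenance.json`` and ``run.log`` into ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    errors: list[dict] = []
    all_rows: list[dict] = []
    try:
        for sample in config.samples:
            try:
                all_rows.extend(_analyse_sample(sample, config))
                logger.info("sample %s: ok", sample["id"])
            except Exception as exc:  # keep going; report at the end
                errors.append(
                    {"sample_id": sample.get("id", "?"), "stage": "analysis", "error": str(exc)}
                )
                logger.error("sample %s failed: %s", sample.get("id", "?"), exc)

        per_sample = pd.DataFrame(all_rows)
        if not per_sample.empty:
            per_sample = per_sample.sort_values(["sample_id", "roi_label"]).reset_index(drop=True)
        stats = _group_statistics(per_sample)

        per_sample.to_csv(out / "per_sample.csv", index=False, float_format=_CSV_FLOAT)
        stats.to_csv(out / "stats.csv", index=False, float_format=_CSV_FLOAT)
        if not per_sample.empty:
            melted = per_sample.melt(
                id_vars=["sample_id", "group", "roi_label"],
                var_name="measurement",
                value_name="value",
            ).dropna(subset=["value"])
            melted["measurement"] = melted["roi_label"] + ":" + melted["measurement"]
            summarise(melted[["measurement", "group", "value"]]).to_csv(
                out / "summary.csv", index=False, float_format=_CSV_FLOAT
            )

        provenance = {
            "bonemorph_version": __version__,
            "numpy_version": np.__version__,
            "parameters": {
                "filter": {"sigma": config.filter_params.sigma, "support": config.filter_params.support},
                "strong_filter": {
                    "sigma": config.strong_params.sigma,
                    "support": config.strong_params.support,
                },
                "threshold": config.seg_params.threshold,
                "seed": config.seed,
            },
            "rois": config.rois,
            "inputs": {
                s["id"]: {"path": str(s["volume"]), "sha256": _sha256(Path(s["volume"]))}
                for s in config.samples
                if Path(s["volume"]).exists()
            },
            "errors": errors,
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, default=str)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return RunResult(per_sample=per_sample, stats=stats, errors=errors, output_dir=out)


def validate(config_path: str | Path) -> list[str]:
    """Check a configuration without running anything; returns problems."""
    problems: list[str] = []
    try:
        config = load_config(config_path)
    except Exception as exc:
        return [f"config does not parse: {exc}"]
    if not config.samples:
        problems.append("no samples defined")
    seen = set()
    for s in config.samples:
        sid = s.get("id")
        if sid is None:
            problems.append("sample without id")
        elif sid in seen:
            problems.append(f"duplicate sample id {sid!r}")
        seen.add(sid)
        if not Path(s["volume"]).exists():
            problems.append(f"sample {sid!r}: missing volume file {s['volume']}")
    if not config.rois:
        problems.append("no ROIs defined")
    for r in config.rois:
        label = r.get("label", "custom")
        kind = r.get("kind", "slab")
        if r.get("analysis", "joint") not in _ANALYSES:
            problems.append(f"ROI {label!r}: unknown analysis {r.get('analysis')!r}")
        if kind == "slab":
            if "extent_mm" not in r:
                problems.append(f"ROI {label!r}: slab needs extent_mm")
            elif float(r["extent_mm"]) <= 0:
                problems.append(f"ROI {label!r}: extent_mm must be > 0")
        elif kind == "centered":
            if "center_slice" not in r or "n_slices" not in r:
                problems.append(f"ROI {label!r}: centered needs center_slice and n_slices")
            elif int(r["n_slices"]) < 1:
                problems.append(f"ROI {label!r}: n_slices must be >= 1")
        elif kind == "mask":
            if not Path(r["path"]).exists():
                problems.append(f"ROI {label!r}: missing mask file {r['path']}")
        else:
            problems.append(f"ROI {label!r}: unknown kind {kind!r}")
    try:
        FilterParams(config.filter_params.sigma, config.filter_params.support)
        FilterParams(config.strong_params.sigma, config.strong_params.support)
    except ValueError as exc:
        problems.append(str(exc))
    # lazy geometry probe: check slab ROIs against the first readable volume
    for s in config.samples[:1]:
        if Path(s["volume"]).exists():
            try:
                vol = read_volume(s["volume"])
                for r in config.rois:
                    if r.get("kind", "slab") == "slab" and "extent_mm" in r:
                        try:
                            _build_roi(r, vol, s)
                        except Exception as exc:
                            problems.append(
                                f"ROI {r.get('label')!r} on sample {s.get('id')!r}: {exc}"
                            )
            except Exception as exc:
                problems.append(f"cannot read volume for geometry probe: {exc}")
    return problems
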