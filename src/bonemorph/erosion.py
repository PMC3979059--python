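"""Focal-erosion statistics for periarticular bone.

Two complementary scores quantify surface erosion in a joint ROI:

* **surface density BS/BV** (1/mm): the ratio of bone surface to bone
  volume.  Superficial pitting raises BS while lowering BV, so BS/BV
  rises with erosion — but it also falls when bone is added anywhere
  (e.g. endosteal apposition), so it confounds erosion with bone mass.
* **smoothness BSsmooth/BS** (dimensionless): BS is recomputed after a
  strong Gaussian smoothing (sigma = 2.5, support = 5) of the grayscale
  volume, giving BSsmooth, and the ratio BSsmooth/BS is reported.  A
  perfectly smooth surface is unchanged by extra smoothing (ratio near
  one); a heavily pitted or rough surface loses most of its area (ratio
  toward zero).  Because it is a ratio of areas of the same structure it
  is insensitive to bone-volume changes, which lets it dissociate
  persistent surface pitting from bone accrual.

The strong filter is applied to the raw grayscale volume and the field is
re-segmented at the same fixed threshold before re-meshing, so the ratio
isolates the effect of the filter on surface geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .morphometry import bone_surface, bone_volume
from .preprocess import (
    DEFAULT_SEGMENTATION,
    STANDARD_FILTER,
    STRONG_FILTER,
    FilterParams,
    SegmentationParams,
    gaussian_filter,
    segment,
)
from .roi import RoiMask
from .volio import DensityVolume

__all__ = ["ErosionScores", "surface_density", "smoothness_estimator"]


@dataclass
class ErosionScores:
    """BS/BV and BSsmooth/BS for one joint ROI, with the parameters used."""

    label: str
    BS: float  # mm^2, from the standard-filtered field
    BV: float  # mm^3, standard segmentation
    BS_over_BV: float  # 1/mm
    BS_smooth: float  # mm^2, from the strongly-filtered field
    smoothness: float  # BSsmooth / BS, dimensionless
    params: dict = field(default_factory=dict)


def surface_density(BS: float, BV: float) -> float:
    """Surface density BS/BV in 1/mm; requires BV > 0."""
    if BV <= 0:
        raise ValueError(f"BV must be > 0 to form BS/BV, got {BV}")
    return BS / BV


def smoothness_estimator(
    raw: DensityVolume,
    roi: RoiMask,
    standard: FilterParams = STANDARD_FILTER,
    strong: FilterParams = STRONG_FILTER,
    seg: SegmentationParams = DEFAULT_SEGMENTATION,
) -> ErosionScores:
    """Compute BS, BV, BS/BV, BSsmooth and the smoothness ratio for a ROI.

    ``raw`` is the unsmoothed calibrated volume.  BS and BV come from the
    standard denoising filter; BSsmooth repeats the identical iso-surface
    computation after the strong filter.  If the strong filter erases all
    structure, BSsmooth = 0 and smoothness = 0 (the rough-surface limit).
    """
    filt = gaussian_filter(raw, standard)
    mask = segment(filt, seg)
    BV = bone_volume(mask, roi)
    BS = bone_surface(filt, seg.threshold, roi)
    if BS <= 0:
        raise ValueError("no bone surface in the ROI under standard filtering")
    strong_filt = gaussian_filter(raw, strong)
    BS_smooth = bone_surface(strong_filt, seg.threshold, roi)
    return ErosionScores(
        label=roi.label,
        BS=BS,
        BV=BV,
        BS_over_BV=surface_density(BS, BV) if BV > 0 else float("nan"),
        BS_smooth=BS_smooth,
        smoothness=BS_smooth / BS,
        params={
            "standard_sigma": standard.sigma,
            "standard_support": standard.support,
            "strong_sigma": strong.sigma,
            "strong_support": strong.support,
            "threshold": seg.threshold,
        },
    )
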