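"""Noise filtering and fixed-threshold segmentation.

The denoising step is a separable discrete Gaussian whose kernel is
sampled at integer offsets, truncated at +/- ``support`` voxels per axis
and renormalised to unit sum — the (sigma, support) parameterisation used
by SCANCO's IPL software.  The standard denoising setting is
sigma = 0.8, support = 1 (a 3-tap kernel per axis); the strong smoothing
used by the surface-smoothness estimator is sigma = 2.5, support = 5.
Boundaries are handled by mirror reflection so that structures near the
volume edge are not darkened.

Segmentation is a global fixed threshold on the calibrated density,
default 500 mg HA/cm^3, with the inclusive convention bone := density >=
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import BinaryVolume, DensityVolume

__all__ = [
    "FilterParams",
    "SegmentationParams",
    "STANDARD_FILTER",
    "STRONG_FILTER",
    "DEFAULT_SEGMENTATION",
    "gaussian_kernel",
    "gaussian_filter",
    "segment",
]


@dataclass(frozen=True)
class FilterParams:
    """Gaussian kernel standard deviation and truncation half-width, voxels."""

    sigma: float = 0.8
    support: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.support < 0 or int(self.support) != self.support:
            raise ValueError(f"support must be a non-negative integer, got {self.support}")


@dataclass(frozen=True)
class SegmentationParams:
    """Fixed density threshold, mg HA/cm^3."""

    threshold: float = 500.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


STANDARD_FILTER = FilterParams(sigma=0.8, support=1)
STRONG_FILTER = FilterParams(sigma=2.5, support=5)
DEFAULT_SEGMENTATION = SegmentationParams(threshold=500.0)


def gaussian_kernel(sigma: float, support: int) -> np.ndarray:
    """1-D discrete Gaussian sampled at integer taps in [-support, support].

    The taps are ``exp(-i^2 / (2 sigma^2))`` renormalised to sum to one, so
    constants are preserved exactly.  ``sigma == 0`` or ``support == 0``
    gives the identity kernel ``[1.0]``.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if support < 0:
        raise ValueError(f"support must be >= 0, got {support}")
    if sigma == 0 or support == 0:
        return np.ones(1)
    taps = np.arange(-support, support + 1, dtype=np.float64)
    w = np.exp(-(taps**2) / (2.0 * sigma**2))
    return w / w.sum()


def gaussian_filter(vol: DensityVolume, params: FilterParams) -> DensityVolume:
    """Separable truncated-Gaussian smoothing with mirror boundaries."""
    kernel = gaussian_kernel(params.sigma, params.support)
    out = np.asarray(vol.data, dtype=np.float64)
    if kernel.size > 1:
        for axis in range(3):
            out = ndimage.correlate1d(out, kernel, axis=axis, mode="mirror")
    else:
        out = out.copy()
    return DensityVolume(
        data=out, voxel_size_um=vol.voxel_size_um, slice_axis=vol.slice_axis, name=vol.name
    )


def segment(vol: DensityVolume, params: SegmentationParams = DEFAULT_SEGMENTATION) -> BinaryVolume:
    """Fixed-threshold segmentation: bone where density >= threshold."""
    return BinaryVolume(
        mask=vol.data >= params.threshold,
        voxel_size_um=vol.voxel_size_um,
        slice_axis=vol.slice_axis,
        name=vol.name,
    )
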