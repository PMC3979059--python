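"""Regions of interest: landmark-anchored slabs and compartment masks.

ROIs follow the conventions of standard rodent microCT protocols, where
regions are specified as counts of tomograms (slices along axis 0):

* mid-diaphysis cortical bone: a 0.6 mm slab (100 tomograms at 6 um);
* proximal metaphysis trabecular bone: a slab starting 0.30 mm distal to
  a growth-plate landmark and extending 1.2 mm (200 tomograms);
* knee / ankle joints: 640 / 700 tomograms centred on the joint space.

The anatomic landmark is supplied as an explicit slice index (by the
phantom generator, or by the user for real scans); automatic landmark
detection is out of scope.  Millimetre extents are converted to slice
counts with round-half-away-from-zero so that 0.6 mm -> 100 and
1.2 mm -> 200 slices at 6 um exactly.

The trabecular compartment (the marrow space enclosed by the cortical
shell) is obtained by per-slice morphological filling of the shell; this
replaces the manual contouring a human operator would perform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import BinaryVolume, DensityVolume

__all__ = [
    "SlabSpec",
    "RoiMask",
    "slab_to_slices",
    "slab_mask",
    "joint_roi",
    "cortical_shell_mask",
    "trabecular_compartment_mask",
    "OpenShellError",
]

ROI_LABELS = {
    "vertebral_body",
    "tibial_metaphysis_trab",
    "tibial_midshaft_cort",
    "knee_joint",
    "ankle_joint",
    "custom",
}


class OpenShellError(ValueError):
    """Raised when a cortical shell is not closed on some slice."""

    def __init__(self, slice_index: int):
        self.slice_index = slice_index
        super().__init__(
            f"cortical shell is not closed on slice {slice_index}: "
            "no enclosed interior found where neighbouring slices have one"
        )


@dataclass(frozen=True)
class SlabSpec:
    """A slab anchored to an anatomic landmark slice.

    ``offset_mm`` is the (signed) distance from the landmark to the slab
    start and ``extent_mm`` the slab length; ``direction`` is +1 or -1
    along the slice axis.
    """

    landmark_slice: int
    offset_mm: float = 0.0
    extent_mm: float = 0.6
    direction: int = 1

    def __post_init__(self) -> None:
        if self.extent_mm <= 0:
            raise ValueError(f"extent_mm must be > 0, got {self.extent_mm}")
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")


@dataclass
class RoiMask:
    """A labelled analysis region sharing the geometry of its source volume."""

    mask: BinaryVolume
    label: str = "custom"
    allow_empty: bool = False

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}; use one of {sorted(ROI_LABELS)}")
        if not self.allow_empty and not self.mask.mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.mask.sum())


def _round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def slab_to_slices(
    spec: SlabSpec, voxel_size_um: float, n_slices_total: int | None = None
) -> range:
    """Convert a landmark-anchored slab to a half-open slice range.

    The slab holds ``n = round(extent_mm * 1000 / voxel_size_um)`` slices
    starting at ``landmark + direction * round(offset_mm * 1000 /
    voxel_size_um)``; for ``direction == -1`` the slab extends toward
    lower indices.  If ``n_slices_total`` is given the range is checked
    against the volume bounds.
    """
    if voxel_size_um <= 0:
        raise ValueError(f"voxel_size_um must be > 0, got {voxel_size_um}")
    n = _round_half_away(spec.extent_mm * 1000.0 / voxel_size_um)
    if n == 0:
        raise ValueError(
            f"slab extent {spec.extent_mm} mm is below one slice at {voxel_size_um} um"
        )
    anchor = spec.landmark_slice + spec.direction * _round_half_away(
        spec.offset_mm * 1000.0 / voxel_size_um
    )
    start = anchor if spec.direction == 1 else anchor - n + 1
    stop = start + n
    if start < 0 or (n_slices_total is not None and stop > n_slices_total):
        raise ValueError(
            f"slab [{start}, {stop}) exits the volume"
            + (f" of {n_slices_total} slices" if n_slices_total is not None else "")
        )
    return range(start, stop)


def slab_mask(vol: DensityVolume | BinaryVolume, slices: range, label: str = "custom") -> RoiMask:
    """Full-lateral ROI covering the given slice range."""
    shape = vol.shape if isinstance(vol, DensityVolume) else vol.mask.shape
    if slices.start < 0 or slices.stop > shape[0]:
        raise ValueError(f"slab [{slices.start}, {slices.stop}) exits the volume")
    mask = np.zeros(shape, dtype=bool)
    mask[slices.start : slices.stop] = True
    return RoiMask(
        mask=BinaryVolume(mask=mask, voxel_size_um=vol.voxel_size_um),
        label=label,
    )


def joint_roi(
    vol: DensityVolume,
    center_slice: int,
    n_slices: int,
    lateral_mask: np.ndarray | None = None,
    label: str = "custom",
) -> RoiMask:
    """Slab of ``n_slices`` centred on ``center_slice`` (ties toward lower index),
    optionally intersected with a lateral (2-D per-slice or full 3-D) mask."""
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    start = center_slice - n_slices // 2
    stop = start + n_slices
    if start < 0 or stop > vol.shape[0]:
        raise ValueError(
            f"joint slab [{start}, {stop}) exceeds volume bounds (0, {vol.shape[0]})"
        )
    mask = np.zeros(vol.shape, dtype=bool)
    mask[start:stop] = True
    if lateral_mask is not None:
        lateral_mask = np.asarray(lateral_mask, dtype=bool)
        if lateral_mask.ndim == 2:
            mask &= lateral_mask[None, :, :]
        elif lateral_mask.ndim == 3:
            mask &= lateral_mask
        else:
            raise ValueError("lateral_mask must be 2-D or 3-D")
    return RoiMask(mask=BinaryVolume(mask=mask, voxel_size_um=vol.voxel_size_um), label=label)


def cortical_shell_mask(bone: BinaryVolume, slices: range | None = None) -> BinaryVolume:
    """Identify the cortical shell per slice as the connected component that
    encloses the largest area (shell plus its interior).

    Trabecular structures lying free inside the shell are excluded;
    structures fused to the shell remain part of it.
    """
    mask = bone.mask
    sl = slices if slices is not None else range(0, mask.shape[0])
    shell = np.zeros_like(mask)
    for k in sl:
        plane = mask[k]
        if not plane.any():
            continue
        labels, n = ndimage.label(plane)
        best, best_area = 0, -1
        for lab in range(1, n + 1):
            filled = ndimage.binary_fill_holes(labels == lab)
            area = int(filled.sum())
            if area > best_area:
                best, best_area = lab, area
        shell[k] = labels == best
    return BinaryVolume(mask=shell, voxel_size_um=bone.voxel_size_um)


def trabecular_compartment_mask(
    cortex_mask: BinaryVolume, label: str = "tibial_metaphysis_trab"
) -> RoiMask:
    """Endosteal compartment: per-slice fill of the cortical shell minus the shell.

    A slice whose shell encloses no interior while other slices do is
    reported as an open (broken) shell; a shell with no interior anywhere
    (a solid rod) yields an empty compartment.
    """
    shell = cortex_mask.mask
    interior = np.zeros_like(shell)
    empty_slices: list[int] = []
    for k in range(shell.shape[0]):
        plane = shell[k]
        if not plane.any():
            continue
        filled = ndimage.binary_fill_holes(plane)
        inner = filled & ~plane
        interior[k] = inner
        if not inner.any():
            empty_slices.append(k)
    if interior.any() and empty_slices:
        raise OpenShellError(empty_slices[0])
    return RoiMask(
        mask=BinaryVolume(mask=interior, voxel_size_um=cortex_mask.voxel_size_um),
        label=label,
        allow_empty=True,
    )
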