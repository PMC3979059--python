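"""Calibrated 3-D volume containers and file I/O.

All volumes in this package are dense 3-D grids with a single isotropic
voxel size.  Density values are calibrated mineral density in
mg hydroxyapatite / cm**3; the producer is assumed to have applied the
scanner calibration already.  The tomogram stack runs along axis 0
(``slice_axis``), so a "slab of N tomograms" is a contiguous run of N
indices on axis 0.  Slices are 0-indexed and slab ranges are half-open.

Supported on-disk formats:

* multipage TIFF (any integer or float dtype) with a JSON sidecar
  (``<stem>.json``) carrying ``voxel_size_um`` and, for integer data, an
  optional ``density_scale`` factor mapping stored counts to mg HA/cm^3;
* MetaImage (``.mha``/``.mhd``) and NRRD (``.nrrd``), whose headers carry
  the spacing in millimetres.

Binary masks are stored as 8-bit {0, 1}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "DensityVolume",
    "BinaryVolume",
    "read_volume",
    "read_mask",
    "write_volume",
]

_SITK_SUFFIXES = {".mha", ".mhd", ".nrrd"}
_TIFF_SUFFIXES = {".tif", ".tiff"}

#: relative tolerance on spacing isotropy when reading header-bearing formats
_ISO_RTOL = 1e-6


@dataclass
class DensityVolume:
    """A calibrated 3-D mineral-density grid (mg HA/cm^3) with voxel geometry."""

    data: np.ndarray
    voxel_size_um: float
    slice_axis: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        self.voxel_size_um = float(self.voxel_size_um)
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if self.slice_axis != 0:
            raise ValueError("the tomogram stack must run along axis 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3


@dataclass
class BinaryVolume:
    """A boolean segmentation mask sharing the geometry of its source volume."""

    mask: np.ndarray
    voxel_size_um: float
    slice_axis: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got ndim={mask.ndim}")
        if mask.dtype != bool:
            vals = np.unique(mask)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError("mask values must be strictly binary")
            mask = mask.astype(bool)
        self.mask = mask
        self.voxel_size_um = float(self.voxel_size_um)
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if self.slice_axis != 0:
            raise ValueError("the tomogram stack must run along axis 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            return json.load(fh)
    return {}


def _read_sitk(path: Path) -> tuple[np.ndarray, float]:
    img = sitk.ReadImage(str(path))
    spacing = np.asarray(img.GetSpacing(), dtype=float)  # (x, y, z), mm
    if not np.allclose(spacing, spacing[0], rtol=_ISO_RTOL, atol=0):
        raise ValueError(
            f"{path}: anisotropic spacing {tuple(spacing)} mm is not supported; "
            "resample to isotropic voxels first"
        )
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    return data, float(spacing[0]) * 1000.0


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> DensityVolume:
    """Read a calibrated density volume from TIFF / MetaImage / NRRD.

    Parameters
    ----------
    path
        File to read.  TIFF stacks need either ``voxel_size_um`` here or a
        JSON sidecar; MetaImage and NRRD carry spacing in their header
        (header spacing is in mm and is converted to microns).
    voxel_size_um
        Isotropic voxel size override.  Required for TIFF without sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    suffix = path.suffix.lower()

    if suffix in _SITK_SUFFIXES:
        data, vs_header = _read_sitk(path)
        vs = voxel_size_um if voxel_size_um is not None else vs_header
        meta = _read_sidecar(path)
    elif suffix in _TIFF_SUFFIXES:
        data = tifffile.imread(str(path))
        if data.ndim == 2:  # single-page stack
            data = data[None]
        meta = _read_sidecar(path)
        vs = voxel_size_um if voxel_size_um is not None else meta.get("voxel_size_um")
        if vs is None:
            raise ValueError(
                f"{path}: TIFF carries no voxel size; pass voxel_size_um or "
                "provide a JSON sidecar"
            )
        if np.issubdtype(data.dtype, np.integer) and "density_scale" in meta:
            data = data.astype(np.float64) * float(meta["density_scale"])
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")

    name = meta.get("name", path.stem)
    return DensityVolume(data=np.asarray(data, dtype=np.float64), voxel_size_um=vs, name=name)


def read_mask(path: str | Path, voxel_size_um: float | None = None) -> BinaryVolume:
    """Read a binary mask (stored as 8-bit {0,1}) from any supported format."""
    vol = read_volume(path, voxel_size_um=voxel_size_um)
    return BinaryVolume(mask=vol.data > 0.5, voxel_size_um=vol.voxel_size_um, name=vol.name)


def write_volume(vol: DensityVolume | BinaryVolume, path: str | Path) -> None:
    """Write a volume or mask; read_volume/read_mask round-trips losslessly."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    suffix = path.suffix.lower()

    is_mask = isinstance(vol, BinaryVolume)
    data = vol.mask.astype(np.uint8) if is_mask else np.asarray(vol.data)

    if suffix in _SITK_SUFFIXES:
        img = sitk.GetImageFromArray(data)
        img.SetSpacing((vol.voxel_size_mm,) * 3)
        sitk.WriteImage(img, str(path))
    elif suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(str(path), data, photometric="minisblack")
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")

    sidecar = {
        "name": vol.name,
        "voxel_size_um": vol.voxel_size_um,
        "units": "binary" if is_mask else "mg HA/cm^3",
        "kind": "mask" if is_mask else "density",
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)
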