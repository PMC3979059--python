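"""Synthetic bone phantoms with analytic ground truth.

Every phantom is an analytic solid voxelised at voxel centres on an
isotropic grid, mapped to calibrated density (bone 900, background
100 mg HA/cm^3 by default) with i.i.d. Gaussian scanner noise (sd
60 mg HA/cm^3 by default) added everywhere.  Those defaults bracket the
500 mg HA/cm^3 segmentation threshold symmetrically with a ~6.7-sigma
separation, so thresholding recovers the analytic solid up to boundary
voxels.  Generation is fully deterministic given (spec, seed); changing
only the seed changes only the noise and the pit placement, never the
analytic geometry.

Families
--------
sphere, plate, rod_lattice, cortical_tube, pitted_sphere, pitted_tube,
speckle, and the composite ``tibia`` used by :func:`make_study`.

Focal erosion is modelled as hemispherical pits: pit centres are drawn
from a Poisson process on the analytic outer surface with intensity
``pit_density`` (pits per mm^2) and bone within ``pit_radius_mm`` of each
centre is removed.

The composite tibia phantom is a cortical tube along the slice axis with
three analysis zones: a "metaphysis" containing a trabecular rod lattice
inside the shell, a plain "midshaft", and a "joint" zone whose outer
(periosteal) surface may carry pits.  :func:`make_study` builds a
three-group study on this phantom:

* ``CTR`` — healthy: baseline rods, no pits, baseline marrow;
* ``CIA_PBS`` — arthritic, vehicle-treated: trabecular thinning (rod
  diameter scaled by a thinning factor) and periosteal pitting;
* ``CIA_SclAbI`` — arthritic, anabolic-antibody-treated: the same
  pitting, no trabecular thinning, and endosteal apposition (the inner
  radius is reduced so the marrow volume shrinks by a configured
  fold-change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volio import DensityVolume

__all__ = [
    "PhantomSpec",
    "TibiaParams",
    "make_phantom",
    "make_tibia",
    "make_study",
    "STUDY_GROUPS",
]

FAMILIES = {
    "sphere",
    "plate",
    "rod_lattice",
    "cortical_tube",
    "pitted_sphere",
    "pitted_tube",
    "speckle",
}

STUDY_GROUPS = ("CTR", "CIA_PBS", "CIA_SclAbI")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic volume; geometry keys are family-specific."""

    family: str
    geometry: dict = field(default_factory=dict)
    bone_density: float = 900.0
    background_density: float = 100.0
    noise_sd: float = 60.0
    pit_density: float = 0.0  # pits per mm^2 of analytic surface
    pit_radius_mm: float = 0.05
    voxel_size_um: float = 6.0
    seed: int = 0
    shape: tuple[int, int, int] | None = None
    margin_voxels: int = 6

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown phantom family {self.family!r}")
        if self.pit_density < 0 or self.pit_radius_mm < 0:
            raise ValueError("pit parameters must be >= 0")
        if any(v <= 0 for k, v in self.geometry.items() if k.endswith("_mm")):
            raise ValueError("all geometric lengths must be > 0")
        if not self.bone_density > self.background_density:
            raise ValueError("bone density must exceed background density")


def _axis_coords(n: int, vs_mm: float) -> np.ndarray:
    """Voxel-centre coordinates (mm) with the origin at the grid centre."""
    return (np.arange(n) - (n - 1) / 2.0) * vs_mm


def _grids(shape: tuple[int, int, int], vs_mm: float):
    z = _axis_coords(shape[0], vs_mm)[:, None, None]
    y = _axis_coords(shape[1], vs_mm)[None, :, None]
    x = _axis_coords(shape[2], vs_mm)[None, None, :]
    return z, y, x


def _carve_pits(
    bone: np.ndarray,
    centers_mm: np.ndarray,
    pit_radius_mm: float,
    shape: tuple[int, int, int],
    vs_mm: float,
) -> None:
    """Remove bone within pit_radius of each centre (in-place)."""
    if len(centers_mm) == 0 or pit_radius_mm <= 0:
        return
    offsets = np.array([(n - 1) / 2.0 for n in shape])
    r_vox = pit_radius_mm / vs_mm
    for c in centers_mm:
        ci = c / vs_mm + offsets  # fractional voxel index
        lo = np.maximum(np.floor(ci - r_vox - 1).astype(int), 0)
        hi = np.minimum(np.ceil(ci + r_vox + 2).astype(int), shape)
        if np.any(lo >= hi):
            continue
        zz = (np.arange(lo[0], hi[0]) - ci[0])[:, None, None]
        yy = (np.arange(lo[1], hi[1]) - ci[1])[None, :, None]
        xx = (np.arange(lo[2], hi[2]) - ci[2])[None, None, :]
        ball = zz**2 + yy**2 + xx**2 <= r_vox**2
        bone[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] &= ~ball


def _sphere_points(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius


def make_phantom(spec: PhantomSpec) -> tuple[DensityVolume, dict]:
    """Generate one phantom volume plus its ground-truth record.

    The truth record carries the analytic bone volume / surface /
    thickness where closed forms exist, the realised pit count, and every
    parameter used.
    """
    vs = spec.voxel_size_um / 1000.0
    m = spec.margin_voxels
    g = spec.geometry
    rng_noise = np.random.default_rng([spec.seed, 0])
    rng_pits = np.random.default_rng([spec.seed, 1])
    truth: dict = {"family": spec.family, "seed": spec.seed, "voxel_size_um": spec.voxel_size_um}

    if spec.family in ("sphere", "pitted_sphere"):
        R = g["radius_mm"]
        n = spec.shape[0] if spec.shape else 2 * (math.ceil(R / vs) + m)
        shape = spec.shape or (n, n, n)
        z, y, x = _grids(shape, vs)
        bone = z**2 + y**2 + x**2 <= R**2
        area = 4.0 * math.pi * R**2
        truth.update(
            radius_mm=R,
            BV_mm3=4.0 / 3.0 * math.pi * R**3,
            BS_mm2=area,
            thickness_mm=2 * R,
        )
        if spec.family == "pitted_sphere":
            n_pits = int(rng_pits.poisson(spec.pit_density * area))
            centers = _sphere_points(rng_pits, n_pits, R)
            _carve_pits(bone, centers, spec.pit_radius_mm, shape, vs)
            truth.update(pit_count=n_pits, pit_density=spec.pit_density,
                         pit_radius_mm=spec.pit_radius_mm)

    elif spec.family == "plate":
        t = g["thickness_mm"]
        lat = int(g.get("lateral_voxels", 64))
        nz = spec.shape[0] if spec.shape else math.ceil(t / vs) + 2 * m
        nz += nz % 2
        shape = spec.shape or (nz, lat, lat)
        z, _, _ = _grids(shape, vs)
        bone = np.broadcast_to(np.abs(z) <= t / 2.0, shape).copy()
        truth.update(thickness_mm=t)

    elif spec.family == "rod_lattice":
        d = g["rod_diameter_mm"]
        s = g["spacing_mm"]
        k = int(g.get("n_rods", 4))
        nz = int(g.get("length_voxels", 64))
        if d >= s:
            raise ValueError("rod diameter must be smaller than the lattice spacing")
        lat = int(round(k * s / vs))
        shape = spec.shape or (nz, lat, lat)
        _, y, x = _grids(shape, vs)
        centers = (np.arange(k) - (k - 1) / 2.0) * s
        bone = np.zeros(shape, dtype=bool)
        lateral = np.zeros(shape[1:], dtype=bool)
        for cy in centers:
            for cx in centers:
                lateral |= ((y[0] - cy) ** 2 + (x[0] - cx) ** 2 <= (d / 2.0) ** 2)
        bone |= lateral[None, :, :]
        truth.update(
            rod_diameter_mm=d,
            spacing_mm=s,
            thickness_mm=d,
            fill_fraction=math.pi * (d / 2.0) ** 2 / s**2,
        )

    elif spec.family in ("cortical_tube", "pitted_tube"):
        R = g["outer_radius_mm"]
        r_in = g["inner_radius_mm"]
        if r_in >= R:
            raise ValueError("inner radius must be smaller than outer radius")
        nz = int(g.get("length_voxels", 64))
        lat = spec.shape[1] if spec.shape else 2 * (math.ceil(R / vs) + m)
        shape = spec.shape or (nz, lat, lat)
        _, y, x = _grids(shape, vs)
        rho2 = (y**2 + x**2)[0]
        ring = (rho2 > r_in**2) & (rho2 <= R**2)
        bone = np.broadcast_to(ring[None, :, :], shape).copy()
        L = shape[0] * vs
        truth.update(
            outer_radius_mm=R,
            inner_radius_mm=r_in,
            length_mm=L,
            thickness_mm=R - r_in,
            BV_mm3=math.pi * (R**2 - r_in**2) * L,
            marrow_volume_mm3=math.pi * r_in**2 * L,
            BS_mm2=2.0 * math.pi * (R + r_in) * L,
        )
        if spec.family == "pitted_tube":
            area = 2.0 * math.pi * R * L
            n_pits = int(rng_pits.poisson(spec.pit_density * area))
            theta = rng_pits.uniform(0, 2 * math.pi, n_pits)
            zc = rng_pits.uniform(-L / 2.0, L / 2.0, n_pits)
            centers = np.column_stack(
                [zc, R * np.sin(theta), R * np.cos(theta)]
            )
            _carve_pits(bone, centers, spec.pit_radius_mm, shape, vs)
            truth.update(pit_count=n_pits, pit_density=spec.pit_density,
                         pit_radius_mm=spec.pit_radius_mm)

    elif spec.family == "speckle":
        shape = spec.shape or (128, 128, 128)
        p = float(g.get("fill_fraction", 0.5))
        bone = rng_pits.random(shape) < p
        truth.update(fill_fraction=p)

    else:  # pragma: no cover - guarded by PhantomSpec
        raise ValueError(f"unknown phantom family {spec.family!r}")

    data = np.where(bone, spec.bone_density, spec.background_density).astype(np.float64)
    truth["bone_voxel_count"] = int(bone.sum())
    if spec.noise_sd > 0:
        data += rng_noise.normal(0.0, spec.noise_sd, size=data.shape)
    vol = DensityVolume(
        data=data,
        voxel_size_um=spec.voxel_size_um,
        name=f"{spec.family}_seed{spec.seed}",
    )
    truth.update(
        bone_density=spec.bone_density,
        background_density=spec.background_density,
        noise_sd=spec.noise_sd,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# Composite tibia phantom and study generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TibiaParams:
    """Geometry of the composite tibia-like phantom.

    The defaults give, at a 10 um voxel, a 40-voxel outer radius cortical
    shell with 10-voxel trabecular rods — feature sizes comfortably above
    the ~5-voxel limit at which discrete morphometry becomes unreliable,
    in a grid small enough for routine simulation studies.
    """

    voxel_size_um: float = 10.0
    outer_radius_mm: float = 0.40
    inner_radius_mm: float = 0.30
    rod_diameter_mm: float = 0.10
    rod_spacing_mm: float = 0.15
    lateral_voxels: int = 96
    margin_slices: int = 8
    metaphysis_slices: int = 50
    midshaft_slices: int = 50
    joint_slices: int = 48
    pit_radius_mm: float = 0.05
    bone_density: float = 900.0
    background_density: float = 100.0
    noise_sd: float = 60.0

    @property
    def n_slices(self) -> int:
        return (
            2 * self.margin_slices
            + self.metaphysis_slices
            + self.midshaft_slices
            + self.joint_slices
        )

    @property
    def zones(self) -> dict[str, range]:
        """Half-open slice ranges of the three analysis zones."""
        a = self.margin_slices
        b = a + self.metaphysis_slices
        c = b + self.midshaft_slices
        d = c + self.joint_slices
        return {
            "tibial_metaphysis_trab": range(a, b),
            "tibial_midshaft_cort": range(b, c),
            "ankle_joint": range(c, d),
        }

    @property
    def landmark_slice(self) -> int:
        """Growth-plate stand-in: the first metaphysis slice."""
        return self.margin_slices


def make_tibia(
    params: TibiaParams,
    thinning_factor: float = 1.0,
    inner_radius_mm: float | None = None,
    pit_density: float = 0.0,
    seed: int = 0,
) -> tuple[DensityVolume, dict]:
    """Build one composite tibia phantom.

    ``thinning_factor`` scales the trabecular rod diameter (arthritic
    thinning); ``inner_radius_mm`` overrides the endosteal radius
    (apposition reduces it); ``pit_density`` (pits/mm^2) applies
    hemispherical pits to the periosteal surface of the joint zone only.
    """
    vs = params.voxel_size_um / 1000.0
    r_in = params.inner_radius_mm if inner_radius_mm is None else inner_radius_mm
    if not 0 < r_in < params.outer_radius_mm:
        raise ValueError(
            f"inner radius {r_in} mm must lie in (0, {params.outer_radius_mm})"
        )
    d_rod = params.rod_diameter_mm * thinning_factor
    if d_rod <= 0:
        raise ValueError("thinning factor produced a non-physical rod diameter")
    shape = (params.n_slices, params.lateral_voxels, params.lateral_voxels)
    _, y, x = _grids(shape, vs)
    rho2 = (y**2 + x**2)[0]
    rng_noise = np.random.default_rng([seed, 0])
    rng_pits = np.random.default_rng([seed, 1])

    bone = np.zeros(shape, dtype=bool)
    ring = (rho2 > r_in**2) & (rho2 <= params.outer_radius_mm**2)
    bone |= ring[None, :, :]

    # trabecular rod lattice in the metaphysis, kept clear of the shell
    zones = params.zones
    met = zones["tibial_metaphysis_trab"]
    rod_zone_max = params.inner_radius_mm - params.rod_diameter_mm / 2.0 - 3 * vs
    k = int(math.floor(rod_zone_max / params.rod_spacing_mm)) * 2 + 1
    centers = (np.arange(k) - (k - 1) / 2.0) * params.rod_spacing_mm
    lateral = np.zeros(shape[1:], dtype=bool)
    n_rods = 0
    for cy in centers:
        for cx in centers:
            if math.hypot(cy, cx) <= rod_zone_max:
                lateral |= ((y[0] - cy) ** 2 + (x[0] - cx) ** 2 <= (d_rod / 2.0) ** 2)
                n_rods += 1
    bone[met.start : met.stop] |= lateral[None, :, :]

    # periosteal pits in the joint zone
    joint = zones["ankle_joint"]
    L_joint = len(joint) * vs
    n_pits = 0
    if pit_density > 0:
        area = 2.0 * math.pi * params.outer_radius_mm * L_joint
        n_pits = int(rng_pits.poisson(pit_density * area))
        theta = rng_pits.uniform(0, 2 * math.pi, n_pits)
        z_coords = _axis_coords(shape[0], vs)
        z_lo = z_coords[joint.start] - vs / 2.0
        zc = z_lo + rng_pits.uniform(0, L_joint, n_pits)
        centers_mm = np.column_stack(
            [
                zc,
                params.outer_radius_mm * np.sin(theta),
                params.outer_radius_mm * np.cos(theta),
            ]
        )
        _carve_pits(bone, centers_mm, params.pit_radius_mm, shape, vs)

    data = np.where(bone, params.bone_density, params.background_density).astype(np.float64)
    if params.noise_sd > 0:
        data += rng_noise.normal(0.0, params.noise_sd, size=shape)
    vol = DensityVolume(data=data, voxel_size_um=params.voxel_size_um, name=f"tibia_seed{seed}")

    mid = zones["tibial_midshaft_cort"]
    L_mid = len(mid) * vs
    truth = {
        "seed": seed,
        "voxel_size_um": params.voxel_size_um,
        "thinning_factor": thinning_factor,
        "rod_diameter_mm": d_rod,
        "n_rods": n_rods,
        "outer_radius_mm": params.outer_radius_mm,
        "inner_radius_mm": r_in,
        "cortical_thickness_mm": params.outer_radius_mm - r_in,
        "marrow_volume_mm3": math.pi * r_in**2 * L_mid,
        "total_diaphysis_volume_mm3": math.pi * params.outer_radius_mm**2 * L_mid,
        "pit_density": pit_density,
        "pit_count": n_pits,
        "landmark_slice": params.landmark_slice,
    }
    return vol, truth


def make_study(
    group_sizes: dict[str, int] | tuple[int, int, int],
    thinning: float = 0.8,
    marrow_fold_change: float = 1.6,
    pit_density: float = 5.0,
    base: TibiaParams | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str, DensityVolume]], pd.DataFrame]:
    """Generate a three-group study of tibia phantoms.

    ``marrow_fold_change`` is the factor by which the marrow volume of
    treated (``CIA_SclAbI``) animals is smaller than vehicle-treated
    ones; the endosteal radius is scaled by ``1/sqrt(fold)``.  Setting
    ``thinning = 1``, ``marrow_fold_change = 1`` and ``pit_density = 0``
    produces three statistically exchangeable groups (a null study).

    Returns ``(samples, truth)`` where samples are ``(sample_id, group,
    volume)`` and truth is one row per sample.
    """
    base = base or TibiaParams()
    if isinstance(group_sizes, (tuple, list)):
        group_sizes = dict(zip(STUDY_GROUPS, group_sizes))
    unknown = set(group_sizes) - set(STUDY_GROUPS)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}; expected {STUDY_GROUPS}")
    if any(n < 1 for n in group_sizes.values()):
        raise ValueError("each group needs at least one sample")
    if marrow_fold_change <= 0 or thinning <= 0:
        raise ValueError("effect parameters must be > 0")
    r_apposed = base.inner_radius_mm / math.sqrt(marrow_fold_change)

    effects = {
        "CTR": dict(thinning_factor=1.0, inner_radius_mm=base.inner_radius_mm, pit_density=0.0),
        "CIA_PBS": dict(
            thinning_factor=thinning, inner_radius_mm=base.inner_radius_mm,
            pit_density=pit_density,
        ),
        "CIA_SclAbI": dict(
            thinning_factor=1.0, inner_radius_mm=r_apposed, pit_density=pit_density
        ),
    }

    samples: list[tuple[str, str, DensityVolume]] = []
    rows: list[dict] = []
    i = 0
    for group in STUDY_GROUPS:
        for j in range(group_sizes.get(group, 0)):
            sample_seed = int(np.random.default_rng([seed, 2, i]).integers(2**31))
            sid = f"{group}_{j:02d}"
            vol, truth = make_tibia(base, seed=sample_seed, **effects[group])
            truth.update(sample_id=sid, group=group)
            samples.append((sid, group, vol))
            rows.append(truth)
            i += 1
    truth_df = pd.DataFrame(rows)
    cols = ["sample_id", "group"] + [c for c in truth_df.columns if c not in ("sample_id", "group")]
    return samples, truth_df[cols]
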