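"""Morphometric operators against analytic and brute-force oracles."""

import math

import numpy as np
import pytest

from bonemorph.morphometry import (
    bone_surface,
    bone_volume,
    cortical_thickness,
    local_thickness,
    marrow_and_total_volume,
    total_volume,
    trabecular_thickness,
)
from bonemorph.phantoms import PhantomSpec, make_phantom
from bonemorph.preprocess import (
    STANDARD_FILTER,
    SegmentationParams,
    gaussian_filter,
    segment,
)
from bonemorph.roi import RoiMask, slab_mask

from conftest import make_mask, make_volume

VS = 6.0  # um
VOX = (VS / 1000.0) ** 3  # mm^3


def _segmented(spec: PhantomSpec):
    vol, truth = make_phantom(spec)
    filt = gaussian_filter(vol, STANDARD_FILTER)
    mask = segment(filt, SegmentationParams(500.0))
    roi = slab_mask(vol, range(vol.shape[0]), label="custom")
    return vol, filt, mask, roi, truth


def test_bone_volume_is_count_times_voxel_volume():
    mask = np.zeros((20, 10, 10), dtype=bool)
    mask.reshape(-1)[:1000] = True
    bv = make_mask(mask, VS)
    roi = slab_mask(bv, range(20), label="custom")
    assert bone_volume(bv, roi) == pytest.approx(1000 * VOX, rel=1e-12)
    empty = make_mask(np.zeros((20, 10, 10), dtype=bool), VS)
    assert bone_volume(empty, roi) == 0.0


def test_bone_volume_ball_matches_per_voxel_counting_oracle():
    spec = PhantomSpec(
        family="sphere", geometry={"radius_mm": 0.12}, noise_sd=0.0, voxel_size_um=VS, seed=2
    )
    vol, truth = make_phantom(spec)
    mask = segment(vol, SegmentationParams(500.0))  # noise-free: threshold recovers the solid
    roi = slab_mask(vol, range(vol.shape[0]), label="custom")
    # independent counting oracle over voxel centres
    n = vol.shape[0]
    c = (n - 1) / 2.0
    z, y, x = np.mgrid[0:n, 0:n, 0:n]
    inside = ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) * (VS / 1000.0) ** 2 <= 0.12**2
    assert bone_volume(mask, roi) == pytest.approx(int(inside.sum()) * VOX, rel=1e-12)


def test_total_volume_arithmetic():
    bv = make_mask(np.ones((100, 50, 50), dtype=bool), VS)
    roi = slab_mask(bv, range(100), label="custom")
    assert total_volume(roi) == pytest.approx(100 * 2500 * VOX, rel=1e-12)
    single = np.zeros((4, 4, 4), dtype=bool)
    single[1, 2, 3] = True
    roi1 = RoiMask(mask=make_mask(single, VS), label="custom")
    assert total_volume(roi1) == pytest.approx(VOX, rel=1e-12)


def test_total_volume_cylinder_matches_analytic():
    n, r = 64, 22
    y, x = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    disc = (y - c) ** 2 + (x - c) ** 2 <= r**2
    roi = RoiMask(mask=make_mask(np.broadcast_to(disc, (30, n, n)).copy(), VS), label="custom")
    analytic = math.pi * (r * VS / 1000.0) ** 2 * (30 * VS / 1000.0)
    assert total_volume(roi) == pytest.approx(analytic, rel=0.02)


def test_bone_surface_sphere_within_3pct():
    spec = PhantomSpec(
        family="sphere", geometry={"radius_mm": 0.18}, voxel_size_um=VS, seed=1
    )
    _, filt, _, roi, truth = _segmented(spec)
    bs = bone_surface(filt, 500.0, roi)
    assert bs == pytest.approx(4 * math.pi * 0.18**2, rel=0.03)


def test_bone_surface_additive_for_disjoint_spheres():
    # two identical spheres far apart in one volume
    spec = PhantomSpec(
        family="sphere", geometry={"radius_mm": 0.09}, noise_sd=0.0, voxel_size_um=VS, seed=1
    )
    vol, truth = make_phantom(spec)
    n = vol.shape[0]
    pair = np.full((n, n, 2 * n + 10), 100.0)
    pair[:, :, :n] = vol.data
    pair[:, :, n + 10 :] = vol.data
    vol2 = make_volume(pair, VS)
    filt1 = gaussian_filter(vol, STANDARD_FILTER)
    filt2 = gaussian_filter(vol2, STANDARD_FILTER)
    roi1 = slab_mask(vol, range(n), label="custom")
    roi2 = slab_mask(vol2, range(n), label="custom")
    single = bone_surface(filt1, 500.0, roi1)
    both = bone_surface(filt2, 500.0, roi2)
    assert both == pytest.approx(2 * single, rel=1e-6)


def test_bone_surface_empty_roi_bone_returns_zero():
    vol = make_volume(np.full((10, 10, 10), 100.0), VS)
    roi = slab_mask(vol, range(10), label="custom")
    assert bone_surface(vol, 500.0, roi) == 0.0


def test_bone_surface_convergence_with_radius():
    # Gaussian blurring moves an iso-surface inward by sigma^2 * curvature,
    # so the mid-level set of the filtered ball is a sphere of radius
    # ~ r - sigma_eff^2 / r; against that target the triangulated area
    # converges as the radius grows.
    from bonemorph.preprocess import gaussian_kernel

    k = gaussian_kernel(0.8, 1)
    sig2 = float((k * np.array([-1, 0, 1]) ** 2).sum())
    errs = []
    for r_vox in (10, 20, 40):
        r_mm = r_vox * VS / 1000.0
        spec = PhantomSpec(
            family="sphere", geometry={"radius_mm": r_mm}, noise_sd=0.0, voxel_size_um=VS, seed=1
        )
        _, filt, _, roi, _ = _segmented(spec)
        bs = bone_surface(filt, 500.0, roi)
        r_star = (r_vox - sig2 / r_vox) * VS / 1000.0
        errs.append(abs(bs / (4 * math.pi * r_star**2) - 1.0))
    assert errs[0] > errs[1] > errs[2]


def test_plate_thickness_within_one_voxel():
    spec = PhantomSpec(
        family="plate",
        geometry={"thickness_mm": 0.060, "lateral_voxels": 48},
        noise_sd=0.0,
        voxel_size_um=VS,
        seed=2,
    )
    _, _, mask, roi, _ = _segmented(spec)
    assert trabecular_thickness(mask, roi) == pytest.approx(0.060, abs=VS / 1000.0)


def test_ball_central_thickness_is_diameter():
    spec = PhantomSpec(
        family="sphere", geometry={"radius_mm": 0.12}, noise_sd=0.0, voxel_size_um=VS, seed=4
    )
    _, _, mask, _, _ = _segmented(spec)
    th = local_thickness(mask.mask)
    c = tuple(s // 2 for s in mask.mask.shape)
    assert th[c] == pytest.approx(40.0, abs=2.0)  # diameter in voxels


def test_rod_lattice_thickness_within_15pct():
    spec = PhantomSpec(
        family="rod_lattice",
        geometry={"rod_diameter_mm": 0.048, "spacing_mm": 0.12, "n_rods": 3, "length_voxels": 40},
        noise_sd=0.0,
        voxel_size_um=VS,
        seed=3,
    )
    _, _, mask, roi, _ = _segmented(spec)
    assert trabecular_thickness(mask, roi) == pytest.approx(0.048, rel=0.15)


def test_hollow_cylinder_cortical_thickness_within_one_voxel():
    spec = PhantomSpec(
        family="cortical_tube",
        geometry={"outer_radius_mm": 0.36, "inner_radius_mm": 0.24, "length_voxels": 40},
        noise_sd=0.0,
        voxel_size_um=VS,
        seed=3,
    )
    _, _, mask, roi, _ = _segmented(spec)
    assert cortical_thickness(mask, roi) == pytest.approx(0.120, abs=VS / 1000.0)


def test_solid_cylinder_thickness_approaches_diameter_at_centre():
    n = 60
    y, x = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    disc = (y - c) ** 2 + (x - c) ** 2 <= 20**2
    mask = np.broadcast_to(disc, (50, n, n)).copy()
    th = local_thickness(mask)
    assert th[25, n // 2, n // 2] == pytest.approx(40.0, abs=2.0)


def test_one_voxel_shell_reads_at_most_two_voxels():
    ring = np.zeros((30, 30), dtype=bool)
    y, x = np.mgrid[0:30, 0:30]
    c = (30 - 1) / 2.0
    rho = np.sqrt((y - c) ** 2 + (x - c) ** 2)
    ring[(rho > 9.0) & (rho <= 10.0)] = True
    mask = np.broadcast_to(ring, (10, 30, 30)).copy()
    th = local_thickness(mask)
    mean = th[mask].mean()
    assert 0.0 < mean <= 2.01


def test_marrow_volume_analytic_and_conservation():
    spec = PhantomSpec(
        family="cortical_tube",
        geometry={"outer_radius_mm": 0.36, "inner_radius_mm": 0.24, "length_voxels": 100},
        noise_sd=0.0,
        voxel_size_um=VS,
        seed=3,
    )
    _, _, mask, roi, _ = _segmented(spec)
    marrow, total = marrow_and_total_volume(mask, roi)
    analytic = math.pi * 0.24**2 * (100 * VS / 1000.0)
    assert marrow == pytest.approx(analytic, rel=0.02)
    assert total - marrow == pytest.approx(bone_volume(mask, roi), rel=1e-12)


def test_solid_cylinder_has_zero_marrow():
    n = 40
    y, x = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    disc = (y - c) ** 2 + (x - c) ** 2 <= 12**2
    mask = make_mask(np.broadcast_to(disc, (10, n, n)).copy(), VS)
    roi = slab_mask(mask, range(10), label="custom")
    marrow, total = marrow_and_total_volume(mask, roi)
    assert marrow == 0.0
    assert total == pytest.approx(bone_volume(mask, roi), rel=1e-12)


def test_bvtv_matches_generator_fill_fraction():
    spec = PhantomSpec(
        family="rod_lattice",
        geometry={"rod_diameter_mm": 0.06, "spacing_mm": 0.12, "n_rods": 4, "length_voxels": 40},
        noise_sd=0.0,
        voxel_size_um=VS,
        seed=5,
    )
    _, _, mask, roi, truth = _segmented(spec)
    bvtv = bone_volume(mask, roi) / total_volume(roi)
    assert bvtv == pytest.approx(truth["fill_fraction"], rel=0.02)


def test_extensive_quantities_additive_over_disjoint_rois():
    spec = PhantomSpec(
        family="cortical_tube",
        geometry={"outer_radius_mm": 0.24, "inner_radius_mm": 0.15, "length_voxels": 40},
        voxel_size_um=VS,
        seed=6,
    )
    vol, filt, mask, _, _ = _segmented(spec)
    lower = slab_mask(vol, range(0, 20), label="custom")
    upper = slab_mask(vol, range(20, 40), label="custom")
    whole = slab_mask(vol, range(0, 40), label="custom")
    assert bone_volume(mask, lower) + bone_volume(mask, upper) == pytest.approx(
        bone_volume(mask, whole), rel=1e-12
    )
    # lateral surface is additive; the split plane introduces no caps
    bs_sum = bone_surface(filt, 500.0, lower) + bone_surface(filt, 500.0, upper)
    assert bs_sum == pytest.approx(bone_surface(filt, 500.0, whole), rel=0.05)


def test_thickness_resolution_consistency():
    vals = {}
    for vs in (12.0, 6.0):
        spec = PhantomSpec(
            family="cortical_tube",
            geometry={"outer_radius_mm": 0.36, "inner_radius_mm": 0.24, "length_voxels": 20},
            noise_sd=0.0,
            voxel_size_um=vs,
            seed=3,
        )
        _, _, mask, roi, _ = _segmented(spec)
        vals[vs] = cortical_thickness(mask, roi)
    assert vals[6.0] == pytest.approx(vals[12.0], rel=0.05)


def test_geometry_mismatch_rejected():
    a = make_mask(np.ones((4, 4, 4), dtype=bool), 6.0)
    b = slab_mask(make_mask(np.ones((4, 4, 4), dtype=bool), 12.0), range(4), label="custom")
    with pytest.raises(ValueError, match="geometry mismatch"):
        bone_volume(a, b)
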