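"""Phantom generator: determinism, analytic truth, pits, study design."""

import math

import numpy as np
import pytest

from bonemorph.phantoms import (
    PhantomSpec,
    TibiaParams,
    make_phantom,
    make_study,
    make_tibia,
)


def test_generation_deterministic():
    spec = PhantomSpec(family="sphere", geometry={"radius_mm": 0.1}, voxel_size_um=6.0, seed=1)
    a, ta = make_phantom(spec)
    b, tb = make_phantom(spec)
    np.testing.assert_array_equal(a.data, b.data)
    assert ta == tb


def test_seed_changes_noise_not_geometry():
    spec1 = PhantomSpec(family="sphere", geometry={"radius_mm": 0.1}, voxel_size_um=6.0, seed=1)
    spec2 = PhantomSpec(family="sphere", geometry={"radius_mm": 0.1}, voxel_size_um=6.0, seed=2)
    a, ta = make_phantom(spec1)
    b, tb = make_phantom(spec2)
    assert (a.data != b.data).any()
    assert ta["bone_voxel_count"] == tb["bone_voxel_count"]


def test_noise_free_sphere_matches_membership_oracle():
    spec = PhantomSpec(
        family="sphere", geometry={"radius_mm": 0.1}, noise_sd=0.0, voxel_size_um=6.0, seed=1
    )
    vol, truth = make_phantom(spec)
    n = vol.shape[0]
    c = (n - 1) / 2.0
    z, y, x = np.mgrid[0:n, 0:n, 0:n]
    inside = ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) * 0.006**2 <= 0.1**2
    assert int((vol.data > 500).sum()) == int(inside.sum()) == truth["bone_voxel_count"]
    # lower bound sanity: digital count near analytic ball volume
    assert truth["bone_voxel_count"] >= 0.95 * (4 / 3) * math.pi * (0.1 / 0.006) ** 3


def test_pit_count_is_poisson_with_stated_intensity():
    density = 2.0
    counts = []
    for seed in range(50):
        spec = PhantomSpec(
            family="pitted_sphere",
            geometry={"radius_mm": 0.9},
            pit_density=density,
            pit_radius_mm=0.06,
            noise_sd=0.0,
            voxel_size_um=30.0,
            seed=seed,
        )
        _, truth = make_phantom(spec)
        counts.append(truth["pit_count"])
    lam = density * 4 * math.pi * 0.9**2
    assert np.mean(counts) == pytest.approx(lam, rel=0.15)
    assert np.var(counts) == pytest.approx(lam, rel=0.6)  # Poisson dispersion


def test_pits_remove_bone():
    base = dict(geometry={"radius_mm": 0.2}, noise_sd=0.0, voxel_size_um=6.0, seed=3)
    _, smooth = make_phantom(PhantomSpec(family="sphere", **base))
    _, pitted = make_phantom(
        PhantomSpec(family="pitted_sphere", pit_density=5.0, pit_radius_mm=0.05, **base)
    )
    assert pitted["pit_count"] > 0
    assert pitted["bone_voxel_count"] < smooth["bone_voxel_count"]


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(family="doughnut")
    with pytest.raises(ValueError):
        PhantomSpec(family="sphere", geometry={"radius_mm": -1.0})
    with pytest.raises(ValueError):
        PhantomSpec(family="sphere", geometry={"radius_mm": 0.1}, pit_density=-1.0)
    with pytest.raises(ValueError):
        make_phantom(
            PhantomSpec(
                family="cortical_tube",
                geometry={"outer_radius_mm": 0.1, "inner_radius_mm": 0.2, "length_voxels": 8},
            )
        )


def test_speckle_fill_fraction():
    spec = PhantomSpec(family="speckle", shape=(64, 64, 64), seed=1)
    _, truth = make_phantom(spec)
    assert truth["bone_voxel_count"] / 64**3 == pytest.approx(0.5, abs=0.01)


def test_study_bookkeeping():
    samples, truth = make_study(
        (2, 2, 2), thinning=0.8, marrow_fold_change=1.6, pit_density=5.0, seed=7
    )
    assert len(samples) == 6
    assert truth.shape[0] == 6
    assert set(truth["group"]) == {"CTR", "CIA_PBS", "CIA_SclAbI"}
    pbs = truth[truth.group == "CIA_PBS"].iloc[0]
    ctr = truth[truth.group == "CTR"].iloc[0]
    scl = truth[truth.group == "CIA_SclAbI"].iloc[0]
    assert pbs["thinning_factor"] == 0.8
    assert scl["thinning_factor"] == 1.0
    assert ctr["pit_density"] == 0.0
    assert pbs["pit_density"] == scl["pit_density"] == 5.0


def test_study_truth_marrow_fold_change_self_consistent():
    _, truth = make_study((1, 1, 1), marrow_fold_change=1.6, seed=3)
    pbs = truth[truth.group == "CIA_PBS"]["marrow_volume_mm3"].iloc[0]
    scl = truth[truth.group == "CIA_SclAbI"]["marrow_volume_mm3"].iloc[0]
    assert pbs / scl == pytest.approx(1.6, rel=1e-9)


def test_null_study_groups_geometrically_exchangeable():
    _, truth = make_study((2, 2, 2), thinning=1.0, marrow_fold_change=1.0, pit_density=0.0, seed=5)
    assert truth["rod_diameter_mm"].nunique() == 1
    assert truth["inner_radius_mm"].nunique() == 1
    assert (truth["pit_count"] == 0).all()


def test_study_rejects_bad_design():
    with pytest.raises(ValueError):
        make_study((0, 2, 2))
    with pytest.raises(ValueError):
        make_study({"CTR": 2, "MYSTERY": 2})
    with pytest.raises(ValueError):
        make_study((1, 1, 1), marrow_fold_change=-1.0)


def test_tibia_pits_restricted_to_joint_zone():
    base = TibiaParams()
    vol_p, truth_p = make_tibia(base, pit_density=8.0, seed=2)
    vol_0, truth_0 = make_tibia(base, pit_density=0.0, seed=2)
    assert truth_p["pit_count"] > 0
    diff = vol_p.data != vol_0.data
    zones = base.zones
    joint = zones["ankle_joint"]
    ks = np.flatnonzero(diff.any(axis=(1, 2)))
    # pits may spill a pit radius outside the zone but not further
    spill = math.ceil(base.pit_radius_mm / (base.voxel_size_um / 1000.0)) + 1
    assert ks.min() >= joint.start - spill
    assert ks.max() < joint.stop + spill


def test_tibia_rejects_nonphysical_geometry():
    with pytest.raises(ValueError):
        make_tibia(TibiaParams(), inner_radius_mm=0.5)  # >= outer radius
    with pytest.raises(ValueError):
        make_tibia(TibiaParams(), thinning_factor=0.0)
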