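# Methods

This note documents the measurement model implemented by `bonemorph`,
the numerical conventions it commits to, what the synthetic phantoms do
and do not emulate, and the known limitations.

## Input model

Inputs are dense 3-D grids of calibrated mineral density
(mg hydroxyapatite/cm³) with a single isotropic voxel size; the default
configuration emulates a 6 µm cabinet scanner. Calibration (attenuation
→ density) and any beam-hardening correction are assumed to have been
applied by the scanner software; the package performs none. The
tomogram stack runs along axis 0, slices are 0-indexed, and slab ROIs
are half-open index ranges `[start, start + n)`, so "a 200-tomogram
slab" is an exact count. Millimetre extents convert to slice counts by
round-half-away-from-zero, making 0.6 mm ↔ 100 and 1.2 mm ↔ 200 slices
at 6 µm exact identities.

## Denoising and segmentation

Denoising is a separable discrete Gaussian: taps `exp(-i²/2σ²)` at
integer offsets `i ∈ [-support, support]` per axis, renormalised to unit
sum (so constants are preserved exactly), applied with mirror-reflected
boundaries so structures near the volume edge are not darkened. This is
the (σ, support) parameterisation used by scanner vendors' IPL-style
software; `support` is the truncation half-width in voxels, i.e.
support = 1 gives a 3-tap kernel. Defaults: σ = 0.8, support = 1 for
denoising; σ = 2.5, support = 5 for the strong smoothing used by the
smoothness estimator. Whether the vendor samples the continuous kernel
or integrates it per voxel is not documented; the sampled-and-
renormalised form is used here (the difference is far below the other
discretisation terms). Segmentation is a global fixed threshold on the
calibrated density, default 500 mg HA/cm³, with the inclusive
convention bone := density ≥ threshold (the choice of ≥ versus > is
arbitrary; it is fixed and tested).

## Regions of interest

Slab ROIs are anchored to an anatomic landmark supplied as an explicit
slice index — for phantoms, from the generator; for real scans, by the
operator. Automatic landmark detection is out of scope. Joint ROIs are
slabs of n tomograms centred on a slice (ties broken toward the lower
index), optionally intersected with a lateral mask. The trabecular
compartment replaces manual contouring: the cortical shell on each
slice is the connected component enclosing the largest filled area, and
the compartment is its morphological fill minus the shell. A slice
whose shell encloses no interior while other slices do is reported as a
broken shell with its index; a shell with no interior anywhere (a solid
rod) legitimately yields an empty compartment. Trabecular elements
fused to the shell are counted as shell, a known limitation of
programmatic contouring; the phantom lattice keeps rods clear of the
cortex so this does not affect recovery testing.

## Morphometry

* **BV, TV, BV/TV, marrow and total diaphysis volume** are voxel counts
  × voxel volume. Using pure counting makes conservation exact:
  total − marrow equals shell bone volume to the last bit, which is
  asserted in the tests.
* **BS** is the area of the marching-cubes triangulation of the
  *filtered grayscale* field at the segmentation threshold, restricted
  to ROI-interior grid cells. A mid-grey iso-surface converges to the
  true area (≈ 0.8 % high for a 30-voxel-radius sphere), whereas
  counting voxel faces overestimates smooth oblique surfaces by tens of
  percent. Surfaces cut by the ROI boundary are left open: slab ends
  are artifacts of ROI selection, not anatomy, so they contribute no
  area, and BS is additive across adjacent slabs. The mixed convention
  (mesh area for BS, voxel counting for volumes) is deliberate.
  One subtlety quantified in the tests: Gaussian filtering shifts an
  iso-surface inward by σ²·(mean curvature), so the measured sphere
  area converges to 4π(r − σ_eff²/r)², not 4πr²; at r ≥ 30 voxels the
  distinction is below 1 %.
* **Tb.Th / Ct.Th** use the model-independent local-thickness
  definition (the diameter of the largest inscribed sphere containing
  each point), volume-weighted over bone voxels. The map is computed by
  sphere granulometry on the Euclidean distance transform: radii are
  swept downward in 0.25-voxel steps; voxels within r of a voxel whose
  EDT value is ≥ r receive thickness 2r unless already covered by a
  larger sphere. The inscribed radius is the plain EDT value (the
  convention of the standard ImageJ local-thickness plugin); on digital
  structures this quantises thickness upward by up to one voxel (a
  1-voxel shell reads ≈ 2 voxels), while the sweep step bounds the
  downward binning error at 0.5 voxel. Validated oracles: a 10-voxel
  plate reads exactly 10 voxels, a 20-voxel tube wall reads 20.3, a
  ball's central thickness reads its diameter ± 2 voxels. The array
  boundary is treated as a continuation of the structure, so laterally
  clipped plates are not artificially thinned.

## Erosion scores

`BS/BV` (1/mm) is the classical surface density: pitting raises BS and
lowers BV, so it rises with erosion — but bone accrual anywhere lowers
it, confounding erosion with mass. The smoothness estimator
`BSsmooth/BS` recomputes BS after the strong Gaussian (σ = 2.5,
support = 5) applied to the **raw grayscale volume**, re-segmented at
the same threshold and re-meshed with the identical algorithm and ROI,
then takes the ratio. Smooth surfaces are nearly invariant under extra
smoothing (ratio ≈ 1); rough ones lose most of their area (ratio → 0);
and because numerator and denominator measure the same structure, the
ratio is insensitive to bone-volume changes. This lets the pair of
scores dissociate persistent surface pitting from endosteal apposition:
on a pitted-tube phantom, reducing the endosteal radius (apposition)
moves BS/BV by ~ −37 % while moving smoothness by < 0.1 %.

Conventions: applying the strong filter to the raw volume (rather than
on top of the standard-filtered one) follows the natural reading of
"smoothing the images"; the two differ by a convolution of width
√(0.8² + 2.5²) ≈ 2.6 vs 2.5 voxels, i.e. negligibly. If the strong
filter erases all structure, BSsmooth = 0 and smoothness = 0, matching
the rough-surface limit. Smoothing the *binary mask* instead is a
documented alternative the API can express (segment, scale to density,
re-filter) but is not the default.

A quantified edge case: on an i.i.d. half-filled binary speckle volume
with densities symmetric about the threshold, the strongly-smoothed
field has mean exactly at the iso-level, so a percolating level-set
surface survives smoothing (area per unit volume ≈ 0.18/voxel,
matching the Gaussian-random-field prediction) and the ratio bottoms
out near 0.31 rather than 0. Any asymmetry between fill fraction and
threshold drives it to ~0. The estimator's "rough → 0" limit therefore
holds except exactly at this symmetric singular point, which is where
the default speckle phantom sits.

## Synthetic phantoms

Phantoms are analytic solids voxelised at voxel centres: spheres,
plates, rod lattices, cortical tubes, pitted variants, speckle, and a
composite tibia (cortical tube with a trabecular rod lattice in a
"metaphysis" zone, a bare "midshaft", and a "joint" zone with
periosteal pits). Bone maps to 900 and background to 100 mg HA/cm³ —
values bracketing the 500 threshold symmetrically, as murine cortical
bone and soft tissue do on a calibrated scale — and i.i.d. Gaussian
noise of SD 60 mg HA/cm³ is added everywhere (≈ 6.7 σ separation
between phases, comparable to a good cabinet scan). Focal erosion is
modelled as hemispherical pits: centres drawn from a Poisson process on
the analytic outer surface with a stated intensity (pits/mm²), bone
removed within the pit radius (default 0.05 mm). Generation is fully
deterministic given (spec, seed); noise and pit placement draw from
separate seeded streams, so changing geometry (e.g. the endosteal
radius) never reshuffles the pits — which is what makes matched
apposition comparisons possible.

Auto-sized grids use even dimensions so voxel centres sit at
half-integer offsets from the solid's centre; otherwise round-number
geometry (a 0.060 mm plate at 6 µm) places analytic boundaries exactly
on voxel centres and the digital structure gains a spurious voxel.

`make_study` generates three groups on the tibia phantom: healthy
controls (baseline rods, no pits); arthritic + vehicle (rod diameter
scaled by a thinning factor, default 0.8, and periosteal pitting,
default 5 pits/mm²); arthritic + anabolic antibody (same pitting, no
thinning, and endosteal apposition — the inner radius scaled by
1/√fold so the marrow volume shrinks by the configured fold-change,
default 1.6). Default tibia geometry: 10 µm voxels, outer radius
0.40 mm, endosteal radius 0.30 mm, 0.10 mm rods on a 0.15 mm lattice —
cortical and trabecular feature sizes of 10 voxels, matching murine
microCT practice where trabeculae span ~8–12 voxels. With n = 5 per
group the pipeline recovers the thinning factor to ~3 % and the marrow
fold-change to ~0.3 %.

What the phantoms do **not** emulate: anatomical shape (curved shafts,
condyles, growth-plate primary spongiosa), inter-animal geometric
variability, spatially correlated scanner noise, ring or beam-hardening
artifacts, partial-volume blur beyond the Gaussian model, and erosion
morphologies other than hemispherical pits. Passing recovery tests
therefore demonstrates correctness of the measurement chain on known
geometry, not robustness to anatomical variation or scanner artifacts.

## Statistics

Continuous outcomes: one-way fixed-effects ANOVA from the classical
sums of squares, with Tukey HSD post-hoc comparisons (Tukey–Kramer
standard error for unequal n; adjusted p from the studentized-range
distribution with pooled within-group df). Ordinal outcomes: two-sided
Mann–Whitney U; for small samples (nA·nB ≤ 400 and ≤ 2·10⁵ group
assignments) the exact permutation distribution of U is enumerated —
handling ties correctly, where the textbook normal approximation can be
off by ~0.08 on tie-heavy score-like data — and larger samples use the
tie-corrected normal approximation with continuity correction. The
permutation distribution of U is symmetric about nA·nB/2, so the
two-sided convention P(|U−μ| ≥ |u−μ|) coincides with the doubled-tail
convention on tie-free data. All tests are two-sided with α = 0.05.
Summaries report n, mean, sample SD (n−1) and SEM per group, with SD
undefined for singletons. Under a three-group null (n = 10 each, 2000
seeded replicates) the ANOVA rejects at 5.2 %.

## Pipeline

`run()` processes each sample through read → standard filter →
segment → ROI construction → morphometry → erosion, then pools samples
into group statistics. Per-sample failures are recorded with sample id
and stage and do not stop the run. Output CSVs use a fixed
10-significant-digit float format and the provenance record (package
and library versions, all parameters, SHA-256 of every input volume)
contains no timestamps, so identical configurations reproduce
byte-identical bundles; there is no hidden global randomness. Problem
sizes in the test-suite simulations (128³ speckle, 40-voxel spheres,
15-sample studies at 10 µm) were chosen to exercise every code path at
desk scale while keeping features ≥ 5 voxels, the regime where discrete
morphometry is reliable.

## Known limitations

* Density calibration, scanner-specific corrections and proprietary
  formats (ISQ/AIM, DICOM) are out of scope.
* Thickness values quantise upward by up to one voxel on minimal
  structures; comparisons between groups measured at the same
  resolution are unaffected, absolute values at < 5-voxel features are
  not trustworthy.
* BS/BV and smoothness pool all bone in a joint ROI; per-bone or
  per-pit analysis, and automatic separation of periosteal from
  endosteal surfaces, are not implemented.
* The trabecular-compartment mask assigns shell-fused trabeculae to the
  cortex.
* Tb.N, Tb.Sp, SMI, connectivity and anisotropy are not computed.
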