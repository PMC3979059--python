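# bonemorph

Quantitative microCT bone morphometry and focal-erosion scoring for
small-animal skeletal phenotyping, with a synthetic phantom generator
for validation and simulation studies.

In rodent models of inflammatory arthritis, disease affects bone in two
distinct ways: *systemic* loss of trabecular and cortical bone (thinning
of trabeculae, reduced bone volume fraction), and *focal erosion* —
superficial pitting of the periarticular bone surfaces at inflamed
joints. Anabolic treatments can rebuild bone mass without repairing
surface pits, so an analysis must separate "how much bone" from "how
rough is its surface". `bonemorph` implements the full measurement chain
for calibrated microCT volumes (mg hydroxyapatite/cm³, isotropic
voxels):

* **Preprocessing** — separable truncated Gaussian denoising
  (σ = 0.8, support = 1 voxel by default) and fixed-threshold
  segmentation at 500 mg HA/cm³.
* **Regions of interest** — landmark-anchored slabs counted in
  tomograms (e.g. a 0.6 mm ≡ 100-slice mid-diaphysis segment, a 1.2 mm
  ≡ 200-slice metaphysis slab starting 0.30 mm from a growth-plate
  landmark, joint slabs centred on the synovial space), plus a
  programmatic trabecular-compartment mask (per-slice filling of the
  cortical shell).
* **Morphometry** — BV, TV, BV/TV by voxel counting; BS from a
  triangulated iso-surface (marching cubes) of the filtered density
  field, clipped open at ROI boundaries; Tb.Th and Ct.Th by the
  model-independent maximal-inscribed-sphere (local thickness) method;
  marrow and total diaphysis volume from the filled cortical shell.
* **Erosion scores** — the surface density **BS/BV** (1/mm), which
  rises with pitting but falls with any bone accrual, and the
  **smoothness estimator BSsmooth/BS**: BS is recomputed after a strong
  Gaussian smoothing (σ = 2.5, support = 5) of the grayscale volume and
  the ratio taken. It is ≈ 1 for smooth surfaces (extra smoothing
  changes nothing) and → 0 for very rough ones, and — being a ratio of
  areas of the same structure — is insensitive to changes in bone
  volume. Together the two scores dissociate persistent pitting from
  endosteal bone apposition.
* **Phantoms** — spheres, plates, rod lattices, cortical tubes, pitted
  variants, speckle and a composite tibia-like phantom with known
  analytic geometry, Poisson-distributed hemispherical surface pits and
  Gaussian scanner noise; `make_study` builds three-group studies
  (healthy control / arthritic + vehicle / arthritic + anabolic
  antibody) with configurable trabecular thinning, pit density and
  marrow-volume fold-change, returning a ground-truth table.
* **Statistics** — one-way ANOVA with Tukey HSD post-hoc comparisons
  and the two-sided Mann–Whitney U test (exact permutation enumeration
  for small samples, tie-corrected normal otherwise), plus per-group
  mean/SD/SEM summaries.
* **Pipeline & CLI** — `bonemorph analyze --config run.yaml` runs
  read → filter → segment → ROI → morphometry → erosion → statistics
  for a sample manifest and writes per-sample and group-statistics CSVs
  with a provenance record; `bonemorph generate-study` writes a
  synthetic study (volumes + truth table + ready-to-run config);
  `bonemorph validate` checks a config without computing.

Volumes are read and written as multipage TIFF (with a JSON sidecar for
the voxel size), MetaImage (`.mha`/`.mhd`) or NRRD.

## Worked example

Score a smooth and a pitted bone surface:

```python
from bonemorph import PhantomSpec, make_phantom, slab_mask, smoothness_estimator

for density in (0.0, 8.0):
    spec = PhantomSpec(
        family="pitted_sphere",
        geometry={"radius_mm": 0.24},   # 40 voxels at 6 um
        pit_density=density,            # pits per mm^2 of surface
        pit_radius_mm=0.05,
        voxel_size_um=6.0,
        seed=42,
    )
    volume, truth = make_phantom(spec)
    roi = slab_mask(volume, range(volume.shape[0]), label="custom")
    scores = smoothness_estimator(volume, roi)
    print(
        f"pit density {density:4.1f}/mm^2 ({truth.get('pit_count', 0):2d} pits): "
        f"BV = {scores.BV:.4f} mm^3, BS = {scores.BS:.4f} mm^2, "
        f"BS/BV = {scores.BS_over_BV:.2f} /mm, BSsmooth/BS = {scores.smoothness:.3f}"
    )
```

prints

```
pit density  0.0/mm^2 ( 0 pits): BV = 0.0579 mm^3, BS = 0.7295 mm^2, BS/BV = 12.60 /mm, BSsmooth/BS = 0.985
pit density  8.0/mm^2 (10 pits): BV = 0.0555 mm^3, BS = 0.7731 mm^2, BS/BV = 13.92 /mm, BSsmooth/BS = 0.952
```

Ten hemispherical pits remove bone (BV ↓), add surface (BS ↑), raise
the surface density BS/BV and lower the smoothness ratio — the
signature of focal erosion. For reference, the smooth sphere's measured
BV and BS sit within 1 % of the analytic 4/3·π·r³ = 0.0579 mm³ and
4·π·r² = 0.7238 mm², and BS/BV ≈ 3/r = 12.5 /mm.

A full synthetic study from the shell:

```bash
bonemorph generate-study --out study/ --seed 1
bonemorph analyze --config study/run.yaml
```

writes `study/results/per_sample.csv` (one row per sample × ROI with
BV/TV, Tb.Th, Ct.Th, marrow volume, BS/BV, BSsmooth/BS),
`stats.csv` (ANOVA + Tukey per measurement), `summary.csv` and
`provenance.json`.

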