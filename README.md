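# oomorph

3D morphometry of the ovarian follicle reserve, with simulated histology.

`oomorph` is a Python toolkit for quantifying oocytes in labeled
micro-CT-scale volumes of ovarian cortex — the tissue banked in ovarian
tissue cryopreservation (OTC) programmes, where follicle density is the key
quality metric. It computes, from an instance-labeled 3D volume plus a
surface-epithelium mask:

- **cortical geometry** — an exact Euclidean distance field to the surface
  epithelium and the cortical compartment (tissue within 1 mm of the
  surface);
- **per-oocyte morphometrics** — sub-voxel depth below the epithelium,
  equivalent sphere diameter, and the number of neighbouring oocytes within
  40 μm (oocytes with ≥ 10 neighbours are flagged as cluster members);
- **volumetric density** — oocytes per mm³ of cortex;
- **virtual histology** — the volume is cut into 4-μm sections, profiles are
  counted like a histologist would, and density is estimated with a
  stereological duplicate-count correction, so that sparse 2D sampling
  designs can be compared against the full-volume 3D answer.

Because real labeled patient volumes are not distributable, the package
ships a first-class **phantom generator**: synthetic cortical volumes with
known ground truth, built from a Thomas cluster point process with
depth-stratified oocyte positions, hard-core packing, sphere rasterisation
and optional intensity rendering. Two calibrated presets reproduce the
qualitative regimes of pediatric tissue (dense, shallow — median depth
≈ 140 μm — and strongly clustered, median 6 neighbours) and adult tissue
(sparse, deep — ≈ 370 μm — median 2 neighbours).

## The correction model

A histological section of thickness *t* shows a circular profile of every
oocyte whose sphere intersects the slab, so an oocyte of diameter *D* is
seen in ≈ (D + t)/t consecutive sections and raw profile counts overestimate
density about tenfold for D ≈ 36 μm, t = 4 μm. With every *k*-th section
analyzed, profile count *P*, per-section cortical areas *Aᵢ*, and D̄ the mean
diameter of the largest 10 % of sectioned oocytes, the corrected count and
density are

```
N̂ = P · k · t / (t + D̄)
V_ext = Σᵢ Aᵢ · k · t
density = N̂ / V_ext  =  (P / Σᵢ Aᵢ·t) · t / (t + D̄)
```

an Abercrombie/Schmidt-type estimator: unbiased for equal spheres, and
slightly *over*-correcting when the diameter distribution is right-skewed
(D̄ then overestimates the typical diameter) — both behaviours are asserted
in the test suite.

## Worked example

```python
from oomorph.pipeline import run_pipeline

report = run_pipeline({
    "seed": 1,
    "output_dir": "out",
    "phantom": {"preset": "pediatric", "overrides": {"dims": [240, 480, 240]}},
    "virtslice": {"thickness_um": 4.0, "interval": 10, "start": 10, "n_analyzed": 5},
})
```

This generates a 0.55 × 1.09 × 0.55 mm pediatric-like phantom (2.28 μm
voxels), measures it in 3D, and simulates the clinical five-section
histology design (sections 10, 20, 30, 40, 50). The report it printed:

```json
{
  "n_oocytes": 584,
  "cortical_volume_mm3": 0.299,
  "density_3d_per_mm3": 1953.0,
  "median_depth_um": 139.5,
  "median_neighbor_count": 6.0,
  "clustered_fraction": 0.229
}
```

584 oocytes sit in 0.299 mm³ of cortex (1953 /mm³); half of them lie within
140 μm of the surface epithelium; the median oocyte has 6 neighbours within
40 μm and 23 % belong to tight clusters (≥ 10 neighbours). The simulated
five-section count gives `density_corrected = 1820 /mm³` (−7 % vs 3D) from
195 profiles with D̄ = 35.2 μm, while the *uncorrected* profile density is
17842 /mm³ — the ~10× duplicate-count inflation the correction removes.
The same bundle is written to `out/` as `oocytes.csv`, `sections.csv`,
`summary.json` and `run.log`, byte-identical on rerun with the same config.

A CLI mirrors the library: `oomorph phantom|analyze|virtslice|compare|report`
(see `oomorph --help`).

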