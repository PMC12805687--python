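# Methods

This note documents the models, conventions and numerical choices behind
`oomorph`, and what the synthetic validation does and does not establish.

## Coordinate and unit conventions

All lengths are micrometres; densities are converted to per-mm³ only at the
reporting edge. Volumes are `(z, y, x)` arrays with isotropic voxels
(default 2.28 μm); the physical coordinate of voxel index *i* is
`i · voxel_size` (voxel-centre convention, 0-based). The **z axis is the
sectioning axis**; by default the epithelial surface is a plane normal to
**y**, so virtual sections cut *across* the cortex and every section
contains the epithelium and the full depth range — the geometry of
histological sections of cortical strips, which is why limited section
sampling can be unbiased at all. A `depth_axis="z"` variant (surface
parallel to the sections) is available; with it, a shallow five-section
window samples only the superficial cortex and is systematically biased for
depth-stratified tissue.

Depth is defined as the Euclidean distance to the nearest epithelium voxel
centre. For the planar surface this equals `max(j − (n_e − 1), 0) · v` along
the depth axis (n_e epithelium layers), which `phantom.true_geometry`
evaluates in closed form; tests assert it is identical to the distance
transform so the fast path can stand in for the EDT on planar phantoms.

## Phantom model

Oocyte centres follow a Thomas cluster process: parents are Poisson with
intensity `parent_intensity` per mm³ of nominal cortex, offspring counts are
Poisson(`mean_cluster_size`), and offspring scatter laterally around their
parent with an isotropic Gaussian (`cluster_sd`).

**Depth stratification.** The depth coordinate is resampled so its marginal
distribution follows `depth_law` exactly: each parent draws a depth
*quantile* u ~ U(0,1) and each offspring perturbs it by a wrapped Gaussian
(`depth_scatter_q`, default 0.035–0.05) before mapping through the law's
inverse CDF. Because the perturbed quantile is still marginally uniform, the
pooled depths are distributed exactly as the law prescribes, while clusters
remain depth-compact — without this coherence, clusters would be smeared
over hundreds of μm of depth and realistic neighbour counts would be
geometrically unreachable. A consequence for validation: pooled depths are
within-cluster correlated, so distribution tests (e.g. KS) are run on
cluster-size-1 configurations where draws are independent.

**Packing.** A hard-core constraint (`min_gap`, surface-to-surface) is
enforced by sequential rejection with a budget of 100 attempts per requested
oocyte; exhaustion raises a packing-infeasibility error rather than
returning an under-filled volume. `min_gap` may be negative: primordial
follicles touch in dense cortex, and the presets use −14…−16 μm because a
non-negative hard core between ~32 μm spheres caps the 40-μm neighbour count
far below the pediatric regime's median of 6. Overlapping spheres are
rasterised by nearest-centre assignment, so labels remain disjoint.

**Rasterisation.** A voxel belongs to a sphere iff its centre lies within
the sphere; the volume error of this rule is O(voxel/diameter), and the
equivalent-diameter recovery test bounds it at < 5 % for 36-μm oocytes at
2.28 μm voxels. Oocytes are kept fully inside the grid and (for
`min_gap ≥ 0`) clear of the epithelium.

**Presets** (frozen after a one-off calibration, before any downstream
result was inspected):

| parameter | pediatric | adult |
|---|---|---|
| grid (z, y, x) | 340 × 480 × 340 vox (0.78 × 1.09 × 0.78 mm) | same |
| parents / mm³ | 250 | 42 |
| mean cluster size | 8 | 6 |
| lateral scatter σ | 15 μm | 16 μm |
| depth law | lognormal(139.4 μm, σ=0.55) | lognormal(370 μm, σ=0.60) |
| diameter law | lognormal(32 μm, σ=0.08) | same |
| min_gap | −16 μm | −14 μm |
| realized density | ≈ 1990 /mm³ | ≈ 250 /mm³ |
| median depth / neighbours | ≈ 140 μm / 6 | ≈ 370 μm / 2 |

The preset grids are slightly smaller than the `PhantomSpec` default
(400 × 600 × 400) so that multi-seed studies remain desk-scale; both contain
the full 1-mm cortical shell. Tests and the acceptance script sometimes
shrink the lateral (z, x) extent further (e.g. 240 × 480 × 240) and pool
seeds instead — density, clustering and depth laws are per-volume
properties, so lateral extent trades replicates for per-replicate size.

## Instance extraction

The post-processing an analyst would do interactively is automated as:
connected components (26-connectivity default) → noise filter (volume below
that of a 10-μm sphere, ≈ 524 μm³) → vessel filter (major/minor
principal-axis ratio > 4) → marker-controlled watershed split of components
whose distance transform holds ≥ 2 local maxima ≥ 15 μm apart. Markers are
selected greedily in order of (−EDT value, flat voxel index), making the
split fully deterministic. The vessel filter runs **before** splitting:
splitting a tube first would fragment it into compact chunks that pass the
elongation test. With the noise/vessel filters disabled and splitting off,
extraction reduces exactly to connected components (asserted against a BFS
flood-fill oracle). None of these thresholds is canonical — all are exposed
in `InstanceParams`, including an optional pre-erosion (`erode_voxels`)
mimicking the deliberate one-voxel shrinkage some pipelines use to keep
touching oocytes apart.

`threshold_segment` is a deterministic stand-in for a learned segmenter so
the pipeline can be exercised end-to-end on rendered phantoms: global Otsu
(or fixed) thresholding of dark objects, computed over non-epithelium voxels.

## Morphometrics

- **Depth**: trilinear interpolation of the distance field at the oocyte
  centroid (sub-voxel, matching the sub-voxel minima such measurements show);
  a `surface` mode subtracts the oocyte radius (floored at 0). Centroid mode
  is the default — which convention real measurements used is not knowable,
  so both are provided.
- **Neighbours**: centroid-to-centroid Euclidean distance, boundary
  *inclusive* (exactly 40.0 μm counts), k-d tree implementation contractually
  equal to the quadratic definition (asserted at n = 500).
- **Cortex membership**: by centroid; an oocyte straddling the 1-mm shell
  counts iff its centroid is inside.
- The distance transform is Euclidean, not geodesic through tissue; for thin
  slab-like samples the difference is below voxel scale.

## Virtual histology

Sections are half-open slabs `[(s−1)t, s·t)` along z, 1-based; the clinical
limited design is sections 10, 20, 30, 40, 50 (start 10, interval 10,
t = 4 μm → 40-μm spacing). A sphere contributes at most one profile per
section — its largest in-slab circle, `D` if the equator lies inside the
slab, else `2·√((D/2)² − δ²)` with δ the centre-to-nearest-face distance;
zero-chord grazing contacts are never counted, so slab boundaries cannot
double-count. Profiles thinner than the visibility floor (default 5 μm,
0 for pure geometry tests) are dropped as undetectable polar caps. Per-slab
cortical areas come from the 3D cortex mask (fractional voxel-layer overlap
accumulated and divided by t), not from any per-section re-segmentation.

The corrected estimator is the Abercrombie/Schmidt form
`N̂ = P·k·t/(t + D̄)` with `V_ext = ΣAᵢ·k·t`; D̄ is the mean of the largest
10 % (ceil(0.1·n), min 1) of **per-oocyte maximum** profile diameters — the
largest oocytes, not the largest profiles, deduplicated across sections.
The identity `density_corrected = density_uncorrected · t/(t + D̄)` holds to
1e−12 by construction and is asserted on every estimator test. Expected
behaviours verified by simulation: ≈ (D+t)/t = 10× uncorrected inflation for
36-μm spheres at t = 4; unbiasedness within 5 % for equal spheres at k = 1;
systematic undercorrection (< truth) for right-skewed diameter laws;
stability of the corrected density for intervals k ≤ 10 on dense clustered
phantoms with growing spread once the sampling interval outruns the cluster
length scale (k ≥ 25); and wider five-section error spread in the sparse
clustered adult regime than in the dense pediatric one.

`interval_sweep` analyses sections k, 2k, … ("every k-th"); `offset_sweep`
varies the starting section of a limited design over all feasible starts and
summarises min/max/median/CV. Extrapolation is per analyzed section by k·t;
whether a real workflow would instead extrapolate over the whole block is an
open convention, and this choice is the one that makes k = 1 exactly the
all-sections estimate.

## Statistics

Group comparisons use the two-tailed Mann–Whitney U test: exact null
distribution for n₁·n₂ ≤ 400 without ties, tie-corrected normal
approximation with continuity correction otherwise; verified against
exhaustive enumeration of all group assignments for ≤ 8 values.

## Problem sizes and determinism

Default test/acceptance problem sizes: preset phantoms of ~0.6 mm³ cortex
(≈ 1100–1200 pediatric, ≈ 150 adult oocytes per volume), 5–10 seeds per
stochastic claim, laterally reduced (0.3 mm³) 8-seed pools for the
regime-comparison tests. All randomness flows from a single integer seed
through `numpy.random.default_rng`; identical (spec, seed) reproduces
volumes and tables bit-for-bit, and the pipeline writes byte-identical
bundles on rerun.

## What the phantoms do not model

Vascular trees (vessels are tested with rasterised tubes only),
non-spherical or incompletely segmented oocytes, anisotropic voxels, X-ray
physics (beam hardening, rings), staining gradients, and tissue deformation
or shrinkage during real sectioning. Passing tests therefore demonstrate
correctness of the measurement and estimation machinery under the stated
geometric model — not that a particular scanner or segmentation network
would achieve these accuracies on patient tissue.

## Known limitations

- The depth-quantile cluster construction is one of many ways to impose both
  clustering and a depth gradient; it was chosen for its exact marginal and
  depth-coherent clusters, not fitted to patient data.
- Preset calibration targets population medians; per-volume medians
  fluctuate (±1 neighbour, ±10 % depth) at preset size.
- The spherical-cap surface model supports mask construction and generation
  but has no closed-form fast geometry path and is only smoke-tested.
- `extract_instances` holds the full EDT of the mask in memory; grids much
  beyond ~10⁸ voxels need chunking that is not implemented.
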