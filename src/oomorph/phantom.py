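"""Synthetic ovarian-cortex phantoms with known ground truth.

The generator emulates the statistical structure of labeled cortical
micro-CT volumes: spherical hypodense oocytes of ~30–40 μm under a clustered
(Thomas) point process, a thin hyperdense surface-epithelium layer, and a
prescribed distribution of oocyte depth below the epithelium.  Two calibrated
presets reproduce the qualitative regimes seen in patient tissue: a
pediatric-like cortex (high density, shallow, strongly clustered) and an
adult-like cortex (sparse, deep, mildly clustered).

Spatial model
-------------
Oocyte centres follow a Thomas cluster process: Poisson-distributed parents
in the cortex, each with a Poisson number of offspring scattered laterally
by an isotropic Gaussian.  Depth below the epithelium is controlled
separately so that the marginal depth distribution follows ``depth_law``
exactly: each parent draws a depth *quantile* u ~ Uniform(0, 1) and offspring
perturb that quantile by a small wrapped Gaussian before mapping through the
inverse CDF of the depth law.  This keeps clusters depth-coherent (so local
neighbourhoods are genuinely three-dimensional) while the pooled depths are
distributed exactly as the law prescribes.

A hard-core constraint enforces a minimum surface-to-surface gap between
oocytes by rejection; ``min_gap`` may be negative to allow touching or
overlapping oocytes (useful for merge/split post-processing tests).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .volio import LabeledVolume, empty_oocyte_table

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PackingInfeasibleError",
    "generate_phantom",
    "preset",
    "render_intensity",
]


class PackingInfeasibleError(RuntimeError):
    """Hard-core rejection exhausted its retry budget: density infeasible."""


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of a synthetic cortical volume.

    Parameters
    ----------
    dims : (nz, ny, nx) voxels; z is the sectioning axis.
    voxel_size : isotropic voxel edge, μm.
    epithelium_model : "plane" (slab at the origin face of ``depth_axis``),
        "cap" (spherical cap bulging from that face) or "none".
    depth_axis : "y" (default) or "z"; normal of the epithelial surface.
        With "y" the surface is perpendicular to the virtual sections, as in
        histology of cortical strips where every section contains the
        epithelium and the full cortical depth; "z" stacks the sections
        parallel to the surface instead.
    epithelium_thickness_um : thickness of the epithelial layer.
    cap_radius_um : radius of curvature for the "cap" model.
    parent_intensity : cluster parents per mm³ of nominal cortex.
    mean_cluster_size : expected offspring per parent (Poisson mean, ≥ 1).
    cluster_sd : lateral Gaussian scatter σ of offspring about their parent, μm.
    depth_scatter_q : within-cluster scatter of the depth *quantile*
        (wrapped-Gaussian σ on [0, 1)); small values give depth-compact
        clusters without disturbing the marginal depth distribution.
    depth_law : ("lognormal", median_um, sigma) or ("exponential", scale_um);
        distribution of oocyte-centre depth below the epithelium.
    diameter_law : ("lognormal", median_um, sigma); sigma = 0 is monodisperse.
    min_gap : minimum surface-to-surface separation between oocytes, μm; may
        be negative (overlap allowed) or -inf (hard core disabled).
    cortex_depth_um : nominal cortical depth used to convert parent_intensity
        to an expected parent count.
    seed : RNG seed; a fixed (spec, seed) is bit-reproducible.
    """

    dims: tuple[int, int, int] = (400, 600, 400)
    voxel_size: float = 2.28
    epithelium_model: str = "plane"
    depth_axis: str = "y"
    epithelium_thickness_um: float = 10.0
    cap_radius_um: float = 2000.0
    parent_intensity: float = 100.0
    mean_cluster_size: float = 8.0
    cluster_sd: float = 15.0
    depth_scatter_q: float = 0.05
    depth_law: tuple = ("lognormal", 200.0, 0.5)
    diameter_law: tuple = ("lognormal", 32.0, 0.1)
    min_gap: float = 0.0
    cortex_depth_um: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")
        if self.parent_intensity < 0:
            raise ValueError("parent_intensity must be >= 0")
        if self.mean_cluster_size < 1:
            raise ValueError("mean_cluster_size must be >= 1")
        if self.epithelium_model not in ("plane", "cap", "none"):
            raise ValueError(f"unknown epithelium model {self.epithelium_model!r}")
        if self.depth_axis not in ("z", "y"):
            raise ValueError(f"depth_axis must be 'z' or 'y', got {self.depth_axis!r}")
        if self.depth_law[0] not in ("lognormal", "exponential"):
            raise ValueError(f"unknown depth law {self.depth_law[0]!r}")
        if self.diameter_law[0] != "lognormal":
            raise ValueError(f"unknown diameter law {self.diameter_law[0]!r}")

    # -- geometry helpers -------------------------------------------------

    @property
    def n_epithelium_layers(self) -> int:
        if self.epithelium_model == "none":
            return 0
        return max(1, round(self.epithelium_thickness_um / self.voxel_size))

    @property
    def depth_origin_um(self) -> float:
        """z (resp. radial) coordinate of the innermost epithelium voxel centre.

        Depth is defined as distance to the nearest epithelium voxel centre,
        matching the Euclidean distance transform used downstream.
        """
        if self.epithelium_model == "none":
            return 0.0
        return (self.n_epithelium_layers - 1) * self.voxel_size

    @property
    def _axis_index(self) -> int:
        return 0 if self.depth_axis == "z" else 1

    def nominal_cortical_volume_mm3(self) -> float:
        """Lateral extent × min(cortex depth, available depth), in mm³."""
        v = self.voxel_size
        d = self._axis_index
        lat = [n for i, n in enumerate(self.dims) if i != d]
        depth_extent = max(self.dims[d] * v - self.depth_origin_um, 0.0)
        depth = min(self.cortex_depth_um, depth_extent)
        return (lat[0] * v) * (lat[1] * v) * depth * 1e-9

    def depth_ppf(self, u: np.ndarray) -> np.ndarray:
        if self.depth_law[0] == "lognormal":
            _, median, sigma = self.depth_law
            if sigma == 0:
                return np.full_like(np.asarray(u, float), median)
            return stats.lognorm.ppf(u, sigma, scale=median)
        _, scale = self.depth_law
        return stats.expon.ppf(u, scale=scale)

    def depth_cdf(self, x: np.ndarray) -> np.ndarray:
        if self.depth_law[0] == "lognormal":
            _, median, sigma = self.depth_law
            return stats.lognorm.cdf(x, sigma, scale=median)
        _, scale = self.depth_law
        return stats.expon.cdf(x, scale=scale)

    # -- (de)serialisation ------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        text = json.dumps(d, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PhantomSpec":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        for key in ("dims", "depth_law", "diameter_law"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """A generated phantom: label volume, masks, and the true oocyte table."""

    label_volume: LabeledVolume
    epithelium_mask: np.ndarray
    tissue_mask: np.ndarray
    oocytes: pd.DataFrame  # id, x_um, y_um, z_um, diameter_um, depth_um, parent_id
    spec: PhantomSpec


def _build_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Epithelium and tissue masks; built with the depth axis first, then
    moved back into (z, y, x) order."""
    d = spec._axis_index
    canon = (spec.dims[d],) + tuple(n for i, n in enumerate(spec.dims) if i != d)
    epi = np.zeros(canon, dtype=bool)
    if spec.epithelium_model == "plane":
        epi[: spec.n_epithelium_layers] = True
    elif spec.epithelium_model == "cap":
        v = spec.voxel_size
        R = spec.cap_radius_um
        c1, c2 = (canon[1] - 1) * v / 2.0, (canon[2] - 1) * v / 2.0
        dd = np.arange(canon[0])[:, None, None] * v + R  # centre at depth -R
        a1 = (np.arange(canon[1])[None, :, None] * v - c1) ** 2
        a2 = (np.arange(canon[2])[None, None, :] * v - c2) ** 2
        dist = np.sqrt(dd**2 + a1 + a2)
        T = spec.n_epithelium_layers * v
        epi = (dist >= R) & (dist < R + T)
    epi = np.moveaxis(epi, 0, d)
    return epi, ~epi


def _cap_coord_of_depth(spec: PhantomSpec, depth: float, rho2: float) -> float:
    """Depth-axis coordinate at a given depth below a spherical-cap surface."""
    R = spec.cap_radius_um
    r = R + spec.depth_origin_um + depth
    return -R + math.sqrt(max(r * r - rho2, 0.0))


def generate_phantom(spec: PhantomSpec) -> GroundTruth:
    """Generate a phantom volume with full ground truth.

    Oocyte centres follow the clustered process described in the module
    docstring; spheres are rasterised with the voxel-centre-in-sphere rule.
    Oocytes are kept fully inside the grid and (for ``min_gap >= 0``) clear of
    the epithelium.  Raises :class:`PackingInfeasibleError` if hard-core
    rejection exceeds a budget of 100 attempts per requested oocyte.
    """
    rng = np.random.default_rng(spec.seed)
    v = spec.voxel_size
    origin = spec.depth_origin_um
    d_ax = spec._axis_index
    lat_ax = [i for i in range(3) if i != d_ax]
    upper = tuple((n - 1) * v for n in spec.dims)

    # -- draw the cluster process ----------------------------------------
    vol = spec.nominal_cortical_volume_mm3()
    n_parents = rng.poisson(spec.parent_intensity * vol)
    # parents stay a median-radius margin away from the lateral faces so
    # boundary-stranded clusters cannot exhaust the rejection budget
    margin = spec.diameter_law[1] / 2.0 + max(spec.min_gap, 0.0)

    def _lat_band(axis: int) -> tuple[float, float]:
        extent = spec.dims[axis] * v
        return (margin, extent - margin) if extent > 2 * margin else (0.0, extent)

    parents_a = rng.uniform(*_lat_band(lat_ax[0]), n_parents)
    parents_b = rng.uniform(*_lat_band(lat_ax[1]), n_parents)
    parents_u = rng.uniform(0.0, 1.0, n_parents)
    n_offspring = rng.poisson(spec.mean_cluster_size, n_parents) if n_parents else np.array([], int)
    n_target = int(n_offspring.sum())

    law, dmed, dsig = spec.diameter_law

    def draw(parent: int) -> tuple[np.ndarray, float, float]:
        """One candidate oocyte for the given parent: ((z, y, x), D, depth)."""
        D = dmed * math.exp(dsig * rng.standard_normal()) if dsig > 0 else dmed
        a = parents_a[parent] + spec.cluster_sd * rng.standard_normal()
        b = parents_b[parent] + spec.cluster_sd * rng.standard_normal()
        u = (parents_u[parent] + spec.depth_scatter_q * rng.standard_normal()) % 1.0
        depth = float(spec.depth_ppf(u))
        if spec.epithelium_model == "cap":
            ca = upper[lat_ax[0]] / 2.0
            cb = upper[lat_ax[1]] / 2.0
            rho2 = (a - ca) ** 2 + (b - cb) ** 2
            coord = _cap_coord_of_depth(spec, depth, rho2)
        else:
            coord = origin + depth
        pos = np.empty(3)
        pos[d_ax] = coord
        pos[lat_ax[0]] = a
        pos[lat_ax[1]] = b
        return pos, D, depth

    def feasible(pos: np.ndarray, D: float, depth: float) -> bool:
        r = D / 2.0
        epi_clear = r + max(spec.min_gap, 0.0) + 1e-9
        if spec.epithelium_model != "none" and depth < epi_clear:
            return False
        return all(r <= pos[i] <= upper[i] - r for i in range(3))

    hard_core = np.isfinite(spec.min_gap)
    budget = max(100 * n_target, 1000)
    attempts = 0

    zs: list[float] = []
    ys: list[float] = []
    xs: list[float] = []
    ds: list[float] = []
    depths: list[float] = []
    parent_ids: list[int] = []

    centers = np.empty((n_target, 3))
    radii = np.empty(n_target)
    n_placed = 0
    for parent in range(n_parents):
        for _ in range(int(n_offspring[parent])):
            while True:
                attempts += 1
                if attempts > budget:
                    raise PackingInfeasibleError(
                        f"packing infeasible: {attempts - 1} attempts to place "
                        f"{n_target} oocytes (placed {n_placed}); lower the density, "
                        "cluster tightness, or min_gap"
                    )
                pos, D, depth = draw(parent)
                if not feasible(pos, D, depth):
                    continue
                if hard_core and n_placed:
                    c = centers[:n_placed]
                    min_d = radii[:n_placed] + D / 2.0 + spec.min_gap
                    diff = c - pos
                    if np.any(np.einsum("ij,ij->i", diff, diff) < min_d * min_d):
                        continue
                break
            centers[n_placed] = pos
            radii[n_placed] = D / 2.0
            n_placed += 1
            zs.append(pos[0])
            ys.append(pos[1])
            xs.append(pos[2])
            ds.append(D)
            depths.append(depth)
            parent_ids.append(parent)

    # -- rasterise --------------------------------------------------------
    n = n_placed
    dtype = np.uint16 if n < 2**16 else np.uint32
    grid = np.zeros(spec.dims, dtype=dtype)
    best = None
    if hard_core and spec.min_gap < 0 and n:
        best = np.full(spec.dims, np.inf, dtype=np.float32)
    if not hard_core and n:
        best = np.full(spec.dims, np.inf, dtype=np.float32)
    for i in range(n):
        z, y, x = centers[i]
        r = radii[i]
        lo = [max(int(math.floor((c - r) / v)), 0) for c in (z, y, x)]
        hi = [
            min(int(math.ceil((c + r) / v)) + 1, d)
            for c, d in zip((z, y, x), spec.dims)
        ]
        az = (np.arange(lo[0], hi[0]) * v - z)[:, None, None]
        ay = (np.arange(lo[1], hi[1]) * v - y)[None, :, None]
        ax = (np.arange(lo[2], hi[2]) * v - x)[None, None, :]
        d2 = az**2 + ay**2 + ax**2
        inside = d2 <= r * r
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        if best is None:
            grid[sub][inside] = i + 1
        else:
            win = inside & (d2 < best[sub])
            grid[sub][win] = i + 1
            b = best[sub]
            b[win] = d2[win].astype(np.float32)
            best[sub] = b

    epi, tissue = _build_masks(spec)
    if spec.epithelium_model != "none":
        # labels never encroach on the epithelium layer (rasterisation can
        # only touch it when min_gap < 0, where overlap is tolerated)
        if spec.min_gap >= 0:
            grid[epi] = 0

    oocytes = pd.DataFrame(
        {
            "id": np.arange(1, n + 1, dtype=int),
            "x_um": np.array(xs, float),
            "y_um": np.array(ys, float),
            "z_um": np.array(zs, float),
            "diameter_um": np.array(ds, float),
            "depth_um": np.array(depths, float),
            "parent_id": np.array(parent_ids, int),
        }
    )
    if n == 0:
        oocytes = empty_oocyte_table().assign(depth_um=pd.Series(dtype=float), parent_id=pd.Series(dtype=int))
    return GroundTruth(
        label_volume=LabeledVolume(grid=grid, voxel_size=v),
        epithelium_mask=epi,
        tissue_mask=tissue,
        oocytes=oocytes,
        spec=spec,
    )


def true_geometry(truth: GroundTruth, cortex_depth: float = 1000.0):
    """Analytic cortex geometry for a planar-epithelium phantom.

    For the "plane" surface model the Euclidean distance field has the closed
    form ``max(j - (n_e - 1), 0) * voxel_size`` along the depth axis (j the
    voxel index, n_e the number of epithelium layers), so the geometry can be
    produced without running the distance transform.  Identical to
    :func:`oomorph.morpho3d.build_cortex` output for these phantoms.
    """
    from .morpho3d import CortexGeometry  # local import to avoid a cycle

    spec = truth.spec
    if spec.epithelium_model != "plane":
        raise ValueError("true_geometry is only defined for planar epithelium phantoms")
    v = spec.voxel_size
    d_ax = spec._axis_index
    n = spec.dims[d_ax]
    line = np.maximum(np.arange(n) - (spec.n_epithelium_layers - 1), 0) * v
    shape = [1, 1, 1]
    shape[d_ax] = n
    dist = np.broadcast_to(
        line.reshape(shape).astype(np.float32), spec.dims
    ).copy()
    cortex = truth.tissue_mask & (dist <= cortex_depth)
    volume = float(np.count_nonzero(cortex)) * v**3 * 1e-9
    return CortexGeometry(
        distance_field=dist,
        cortex_mask=cortex,
        cortex_depth=float(cortex_depth),
        cortical_volume_mm3=volume,
        voxel_size=v,
    )


# ---------------------------------------------------------------------------
# Calibrated presets


def preset(regime: str, seed: int = 0) -> PhantomSpec:
    """A calibrated phantom spec for a tissue regime.

    ``"pediatric"``: dense, shallow, strongly clustered cortex whose
    population median depth ≈ 139 μm and median 40-μm neighbour count ≈ 6.
    ``"adult"``: sparse, deep, mildly clustered cortex with median depth
    ≈ 370 μm and median neighbour count ≈ 2.  Densities differ by ~8×.

    The grids measure ≈ 0.78 × 0.78 × 1.09 mm at 2.28 μm voxels, large enough
    to contain the full 1-mm cortical shell.
    """
    if regime == "pediatric":
        return PhantomSpec(
            dims=(340, 480, 340),
            voxel_size=2.28,
            parent_intensity=250.0,
            mean_cluster_size=8.0,
            cluster_sd=15.0,
            depth_scatter_q=0.035,
            depth_law=("lognormal", 139.4, 0.55),
            diameter_law=("lognormal", 32.0, 0.08),
            min_gap=-16.0,
            seed=seed,
        )
    if regime == "adult":
        return PhantomSpec(
            dims=(340, 480, 340),
            voxel_size=2.28,
            parent_intensity=42.0,
            mean_cluster_size=6.0,
            cluster_sd=16.0,
            depth_scatter_q=0.035,
            depth_law=("lognormal", 370.0, 0.60),
            diameter_law=("lognormal", 32.0, 0.08),
            min_gap=-14.0,
            seed=seed,
        )
    raise ValueError(f"unknown regime {regime!r}; expected 'pediatric' or 'adult'")


def render_intensity(
    truth: GroundTruth,
    contrast: tuple[float, float, float] = (40.0, 120.0, 200.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a grey-level volume from a phantom.

    ``contrast`` = (oocyte, background, epithelium) grey levels, which must be
    ordered oocyte < background < epithelium (oocytes are hypodense, the
    epithelium hyperdense).  Additive Gaussian noise with ``noise_sd`` is
    applied voxelwise; deterministic under a fixed seed.
    """
    g_oo, g_bg, g_epi = contrast
    if not (g_oo < g_bg < g_epi):
        raise ValueError(f"contrast must satisfy oocyte < background < epithelium, got {contrast}")
    out = np.full(truth.label_volume.shape, g_bg, dtype=np.float32)
    out[truth.label_volume.grid > 0] = g_oo
    out[truth.epithelium_mask] = g_epi
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out += rng.normal(0.0, noise_sd, out.shape).astype(np.float32)
    return out
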