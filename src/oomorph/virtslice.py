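"""Virtual histology: sectioning simulation and corrected density estimation.

A known 3D oocyte population (spheres: centre + diameter) is cut into
half-open slabs of thickness ``t`` along the z axis, section ``s`` covering
``[(s-1)·t, s·t)`` with 1-based physical numbering.  Every analyzed section
records one profile per intersecting oocyte — the largest circle of the
sphere inside the slab — provided that chord is at least the visibility
floor (tiny polar caps are undetectable in real slides).

Density is then estimated as in standard follicle histomorphometry with an
Abercrombie/Schmidt-type duplicate-count correction:

    N̂ = P · k · t / (t + D̄),        density = N̂ / V_ext,

where ``P`` is the total profile count over analyzed sections, ``k`` the
sectioning interval (every k-th section analyzed), ``D̄`` the mean diameter of
the largest 10 % of sectioned oocytes (per-oocyte maximum profile diameter,
deduplicated across sections), and ``V_ext = ΣA_i · k · t`` the examined
cortical volume extrapolated per analyzed section.  The uncorrected density
``P / (ΣA_i · t)`` counts each oocyte once per section it spans, inflating
density by roughly ``(D + t)/t``.

Sweep helpers quantify how the sampling design (section interval, number of
sections, starting offset) biases the estimate relative to the full-volume
3D density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .morpho3d import CortexGeometry, count_in_cortex, density_3d

__all__ = [
    "SectioningDesign",
    "SectionProfileSet",
    "HistologyEstimate",
    "make_profiles",
    "estimate_density",
    "offset_sweep",
    "interval_sweep",
    "max_stable_interval",
    "compare_strategies",
]


@dataclass(frozen=True)
class SectioningDesign:
    """A histological sampling design.

    thickness: section thickness t in μm (default 4, as in routine
        paraffin histology).
    interval: analyse every k-th section (default 10, i.e. 40 μm apart).
    start: 1-based physical index of the first analyzed section.
    n_analyzed: number of analyzed sections, or None for all feasible.
    axis: sectioning axis (only "z" is supported).
    """

    thickness: float = 4.0
    interval: int = 10
    start: int = 10
    n_analyzed: int | None = None
    axis: str = "z"

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("thickness must be > 0")
        if self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.start < 1:
            raise ValueError("start must be >= 1 (sections are 1-based)")
        if self.n_analyzed is not None and self.n_analyzed < 1:
            raise ValueError("n_analyzed must be >= 1 or None")
        if self.axis != "z":
            raise ValueError("only z-axis sectioning is supported")

    @property
    def spacing_um(self) -> float:
        """Physical spacing between analyzed sections: interval × thickness."""
        return self.interval * self.thickness

    @staticmethod
    def clinical_five_sections(thickness: float = 4.0) -> "SectioningDesign":
        """The limited clinical design: sections 10, 20, 30, 40 and 50."""
        return SectioningDesign(thickness=thickness, interval=10, start=10, n_analyzed=5)


@dataclass
class SectionProfileSet:
    """Profiles observed on the analyzed sections of one design.

    ``profiles`` has one row per (section, oocyte) incidence with the profile
    diameter; ``sections`` one row per analyzed section with slab bounds and
    the cortical slab area in mm².
    """

    profiles: pd.DataFrame  # section, oocyte_id, profile_diameter_um
    sections: pd.DataFrame  # section, z0_um, z1_um, area_mm2
    design: SectioningDesign
    visibility_floor: float  # μm


@dataclass
class HistologyEstimate:
    """Raw and corrected counts/densities from one sectioning design."""

    p_profiles: int
    d_bar_um: float | None  # mean of largest 10 % oocyte profile diameters
    n_hat: float  # corrected extrapolated oocyte count
    v_ext_mm3: float  # extrapolated examined cortical volume
    density_corrected: float  # per mm³
    density_uncorrected: float  # per mm³
    design: SectioningDesign


def _n_sections_total(geom: CortexGeometry, thickness: float) -> int:
    extent_um = geom.cortex_mask.shape[0] * geom.voxel_size
    return int(math.floor(extent_um / thickness))


def _slab_area_mm2(geom: CortexGeometry, z0: float, z1: float) -> float:
    """Cortical area of the slab [z0, z1) from the 3D cortex mask.

    The slab volume is accumulated from per-layer cortex voxel counts with
    fractional overlap of boundary voxel layers, then divided by the slab
    thickness.  Voxel layer j spans [j·v, (j+1)·v) μm.
    """
    counts = geom.cortex_layer_counts()
    v = geom.voxel_size
    j0 = max(int(math.floor(z0 / v)), 0)
    j1 = min(int(math.ceil(z1 / v)), len(counts))
    vol_um3 = 0.0
    for j in range(j0, j1):
        overlap = min(z1, (j + 1) * v) - max(z0, j * v)
        if overlap > 0:
            vol_um3 += counts[j] * overlap * v * v
    return vol_um3 / (z1 - z0) * 1e-6


def analyzed_sections(
    geom: CortexGeometry, design: SectioningDesign
) -> np.ndarray:
    """1-based indices of the analyzed sections for a design."""
    total = _n_sections_total(geom, design.thickness)
    if design.start > total:
        raise ValueError(
            f"design start {design.start} is beyond the sample extent "
            f"({total} sections available at t={design.thickness} μm)"
        )
    idx = np.arange(design.start, total + 1, design.interval)
    if design.n_analyzed is not None:
        if len(idx) < design.n_analyzed:
            raise ValueError(
                f"design requires {design.n_analyzed} sections but only "
                f"{len(idx)} fit (total {total} sections at t={design.thickness} μm)"
            )
        idx = idx[: design.n_analyzed]
    return idx


def make_profiles(
    oocytes: pd.DataFrame,
    geom: CortexGeometry,
    design: SectioningDesign,
    visibility_floor: float = 5.0,
) -> SectionProfileSet:
    """Cut the spherical oocyte population into the design's virtual sections.

    An oocyte appears in a section iff its sphere intersects the slab with an
    in-slab maximal chord ≥ ``visibility_floor``.  The profile diameter is the
    true diameter when the equator lies inside the slab, otherwise
    ``2·sqrt((D/2)² − δ²)`` with δ the distance from the centre to the nearest
    slab face.  Boundary-grazing spheres (zero chord) never produce profiles,
    so no oocyte is counted twice at a slab boundary.
    """
    t = design.thickness
    secs = analyzed_sections(geom, design)
    z = oocytes["z_um"].to_numpy(float) if len(oocytes) else np.empty(0)
    r = oocytes["diameter_um"].to_numpy(float) / 2.0 if len(oocytes) else np.empty(0)
    ids = oocytes["id"].to_numpy() if len(oocytes) else np.empty(0, int)

    rows_sec: list[np.ndarray] = []
    rows_id: list[np.ndarray] = []
    rows_d: list[np.ndarray] = []
    sec_meta = []
    for s in secs:
        z0, z1 = (s - 1) * t, s * t
        sec_meta.append((int(s), z0, z1, _slab_area_mm2(geom, z0, z1)))
        if not len(z):
            continue
        # distance from centre to the slab, 0 if the equator is inside
        delta = np.maximum(np.maximum(z0 - z, z - z1), 0.0)
        chord2 = r * r - delta * delta
        hit = chord2 > 0
        # centres exactly on the open face (z == z1) belong to the next slab,
        # but their chord here is < D, handled by the delta formula already
        diam = 2.0 * np.sqrt(np.where(hit, chord2, 0.0))
        vis = hit & (diam >= visibility_floor)
        if vis.any():
            rows_sec.append(np.full(int(vis.sum()), s, dtype=int))
            rows_id.append(ids[vis])
            rows_d.append(diam[vis])

    profiles = pd.DataFrame(
        {
            "section": np.concatenate(rows_sec) if rows_sec else np.empty(0, int),
            "oocyte_id": np.concatenate(rows_id) if rows_id else np.empty(0, int),
            "profile_diameter_um": np.concatenate(rows_d) if rows_d else np.empty(0),
        }
    )
    sections = pd.DataFrame(sec_meta, columns=["section", "z0_um", "z1_um", "area_mm2"])
    return SectionProfileSet(
        profiles=profiles, sections=sections, design=design, visibility_floor=visibility_floor
    )


def estimate_density(
    profiles: SectionProfileSet, design: SectioningDesign | None = None
) -> HistologyEstimate:
    """Apply the duplicate-count correction to a profile set.

    D̄ is the mean of the largest 10 % (ceil(0.1·n), at least 1) of per-oocyte
    maximum profile diameters among analyzed sections.  Zero profiles yields
    zero densities with D̄ absent.  Zero total cortical area is an error.
    """
    design = design or profiles.design
    t = design.thickness
    k = design.interval
    area_mm2 = float(profiles.sections["area_mm2"].sum())
    if area_mm2 <= 0:
        raise ValueError("total cortical section area is zero; density undefined")
    examined_mm3 = area_mm2 * t * 1e-3
    v_ext = examined_mm3 * k
    p = int(len(profiles.profiles))
    if p == 0:
        return HistologyEstimate(
            p_profiles=0,
            d_bar_um=None,
            n_hat=0.0,
            v_ext_mm3=v_ext,
            density_corrected=0.0,
            density_uncorrected=0.0,
            design=design,
        )
    per_oocyte = profiles.profiles.groupby("oocyte_id")["profile_diameter_um"].max()
    m = max(1, math.ceil(0.1 * len(per_oocyte)))
    d_bar = float(per_oocyte.nlargest(m).mean())
    n_hat = p * k * t / (t + d_bar)
    density_uncorrected = p / examined_mm3
    density_corrected = n_hat / v_ext
    return HistologyEstimate(
        p_profiles=p,
        d_bar_um=d_bar,
        n_hat=n_hat,
        v_ext_mm3=v_ext,
        density_corrected=density_corrected,
        density_uncorrected=density_uncorrected,
        design=design,
    )


def offset_sweep(
    oocytes: pd.DataFrame,
    geom: CortexGeometry,
    thickness: float = 4.0,
    interval: int = 10,
    n_analyzed: int = 5,
    visibility_floor: float = 5.0,
) -> tuple[list[HistologyEstimate], dict]:
    """Estimate density for every feasible starting section of a limited design.

    Returns the per-start estimates plus a summary (min, max, median, CV of
    the corrected density).  CV is the population std over the mean (0 when
    only one start is feasible or the mean is 0).
    """
    total = _n_sections_total(geom, thickness)
    last_start = total - (n_analyzed - 1) * interval
    estimates: list[HistologyEstimate] = []
    for start in range(1, max(last_start, 0) + 1):
        design = SectioningDesign(
            thickness=thickness, interval=interval, start=start, n_analyzed=n_analyzed
        )
        estimates.append(
            estimate_density(make_profiles(oocytes, geom, design, visibility_floor))
        )
    dens = np.array([e.density_corrected for e in estimates])
    if len(dens) == 0:
        summary = {"n_starts": 0, "min": 0.0, "max": 0.0, "median": 0.0, "cv": 0.0}
    else:
        mean = float(dens.mean())
        cv = float(dens.std() / mean) if mean > 0 and len(dens) > 1 else 0.0
        summary = {
            "n_starts": len(dens),
            "min": float(dens.min()),
            "max": float(dens.max()),
            "median": float(np.median(dens)),
            "cv": cv,
        }
    return estimates, summary


def interval_sweep(
    oocytes: pd.DataFrame,
    geom: CortexGeometry,
    thickness: float = 4.0,
    k_range: range | list[int] = range(1, 11),
    visibility_floor: float = 5.0,
) -> pd.DataFrame:
    """Corrected density across sectioning intervals (all feasible sections).

    At interval k the analyzed sections are k, 2k, 3k, … ("every k-th
    section").  Returns a table (k, density_corrected, density_uncorrected,
    p_profiles, n_sections).
    """
    rows = []
    for k in k_range:
        design = SectioningDesign(thickness=thickness, interval=int(k), start=int(k), n_analyzed=None)
        profset = make_profiles(oocytes, geom, design, visibility_floor)
        est = estimate_density(profset)
        rows.append(
            {
                "k": int(k),
                "density_corrected": est.density_corrected,
                "density_uncorrected": est.density_uncorrected,
                "p_profiles": est.p_profiles,
                "n_sections": int(len(profset.sections)),
            }
        )
    return pd.DataFrame(rows)


def max_stable_interval(sweep: pd.DataFrame, tol: float = 0.20) -> int:
    """Largest k such that every interval 1..k stays within ``tol`` of k = 1.

    The sweep table must contain k = 1.  Relative deviation is measured
    against the k = 1 (all-sections) corrected density.
    """
    sweep = sweep.sort_values("k")
    if 1 not in set(sweep["k"]):
        raise ValueError("sweep must include k = 1 as the reference")
    ref = float(sweep.loc[sweep["k"] == 1, "density_corrected"].iloc[0])
    if ref == 0:
        raise ValueError("k = 1 corrected density is zero; stability undefined")
    best = 0
    expected = 1
    for _, row in sweep.iterrows():
        if int(row["k"]) != expected:
            break
        if abs(row["density_corrected"] - ref) / ref <= tol:
            best = expected
            expected += 1
        else:
            break
    return best


def compare_strategies(
    oocytes: pd.DataFrame,
    geom: CortexGeometry,
    thickness: float = 4.0,
    interval: int = 10,
    visibility_floor: float = 5.0,
) -> dict:
    """Full-volume 3D density vs the two simulated-histology strategies.

    Returns the 3D cortical density, the every-k-th full-sample estimate,
    the limited five-section estimate (sections 10, 20, 30, 40, 50), and the
    relative error of each histology strategy against the 3D density
    (0 when the 3D density is 0).
    """
    d3 = density_3d(oocytes, geom)
    full = estimate_density(
        make_profiles(
            oocytes,
            geom,
            SectioningDesign(thickness=thickness, interval=interval, start=interval),
            visibility_floor,
        )
    )
    five = estimate_density(
        make_profiles(
            oocytes,
            geom,
            SectioningDesign.clinical_five_sections(thickness),
            visibility_floor,
        )
    )

    def rel(est: HistologyEstimate) -> float:
        if d3 == 0:
            return 0.0
        return (est.density_corrected - d3) / d3

    return {
        "density_3d": d3,
        "density_every10th_full": full.density_corrected,
        "density_five_sections": five.density_corrected,
        "rel_err_every10th_full": rel(full),
        "rel_err_five_sections": rel(five),
        "n_oocytes_cortex": count_in_cortex(oocytes, geom),
    }
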