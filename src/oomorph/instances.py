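"""Instance extraction from binary oocyte masks, and segmentation scoring.

This is the automated counterpart of the interactive clean-up that a 3D
image-analysis suite would perform on a raw segmentation: elongated
components (blood vessels) and sub-resolution specks (noise) are removed,
and merged oocytes are separated by marker-controlled watershed on the
Euclidean distance transform.  A deterministic threshold segmenter is
provided so rendered phantoms can be pushed through the full pipeline.

Vessel and noise filters run on the raw connected components *before* the
watershed split: splitting first would fragment a tube into compact chunks
that no longer look elongated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .volio import LabeledVolume, empty_oocyte_table

__all__ = [
    "InstanceParams",
    "SegScores",
    "threshold_segment",
    "extract_instances",
    "segmentation_scores",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

#: Noise floor: volume of a 10-μm sphere, below the smallest plausible oocyte.
DEFAULT_MIN_VOLUME = 4.0 / 3.0 * math.pi * 5.0**3  # ≈ 524 μm³


@dataclass(frozen=True)
class InstanceParams:
    """Post-processing thresholds for instance extraction.

    connectivity: voxel connectivity for components (6, 18 or 26).
    min_volume: μm³; smaller components are discarded as noise.
    split_min_distance: μm; minimum separation of watershed markers (distance-
        transform maxima); ``inf`` disables splitting.
    vessel_elongation: major/minor principal-axis length ratio above which a
        component is discarded as a vessel.
    erode_voxels: optional isotropic erosion of the mask before labelling
        (mirrors the deliberate one-voxel shrinkage some pipelines apply to
        keep touching oocytes apart; 0 = off).
    """

    connectivity: int = 26
    min_volume: float = DEFAULT_MIN_VOLUME
    split_min_distance: float = 15.0
    vessel_elongation: float = 4.0
    erode_voxels: int = 0

    def __post_init__(self) -> None:
        if self.connectivity not in _STRUCTURES:
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.min_volume < 0:
            raise ValueError("min_volume must be >= 0")
        if not self.split_min_distance > 0:
            raise ValueError("split_min_distance must be > 0")
        if not self.vessel_elongation > 1:
            raise ValueError("vessel_elongation must be > 1")


@dataclass(frozen=True)
class SegScores:
    """Voxelwise overlap scores between a predicted and a true mask."""

    dice: float
    precision: float
    recall: float


def threshold_segment(
    intensity: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    epithelium_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Segment dark (hypodense) objects by global thresholding.

    Voxels strictly below the threshold are foreground.  If an epithelium
    mask is given, those voxels are excluded both from the threshold
    computation and from the output.  ``method="otsu"`` derives the threshold
    from the intensity histogram; ``method="fixed"`` uses ``threshold``.
    A constant image under Otsu raises a degenerate-histogram error.
    """
    intensity = np.asarray(intensity)
    sel = np.ones(intensity.shape, bool)
    if epithelium_mask is not None:
        sel &= ~np.asarray(epithelium_mask, bool)
    if method == "otsu":
        values = intensity[sel]
        if values.size == 0 or values.min() == values.max():
            raise ValueError(
                "degenerate histogram: image is constant, Otsu threshold undefined"
            )
        thr = float(threshold_otsu(values))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires an explicit threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return (intensity < thr) & sel


def _elongation(coords_um: np.ndarray) -> float:
    """Major/minor principal-axis length ratio of a voxel point cloud."""
    if len(coords_um) < 2:
        return 1.0
    c = coords_um - coords_um.mean(axis=0)
    cov = c.T @ c / len(c)
    eig = np.linalg.eigvalsh(cov)
    # half a voxel of spread accounts for degenerate (flat) distributions
    lo = math.sqrt(max(eig[0], 1e-12))
    hi = math.sqrt(max(eig[-1], 1e-12))
    if lo == 0:
        return math.inf
    return hi / lo


def _watershed_markers(
    edt: np.ndarray, labels: np.ndarray, voxel_size: float, min_distance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic marker selection: EDT local maxima, greedily accepted in
    order of (−EDT, flat index), keeping ≥ ``min_distance`` μm spacing within
    each component.  Returns (marker volume, per-marker component label)."""
    footprint = np.ones((3, 3, 3), bool)
    local_max = (edt == ndimage.maximum_filter(edt, footprint=footprint)) & (labels > 0)
    cand = np.argwhere(local_max)
    if not len(cand):
        return np.zeros_like(labels, dtype=np.int32), np.array([], int)
    values = edt[tuple(cand.T)]
    comp = labels[tuple(cand.T)]
    flat = np.ravel_multi_index(tuple(cand.T), labels.shape)
    order = np.lexsort((flat, -values))
    cand, comp = cand[order], comp[order]
    markers = np.zeros_like(labels, dtype=np.int32)
    marker_comp: list[int] = []
    accepted: dict[int, list[np.ndarray]] = {}
    min_vox = min_distance / voxel_size
    next_id = 0
    for pt, c in zip(cand, comp):
        prev = accepted.setdefault(int(c), [])
        if prev:
            d = np.linalg.norm(np.array(prev) - pt, axis=1)
            if np.any(d < min_vox):
                continue
        prev.append(pt)
        next_id += 1
        markers[tuple(pt)] = next_id
        marker_comp.append(int(c))
    return markers, np.array(marker_comp, int)


def extract_instances(
    mask: np.ndarray, params: InstanceParams, voxel_size: float
) -> tuple[LabeledVolume, pd.DataFrame]:
    """Turn a binary oocyte mask into clean labeled instances plus a table.

    Steps: optional erosion → connected components → noise filter
    (``min_volume``) → vessel filter (``vessel_elongation``) → watershed split
    of components holding ≥ 2 distance-transform maxima separated by
    ``split_min_distance`` → relabel 1..n and tabulate centroid (μm),
    volume (μm³) and equivalent sphere diameter.  An empty mask yields an
    empty table.
    """
    mask = np.asarray(mask, bool)
    if params.erode_voxels > 0:
        mask = ndimage.binary_erosion(
            mask, structure=_STRUCTURES[6], iterations=params.erode_voxels
        )
    structure = _STRUCTURES[params.connectivity]
    labels, n = ndimage.label(mask, structure=structure)
    voxel_vol = voxel_size**3
    if n:
        counts = np.bincount(labels.ravel())[1:]
        keep = counts * voxel_vol >= params.min_volume
        if math.isfinite(params.vessel_elongation):
            objects = ndimage.find_objects(labels)
            for lab in np.nonzero(keep)[0] + 1:
                sl = objects[lab - 1]
                coords = np.argwhere(labels[sl] == lab) * voxel_size
                if _elongation(coords) > params.vessel_elongation:
                    keep[lab - 1] = False
        if not keep.all():
            remap = np.zeros(n + 1, dtype=labels.dtype)
            remap[1:][keep] = np.arange(1, keep.sum() + 1)
            labels = remap[labels]
            n = int(keep.sum())

    if n and math.isfinite(params.split_min_distance):
        fg = labels > 0
        edt = ndimage.distance_transform_edt(fg, sampling=voxel_size)
        markers, marker_comp = _watershed_markers(
            edt, labels, voxel_size, params.split_min_distance
        )
        multi = np.flatnonzero(np.bincount(marker_comp, minlength=1) > 1) if len(marker_comp) else []
        if len(multi):
            split = watershed(-edt, markers, mask=fg)
            # keep unsplit components as they are; renumber split pieces after
            multi_set = set(int(m) for m in multi)
            out = labels.astype(np.int32).copy()
            sel = np.isin(labels, list(multi_set))
            out[sel] = split[sel] + n  # temporary offset, relabelled below
            labels = out
        del edt

    # final compaction to labels 1..n
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    labels = remap[labels]
    n = len(present)

    if n == 0:
        table = empty_oocyte_table().assign(volume_um3=pd.Series(dtype=float))
        return LabeledVolume(grid=labels, voxel_size=voxel_size), table

    idx = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    centroids = np.array(ndimage.center_of_mass(labels > 0, labels, idx))
    volumes = counts * voxel_vol
    diameters = (6.0 * volumes / math.pi) ** (1.0 / 3.0)
    table = pd.DataFrame(
        {
            "id": idx,
            "x_um": centroids[:, 2] * voxel_size,
            "y_um": centroids[:, 1] * voxel_size,
            "z_um": centroids[:, 0] * voxel_size,
            "diameter_um": diameters,
            "volume_um3": volumes,
        }
    )
    dtype = np.uint16 if n < 2**16 else np.uint32
    return LabeledVolume(grid=labels.astype(dtype), voxel_size=voxel_size), table


def segmentation_scores(predicted: np.ndarray, truth: np.ndarray) -> SegScores:
    """Dice, precision and recall between binary masks.

    precision = |P∩T| / |P|, recall = |P∩T| / |T|, dice = 2|P∩T| / (|P|+|T|).
    Both masks empty returns all 1.0 by convention.
    """
    predicted = np.asarray(predicted, bool)
    truth = np.asarray(truth, bool)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    p = int(predicted.sum())
    t = int(truth.sum())
    inter = int((predicted & truth).sum())
    if p == 0 and t == 0:
        return SegScores(dice=1.0, precision=1.0, recall=1.0)
    precision = inter / p if p else 0.0
    recall = inter / t if t else 0.0
    dice = 2.0 * inter / (p + t)
    return SegScores(dice=dice, precision=precision, recall=recall)
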