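"""Volume and table I/O with strict unit metadata.

All lengths are micrometres (μm) internally; densities are converted to
per-mm³ only at the reporting edge.  Volumes are stored with axis order
``(z, y, x)`` where ``z`` is the sectioning axis; the physical coordinate of
voxel index ``i`` along an axis is ``i * voxel_size`` (voxel-centre
convention, 0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LabeledVolume",
    "SchemaError",
    "VolumeFormatError",
    "REQUIRED_TABLE_COLUMNS",
    "read_volume",
    "write_volume",
    "read_table",
    "write_table",
    "validate_oocyte_table",
]

#: Mandatory columns of an oocyte table (all lengths in μm).
REQUIRED_TABLE_COLUMNS = ("id", "x_um", "y_um", "z_um", "diameter_um")

#: Recognised optional columns; unknown extra columns are preserved verbatim.
OPTIONAL_TABLE_COLUMNS = ("volume_um3", "depth_um", "neighbor_count", "parent_id")


class VolumeFormatError(ValueError):
    """Raised when a volume file violates the label-volume contract."""


class SchemaError(ValueError):
    """Raised when an oocyte table is missing mandatory columns."""


@dataclass
class LabeledVolume:
    """A 3D integer grid of instance labels with isotropic voxel size.

    Label 0 is background; positive labels are instances.  Labels need not be
    contiguous.  ``grid`` has axis order (z, y, x) with z the sectioning axis.
    """

    grid: np.ndarray
    voxel_size: float  # μm, isotropic

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise VolumeFormatError(f"expected a 3D grid, got ndim={self.grid.ndim}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise VolumeFormatError(
                f"label volumes must be integer-typed, got dtype {self.grid.dtype}"
            )
        if not self.voxel_size > 0:
            raise VolumeFormatError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        """Sorted array of instance labels present (0 excluded)."""
        u = np.unique(self.grid)
        return u[u > 0]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise VolumeFormatError(f"cannot infer volume format from {path.name!r}")


def read_volume(
    path: str | Path, format: str | None = None, voxel_size: float | None = None
) -> LabeledVolume:
    """Read a label volume from a multi-page TIFF stack or NIfTI-1 file.

    For TIFF the voxel size comes from a sidecar JSON ``<file>.json`` holding
    ``{"voxel_size_um": float}``, or from the explicit ``voxel_size`` argument;
    absence of both is an error.  For NIfTI it comes from the header zooms
    (which must be isotropic) unless overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "tiff_stack":
        grid = tifffile.imread(path)
        if voxel_size is None:
            sidecar = _sidecar_path(path)
            if sidecar.exists():
                voxel_size = float(json.loads(sidecar.read_text())["voxel_size_um"])
            else:
                raise VolumeFormatError(
                    f"{path} carries no voxel-size metadata (no sidecar "
                    f"{sidecar.name}); pass voxel_size explicitly"
                )
    elif fmt == "nifti":
        img = nib.load(str(path))
        # stored (x, y, z) on disk; internal order is (z, y, x)
        data = np.asanyarray(img.dataobj)
        grid = np.ascontiguousarray(data.transpose(2, 1, 0))
        if voxel_size is None:
            zooms = img.header.get_zooms()[:3]
            if not np.allclose(zooms, zooms[0], rtol=1e-6):
                raise VolumeFormatError(f"anisotropic NIfTI zooms {zooms} unsupported")
            voxel_size = float(zooms[0])
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")
    if not np.issubdtype(grid.dtype, np.integer):
        raise VolumeFormatError(
            f"label file {path} has float dtype {grid.dtype}; label volumes "
            "must be integer-typed"
        )
    return LabeledVolume(grid=grid, voxel_size=float(voxel_size))


def write_volume(vol: LabeledVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a label volume losslessly; TIFF gets a voxel-size JSON sidecar."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tiff_stack":
        tifffile.imwrite(path, vol.grid)
        _sidecar_path(path).write_text(
            json.dumps({"voxel_size_um": vol.voxel_size}) + "\n"
        )
    elif fmt == "nifti":
        affine = np.diag([vol.voxel_size, vol.voxel_size, vol.voxel_size, 1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(vol.grid.transpose(2, 1, 0)), affine)
        img.header.set_zooms((vol.voxel_size,) * 3)
        nib.save(img, str(path))
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")
    return path


def validate_oocyte_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an oocyte table against the column schema.

    Required: id, x_um, y_um, z_um, diameter_um.  Optional columns
    (volume_um3, depth_um, neighbor_count, parent_id) and any unknown extra
    columns pass through untouched.
    """
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"oocyte table is missing required column(s): {missing}")
    if len(df):
        if df["id"].duplicated().any():
            raise SchemaError("oocyte ids must be unique")
        if not (df["diameter_um"] > 0).all():
            raise SchemaError("diameters must be > 0")
        if "depth_um" in df.columns:
            depths = df["depth_um"].dropna()
            if len(depths) and not (depths >= 0).all():
                raise SchemaError("depth_um must be >= 0 where present")
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Read an oocyte table from CSV (header mandatory) and validate it."""
    df = pd.read_csv(path)
    return validate_oocyte_table(df)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated oocyte table as RFC-4180 CSV with header."""
    validate_oocyte_table(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def empty_oocyte_table() -> pd.DataFrame:
    """An empty table with the mandatory schema columns."""
    return pd.DataFrame(
        {
            "id": pd.Series(dtype=int),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "z_um": pd.Series(dtype=float),
            "diameter_um": pd.Series(dtype=float),
        }
    )
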