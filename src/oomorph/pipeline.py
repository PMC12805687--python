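"""End-to-end orchestration: phantom/load → instances → morphometrics → virtual histology.

``run_pipeline`` executes the whole analysis from a single YAML/JSON config
and writes a reproducible report bundle (CSV tables, a JSON summary and a
plain-text log).  The same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .instances import InstanceParams, extract_instances, threshold_segment
from .morpho3d import (
    CortexGeometry,
    build_cortex,
    cluster_flags,
    density_3d,
    neighbor_counts,
    oocyte_depths,
)
from .phantom import PhantomSpec, generate_phantom, preset, render_intensity
from .virtslice import SectioningDesign, compare_strategies, estimate_density, make_profiles
from .volio import LabeledVolume, read_volume, write_table

__all__ = ["PipelineStageError", "run_pipeline", "tissue_geometry"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def tissue_geometry(tissue_mask: np.ndarray, voxel_size: float) -> CortexGeometry:
    """Fallback geometry for samples without a visible epithelium.

    The whole tissue mask stands in for the cortex; the distance field is
    undefined (all zero) so depth analyses must be skipped.
    """
    tissue_mask = np.asarray(tissue_mask, bool)
    volume = float(np.count_nonzero(tissue_mask)) * voxel_size**3 * 1e-9
    return CortexGeometry(
        distance_field=np.zeros(tissue_mask.shape, np.float32),
        cortex_mask=tissue_mask,
        cortex_depth=float("inf"),
        cortical_volume_mm3=volume,
        voxel_size=float(voxel_size),
    )


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        return yaml.safe_load(text)
    return dict(config)


def _phantom_spec_from_config(cfg: dict, seed: int) -> PhantomSpec:
    if "preset" in cfg:
        spec = preset(cfg["preset"], seed=seed)
    else:
        spec = PhantomSpec(seed=seed)
    overrides = dict(cfg.get("overrides", {}))
    for key in ("dims", "depth_law", "diameter_law"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    if overrides:
        spec = replace(spec, **overrides)
    return spec


def run_pipeline(config, output_dir: str | Path | None = None) -> dict:
    """Run the full analysis described by a config mapping or YAML/JSON file.

    Returns the report dictionary; when an output directory is configured the
    bundle (oocytes.csv, sections.csv, summary.json, run.log) is written
    there.  Stage failures raise :class:`PipelineStageError` naming the
    stage, after flushing partial outputs with a failure marker.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(output_dir or cfg.get("output_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("oomorph.pipeline")
    log_lines: list[str] = [f"oomorph {__version__} | seed={seed}"]

    def note(msg: str) -> None:
        log.info(msg)
        log_lines.append(msg)

    def fail(stage: str, exc: BaseException):
        (out_dir / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineStageError(stage, exc) from exc

    report: dict = {"seed": seed, "version": __version__}

    # -- stage: input -----------------------------------------------------
    stage = "input"
    try:
        if "phantom" in cfg:
            spec = _phantom_spec_from_config(cfg["phantom"], seed)
            truth = generate_phantom(spec)
            labels, oocytes = truth.label_volume, truth.oocytes
            epithelium, tissue = truth.epithelium_mask, truth.tissue_mask
            note(f"phantom: {len(oocytes)} oocytes, dims={spec.dims}")
            report["phantom_spec"] = json.loads(spec.to_json())
        elif "input" in cfg:
            icfg = cfg["input"]
            vs = icfg.get("voxel_size_um")
            labels = read_volume(icfg["labels"], voxel_size=vs)
            epithelium = (
                read_volume(icfg["epithelium"], voxel_size=vs).grid.astype(bool)
                if icfg.get("epithelium")
                else None
            )
            tissue = (
                read_volume(icfg["tissue"], voxel_size=vs).grid.astype(bool)
                if icfg.get("tissue")
                else np.ones(labels.shape, bool) if epithelium is None else ~epithelium
            )
            truth = None
            oocytes = None
            note(f"loaded labels {labels.shape} @ {labels.voxel_size} μm")
        else:
            raise ValueError("config must contain a 'phantom' or 'input' section")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- stage: instances -------------------------------------------------
    stage = "instances"
    try:
        inst_cfg = dict(cfg.get("instances", {}))
        seg_cfg = dict(cfg.get("segment", {}))
        run_extraction = inst_cfg.pop("enabled", oocytes is None)
        if seg_cfg.get("from_intensity") and truth is not None:
            intensity = render_intensity(
                truth, noise_sd=float(seg_cfg.get("noise_sd", 0.0)), seed=seed
            )
            mask = threshold_segment(intensity, epithelium_mask=epithelium)
            run_extraction = True
        else:
            mask = labels.grid > 0
        if run_extraction:
            params = InstanceParams(**inst_cfg)
            labels, oocytes = extract_instances(mask, params, labels.voxel_size)
            note(f"instances: {len(oocytes)} after post-processing")
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- stage: cortex geometry -------------------------------------------
    stage = "cortex"
    try:
        ccfg = dict(cfg.get("cortex", {}))
        use_epithelium = ccfg.get("epithelium", True) and epithelium is not None
        if use_epithelium:
            geom = build_cortex(
                epithelium, tissue, labels.voxel_size, float(ccfg.get("depth_um", 1000.0))
            )
        else:
            warnings.warn(
                "no epithelium available: depth analysis skipped, density "
                "computed over the tissue mask",
                stacklevel=2,
            )
            note("warning: no epithelium; density over tissue mask, no depths")
            geom = tissue_geometry(tissue, labels.voxel_size)
        report["cortical_volume_mm3"] = geom.cortical_volume_mm3
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- stage: morphometrics ----------------------------------------------
    stage = "morphometrics"
    try:
        if use_epithelium:
            oocytes = oocyte_depths(oocytes, geom)
        ncfg = dict(cfg.get("neighbors", {}))
        oocytes = neighbor_counts(oocytes, float(ncfg.get("radius_um", 40.0)))
        threshold = int(cfg.get("cluster_threshold", 10))
        flagged = cluster_flags(oocytes, threshold)
        report["n_oocytes"] = int(len(oocytes))
        report["density_3d_per_mm3"] = density_3d(oocytes, geom)
        if use_epithelium and len(oocytes):
            report["median_depth_um"] = float(oocytes["depth_um"].median())
        report["median_neighbor_count"] = (
            float(oocytes["neighbor_count"].median()) if len(oocytes) else 0.0
        )
        report["clustered_fraction"] = (
            float(len(flagged) / len(oocytes)) if len(oocytes) else 0.0
        )
        note(
            f"morphometrics: density={report['density_3d_per_mm3']:.2f}/mm³, "
            f"median neighbours={report['median_neighbor_count']}"
        )
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- stage: virtual histology -------------------------------------------
    stage = "virtslice"
    try:
        vcfg = dict(cfg.get("virtslice", {}))
        thickness = float(vcfg.get("thickness_um", 4.0))
        interval = int(vcfg.get("interval", 10))
        floor = float(vcfg.get("visibility_floor_um", 5.0))
        report["strategies"] = compare_strategies(
            oocytes, geom, thickness=thickness, interval=interval, visibility_floor=floor
        )
        design = SectioningDesign(
            thickness=thickness,
            interval=interval,
            start=int(vcfg.get("start", 10)),
            n_analyzed=vcfg.get("n_analyzed", 5),
        )
        profset = make_profiles(oocytes, geom, design, floor)
        est = estimate_density(profset)
        report["design_estimate"] = {
            "p_profiles": est.p_profiles,
            "d_bar_um": est.d_bar_um,
            "n_hat": est.n_hat,
            "v_ext_mm3": est.v_ext_mm3,
            "density_corrected_per_mm3": est.density_corrected,
            "density_uncorrected_per_mm3": est.density_uncorrected,
            "design": asdict(design),
        }
        sections_table = profset.sections.copy()
        counts = profset.profiles.groupby("section").size()
        sections_table["n_profiles"] = (
            sections_table["section"].map(counts).fillna(0).astype(int)
        )
        note(f"virtslice: P={est.p_profiles}, corrected={est.density_corrected:.2f}/mm³")
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- stage: report -----------------------------------------------------
    stage = "report"
    try:
        write_table(oocytes, out_dir / "oocytes.csv")
        sections_table.to_csv(out_dir / "sections.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        marker = out_dir / "FAILED"
        if marker.exists():
            marker.unlink()
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    return report
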