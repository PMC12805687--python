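"""Shared fixtures: desk-scale phantoms reused across test modules.

Session-scoped so the expensive pieces (phantom generation, distance
transforms) run once.  Problem sizes are chosen so the full suite stays
desk-scale while keeping enough oocytes for the statistical checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from oomorph import (
    SectioningDesign,
    build_cortex,
    density_3d,
    estimate_density,
    generate_phantom,
    make_profiles,
    preset,
)
from oomorph.phantom import PhantomSpec


def monodisperse_spec(seed: int, diameter_sigma: float = 0.0) -> PhantomSpec:
    """A weakly clustered phantom of identical 36-μm oocytes (~260 per seed)."""
    return PhantomSpec(
        dims=(340, 480, 160),
        parent_intensity=900.0,
        mean_cluster_size=1.0,
        cluster_sd=10.0,
        depth_law=("lognormal", 300.0, 0.55),
        diameter_law=("lognormal", 36.0, diameter_sigma),
        min_gap=-6.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mono_runs():
    """Five monodisperse phantoms with exact cortex geometry and the k=1
    all-sections corrected estimate (visibility floor 0)."""
    runs = []
    for seed in range(5):
        truth = generate_phantom(monodisperse_spec(seed))
        geom = build_cortex(
            truth.epithelium_mask, truth.tissue_mask, truth.spec.voxel_size
        )
        est = estimate_density(
            make_profiles(
                truth.oocytes,
                geom,
                SectioningDesign(thickness=4.0, interval=1, start=1),
                visibility_floor=0.0,
            )
        )
        runs.append((truth, geom, est, density_3d(truth.oocytes, geom)))
    return runs


@pytest.fixture(scope="session")
def ped_run():
    """Pediatric preset phantom (seed 0) with its EDT-derived geometry."""
    truth = generate_phantom(preset("pediatric", seed=0))
    geom = build_cortex(truth.epithelium_mask, truth.tissue_mask, truth.spec.voxel_size)
    return truth, geom


@pytest.fixture(scope="session")
def adult_truth():
    return generate_phantom(preset("adult", seed=0))
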