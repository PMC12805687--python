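"""Virtual sectioning and the duplicate-count-corrected density estimator."""

import numpy as np
import pandas as pd
import pytest

from oomorph import (
    CortexGeometry,
    SectioningDesign,
    density_3d,
    estimate_density,
    interval_sweep,
    make_profiles,
    max_stable_interval,
    offset_sweep,
)


def box_geometry(nz=300, ny=6, nx=6, voxel=2.28):
    """All-cortex slab geometry for pure sectioning-geometry tests."""
    mask = np.ones((nz, ny, nx), bool)
    return CortexGeometry(
        distance_field=np.zeros((nz, ny, nx), np.float32),
        cortex_mask=mask,
        cortex_depth=np.inf,
        cortical_volume_mm3=nz * ny * nx * voxel**3 * 1e-9,
        voxel_size=voxel,
    )


def sphere_table(z_um, diameters):
    z = np.asarray(z_um, float)
    return pd.DataFrame(
        {
            "id": np.arange(1, len(z) + 1),
            "x_um": 5.0,
            "y_um": 5.0,
            "z_um": z,
            "diameter_um": np.broadcast_to(np.asarray(diameters, float), z.shape),
        }
    )


class TestSectioningDesign:
    def test_spacing_every_10th_of_4um_is_40um(self):
        assert SectioningDesign(thickness=4.0, interval=10).spacing_um == 40.0

    def test_clinical_five_section_design(self):
        d = SectioningDesign.clinical_five_sections()
        assert (d.start, d.interval, d.n_analyzed, d.thickness) == (10, 10, 5, 4.0)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            SectioningDesign(thickness=0.0)
        with pytest.raises(ValueError):
            SectioningDesign(interval=0)
        with pytest.raises(ValueError):
            SectioningDesign(start=0)


class TestMakeProfiles:
    def test_small_sphere_inside_one_slab(self):
        geom = box_geometry()
        # D = 3 μm sphere fully inside section 3 ([8, 12) μm)
        profs = make_profiles(
            sphere_table([10.0], 3.0),
            geom,
            SectioningDesign(thickness=4.0, interval=1, start=1),
            visibility_floor=0.0,
        )
        assert len(profs.profiles) == 1
        assert profs.profiles["section"].iloc[0] == 3
        assert profs.profiles["profile_diameter_um"].iloc[0] == pytest.approx(3.0)

    def test_equator_in_slab_gives_true_diameter(self):
        geom = box_geometry()
        profs = make_profiles(
            sphere_table([30.0], 20.0),
            geom,
            SectioningDesign(thickness=4.0, interval=1, start=1),
            visibility_floor=0.0,
        )
        d = profs.profiles.set_index("section")["profile_diameter_um"]
        assert d.loc[8] == pytest.approx(20.0)  # slab [28, 32) holds the equator
        # off-equator chord: slab [32, 36), δ = 2 μm → 2·sqrt(100 − 4)
        assert d.loc[9] == pytest.approx(2 * np.sqrt(96.0))
        assert (profs.profiles["profile_diameter_um"] <= 20.0 + 1e-12).all()

    def test_one_profile_per_oocyte_per_section(self):
        rng = np.random.default_rng(0)
        geom = box_geometry()
        tab = sphere_table(rng.uniform(50, 600, 300), rng.uniform(20, 40, 300))
        profs = make_profiles(
            tab, geom, SectioningDesign(thickness=4.0, interval=1, start=1), 0.0
        )
        assert not profs.profiles.duplicated(["section", "oocyte_id"]).any()
        merged = profs.profiles.merge(
            tab.rename(columns={"id": "oocyte_id"}), on="oocyte_id"
        )
        assert (
            merged["profile_diameter_um"] <= merged["diameter_um"] + 1e-12
        ).all()

    def test_visibility_floor_hides_polar_caps(self):
        geom = box_geometry()
        design = SectioningDesign(thickness=4.0, interval=1, start=1)
        # top of the sphere pokes 0.2 μm into slab [40, 44): a 4.0-μm chord
        all_profiles = make_profiles(sphere_table([30.2], 20.0), geom, design, 0.0)
        floored = make_profiles(sphere_table([30.2], 20.0), geom, design, 5.0)
        assert len(floored.profiles) < len(all_profiles.profiles)
        assert (floored.profiles["profile_diameter_um"] >= 5.0).all()

    def test_mean_profile_multiplicity_matches_closed_form(self):
        """E[sections hit per sphere] = (D + t)/t for uniform offsets:
        Monte Carlo over ≥ 2000 spheres within 2% of 10 for D=36, t=4."""
        rng = np.random.default_rng(42)
        n = 2000
        geom = box_geometry(nz=500)
        tab = sphere_table(rng.uniform(40.0, 1000.0, n), 36.0)
        profs = make_profiles(
            tab, geom, SectioningDesign(thickness=4.0, interval=1, start=1), 0.0
        )
        mean_mult = len(profs.profiles) / n
        assert mean_mult == pytest.approx(10.0, rel=0.02)

    def test_start_beyond_extent_reports_available_sections(self):
        geom = box_geometry(nz=50)  # 114 μm → 28 sections
        with pytest.raises(ValueError, match="28 sections"):
            make_profiles(
                sphere_table([50.0], 20.0),
                geom,
                SectioningDesign(thickness=4.0, interval=1, start=100),
            )


class TestEstimateDensity:
    def test_zero_profiles_gives_zero_density(self):
        geom = box_geometry()
        est = estimate_density(
            make_profiles(
                sphere_table([], 30.0), geom, SectioningDesign(interval=1, start=1)
            )
        )
        assert est.p_profiles == 0
        assert est.density_corrected == 0.0
        assert est.density_uncorrected == 0.0
        assert est.d_bar_um is None

    def test_zero_area_is_an_error(self):
        geom = box_geometry()
        geom.cortex_mask[:] = False
        with pytest.raises(ValueError, match="area"):
            estimate_density(
                make_profiles(
                    sphere_table([50.0], 20.0),
                    geom,
                    SectioningDesign(interval=1, start=1),
                )
            )

    def test_correction_identity_monodisperse(self):
        """With identical diameters the corrected/uncorrected ratio is exactly
        t/(t + D̄) — and D̄ equals the true diameter because every sphere's
        equator lies in some analyzed slab at k = 1."""
        rng = np.random.default_rng(7)
        geom = box_geometry()
        tab = sphere_table(rng.uniform(40, 600, 200), 36.0)
        est = estimate_density(
            make_profiles(tab, geom, SectioningDesign(thickness=4.0, interval=1, start=1), 0.0)
        )
        assert est.d_bar_um == pytest.approx(36.0)
        assert est.density_corrected == pytest.approx(
            est.density_uncorrected * 4.0 / (4.0 + 36.0), rel=1e-12
        )

    def test_correction_identity_on_random_populations(self):
        """density_corrected == density_uncorrected · t/(t + D̄) to 1e-12."""
        rng = np.random.default_rng(11)
        geom = box_geometry()
        for k, start in [(1, 1), (3, 2), (10, 10)]:
            tab = sphere_table(
                rng.uniform(40, 600, 150), rng.lognormal(np.log(30), 0.2, 150)
            )
            est = estimate_density(
                make_profiles(
                    tab,
                    geom,
                    SectioningDesign(thickness=4.0, interval=k, start=start),
                    0.0,
                )
            )
            assert est.density_corrected == pytest.approx(
                est.density_uncorrected * 4.0 / (4.0 + est.d_bar_um), rel=1e-12
            )

    def test_corrected_estimate_unbiased_for_monodisperse_phantoms(self, mono_runs):
        """k=1 all-sections corrected count within 5% of the true count
        (Abercrombie correction is unbiased for equal spheres)."""
        ratios = [est.n_hat / len(truth.oocytes) for truth, _, est, _ in mono_runs]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)


class TestSweeps:
    def test_degenerate_offset_sweep_single_start(self):
        geom = box_geometry(nz=60)  # 136.8 μm → 34 sections; 5×7-spacing needs 28
        tab = sphere_table([60.0, 80.0], 20.0)
        ests, summary = offset_sweep(tab, geom, interval=7, n_analyzed=5)
        assert summary["n_starts"] == 34 - 28
        # 37 voxels → 21 sections: exactly one feasible start for 3×10
        ests, summary = offset_sweep(tab, box_geometry(nz=37), interval=10, n_analyzed=3)
        assert summary["n_starts"] == 1
        assert summary["cv"] == 0.0

    def test_interval_one_equals_all_sections_estimate(self, mono_runs):
        truth, geom, est_k1, _ = mono_runs[0]
        sweep = interval_sweep(truth.oocytes, geom, k_range=[1], visibility_floor=0.0)
        assert sweep["density_corrected"].iloc[0] == pytest.approx(
            est_k1.density_corrected, rel=1e-12
        )

    def test_max_stable_interval_logic(self):
        df = pd.DataFrame(
            {"k": [1, 2, 3, 4], "density_corrected": [100.0, 110.0, 125.0, 100.0]}
        )
        assert max_stable_interval(df, tol=0.2) == 2  # k=3 breaks the run
        with pytest.raises(ValueError, match="k = 1"):
            max_stable_interval(pd.DataFrame({"k": [2], "density_corrected": [1.0]}))

    def test_empty_population_all_densities_zero(self):
        from oomorph import compare_strategies

        geom = box_geometry(nz=300)
        out = compare_strategies(sphere_table([], 30.0), geom)
        assert out["density_3d"] == 0.0
        assert out["density_every10th_full"] == 0.0
        assert out["density_five_sections"] == 0.0
        assert out["rel_err_five_sections"] == 0.0

    def test_overcorrection_direction_for_right_skewed_diameters(self):
        """With a right-skewed diameter law the top-decile D̄ overestimates the
        typical diameter, so the corrected density falls below truth."""
        from oomorph import generate_phantom, true_geometry
        from oomorph.phantom import PhantomSpec

        spec = PhantomSpec(
            dims=(340, 480, 160),
            parent_intensity=900.0,
            mean_cluster_size=1.0,
            cluster_sd=10.0,
            depth_law=("lognormal", 300.0, 0.55),
            diameter_law=("lognormal", 30.0, 0.30),
            min_gap=-6.0,
            seed=3,
        )
        truth = generate_phantom(spec)
        geom = true_geometry(truth)
        est = estimate_density(
            make_profiles(
                truth.oocytes,
                geom,
                SectioningDesign(thickness=4.0, interval=1, start=1),
                0.0,
            )
        )
        d3 = density_3d(truth.oocytes, geom)
        assert est.density_corrected < d3
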