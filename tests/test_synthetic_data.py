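"""Forward model: determinism, additivity, placement, kinetics tables."""

import numpy as np
import pytest

import nanouptake as nu
from nanouptake.synthetic_data import _signed_distance, render_spot_field


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p = nu.ScenarioParams(particles=[nu.ParticleSpec("intra")] * 3, seed=13)
        m1, g1, t1 = nu.generate_cell_stack(p)
        m2, g2, t2 = nu.generate_cell_stack(p)
        np.testing.assert_array_equal(m1.data, m2.data)
        np.testing.assert_array_equal(g1.data, g2.data)
        assert t1.particles == t2.particles

    def test_different_seed_differs(self):
        p1 = nu.ScenarioParams(particles=[nu.ParticleSpec("intra")], seed=1)
        p2 = nu.ScenarioParams(particles=[nu.ParticleSpec("intra")], seed=2)
        assert not np.array_equal(
            nu.generate_cell_stack(p1)[1].data, nu.generate_cell_stack(p2)[1].data
        )


class TestForwardModel:
    def test_multiplicity_is_additive_before_noise(self):
        shape, vox, psf = (16, 60, 60), (0.25, 0.11, 0.11), (0.45, 0.15)
        pos = np.array([[2.0, 3.0, 3.0]])
        unit = render_spot_field(shape, vox, pos, [1000.0], psf)
        k7 = render_spot_field(shape, vox, pos, [7000.0], psf)
        np.testing.assert_allclose(k7, 7 * unit, rtol=1e-12)

    def test_integrated_spot_intensity_equals_request(self):
        shape, vox, psf = (20, 80, 80), (0.25, 0.11, 0.11), (0.45, 0.15)
        clean = render_spot_field(shape, vox, [[2.5, 4.4, 4.4]], [48090.0], psf)
        assert clean.sum() == pytest.approx(48090.0, rel=1e-3)

    def test_mean_noisy_intensity_near_expected(self):
        grid, truth = nu.generate_calibration_field(
            n_spots=60, cv=0.0, doublet_fraction=0.0, seed=31
        )
        # integrate the whole stack minus the background plane
        total = grid.data.sum() - 100.0 * grid.data.size
        expected = 60 * 48090.0
        assert total == pytest.approx(expected, rel=0.03)


class TestPlacement:
    def test_particles_land_in_their_region_class(self):
        specs = (
            [nu.ParticleSpec("intra")] * 6
            + [nu.ParticleSpec("shell")] * 4
            + [nu.ParticleSpec("outside")] * 5
        )
        params = nu.ScenarioParams(particles=specs, seed=8)
        _, _, truth = nu.generate_cell_stack(params)
        half_w = params.shell_width_um / 2
        for p in truth.particles:
            x, y, z = p["position_um"]
            s = float(_signed_distance(params, np.array([z, y, x])))
            if p["region"] == "intra":
                assert s <= -half_w
            elif p["region"] == "shell":
                assert abs(s) <= half_w
            else:
                assert s >= half_w

    def test_min_separation_respected(self):
        specs = [nu.ParticleSpec("intra")] * 8
        params = nu.ScenarioParams(particles=specs, seed=9)
        _, _, truth = nu.generate_cell_stack(params)
        pos = np.array([[p["position_um"][2], p["position_um"][1], p["position_um"][0]]
                        for p in truth.particles])
        from scipy.spatial.distance import pdist

        assert pdist(pos).min() >= params.min_particle_separation_um

    def test_too_thin_cell_rejects_intra_particles(self):
        params = nu.ScenarioParams(
            cell_shape="sphere", cell_radius_um=0.9,
            particles=[nu.ParticleSpec("intra")], seed=0,
        )
        with pytest.raises(ValueError, match="too thin"):
            nu.generate_cell_stack(params)

    def test_hemisphere_shape_supported(self, default_detection, unit_calibration):
        specs = [nu.ParticleSpec("intra")] * 4 + [nu.ParticleSpec("outside")] * 3
        params = nu.ScenarioParams(
            cell_shape="hemisphere", cell_radius_um=6.0, particles=specs, seed=17
        )
        membrane, particles, truth = nu.generate_cell_stack(params)
        regions = nu.reconstruct_cell(membrane)
        objs = nu.detect_objects(
            nu.subtract_background(particles, default_detection), default_detection
        )
        result = nu.summarize_cell(objs, regions, unit_calibration, grid=particles)
        assert result.totals["n_intracellular"] == 4
        assert result.totals["n_extracellular"] == 3


class TestCalibrationField:
    def test_equal_intensities_without_noise(self, small_calibration_field):
        grid, _ = small_calibration_field
        params = nu.DetectionParams()
        objs = nu.detect_objects(nu.subtract_background(grid, params), params)
        I = np.array([o.integrated_intensity for o in objs])
        assert len(I) == 60
        assert I.std() / I.mean() < 0.01

    def test_doublet_count_matches_fraction(self):
        _, truth = nu.generate_calibration_field(
            n_spots=100, doublet_fraction=0.2, seed=3, poisson_scale=0, read_noise_sd=0
        )
        n_doublets = sum(1 for p in truth.particles if p["multiplicity"] == 2)
        assert n_doublets == 20

    def test_overcrowded_field_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            nu.generate_calibration_field(
                n_spots=200, field_size_um=(8.0, 8.0), seed=0
            )


class TestKinetics:
    def test_constant_distribution(self):
        table, _ = nu.generate_kinetics_dataset(
            [{"condition": "a", "time_h": 4, "n_cells": 30,
              "distribution": {"kind": "constant", "value": 113}}],
            seed=0,
        )
        s = nu.summarize_condition(table["count"], "a", 4)
        assert s.mean_count == 113 and s.sem_count == 0 and s.n_cells == 30

    def test_reproducible(self):
        design = [{"condition": "a", "time_h": 24, "n_cells": 25,
                   "distribution": {"kind": "negative_binomial", "mean": 256, "dispersion": 5}}]
        t1, _ = nu.generate_kinetics_dataset(design, seed=4)
        t2, _ = nu.generate_kinetics_dataset(design, seed=4)
        assert t1.equals(t2)

    def test_sampling_distribution_matches_design(self):
        design = [{"condition": "a", "time_h": 24, "n_cells": 30,
                   "distribution": {"kind": "negative_binomial", "mean": 200, "dispersion": 8}}]
        means = []
        for seed in range(60):
            t, _ = nu.generate_kinetics_dataset(design, seed=seed)
            means.append(t["count"].mean())
        means = np.asarray(means)
        # designed per-cell sd: sqrt(m + m^2/r); SE of the grand mean over all draws
        sd_cell = np.sqrt(200 + 200**2 / 8)
        se_grand = sd_cell / np.sqrt(30 * len(means))
        assert abs(means.mean() - 200) < 3 * se_grand
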