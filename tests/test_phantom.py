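import dataclasses

import numpy as np
import pytest

from callusmech.phantom import (
    HealingLoading,
    HealingRule,
    PhantomGeometry,
    add_image_noise,
    build_phantom,
    simulate_healing,
)


class TestGeometryValidation:
    def test_gap_must_be_positive(self):
        with pytest.raises(ValueError):
            PhantomGeometry(gap_length=0.0)

    def test_thickness_must_fit(self):
        with pytest.raises(ValueError):
            PhantomGeometry(outer_minor_axis=0.2, cortical_thickness=0.15)

    def test_density_above_ladder(self):
        with pytest.raises(ValueError):
            PhantomGeometry(cortical_density=700.0)

    def test_oversized_geometry_names_dimension(self):
        geom = PhantomGeometry(grid_shape=(20, 96, 160))
        with pytest.raises(ValueError, match="outer_major_axis"):
            build_phantom(geom)

    def test_oversized_gap_rejected(self):
        geom = PhantomGeometry(grid_shape=(96, 96, 40), gap_length=0.85)
        with pytest.raises(ValueError, match="gap_length"):
            build_phantom(geom)


class TestBuildPhantom:
    def test_default_gap_spans_81_slices(self):
        # round(850 um / 10.5 um) computed independently
        geom = PhantomGeometry()
        img = build_phantom(geom)
        occupied = (img.values > 0).any(axis=(0, 1))
        assert int((~occupied).sum()) == 81 == round(850 / 10.5)
        # the gap is contiguous and interior
        empty = np.nonzero(~occupied)[0]
        assert empty.max() - empty.min() + 1 == 81

    def test_fragments_touch_axial_faces(self, small_phantom):
        assert (small_phantom.values[:, :, 0] > 0).any()
        assert (small_phantom.values[:, :, -1] > 0).any()

    def test_outside_fragments_zero(self, small_geom, small_phantom):
        vals = small_phantom.values
        assert set(np.unique(vals)) == {0.0, small_geom.cortical_density}

    def test_solid_limit_has_no_marrow(self):
        geom = PhantomGeometry(
            grid_shape=(48, 48, 64),
            outer_major_axis=0.42,
            outer_minor_axis=0.32,
            cortical_thickness=0.16,  # = semi-minor axis -> solid section
            gap_length=0.21,
        )
        img = build_phantom(geom)
        sl = img.values[:, :, 0] > 0
        from scipy import ndimage

        filled = ndimage.binary_fill_holes(sl)
        assert np.array_equal(sl, filled)

    def test_rasterised_volume_within_5pc_of_analytic(self):
        geom = PhantomGeometry(
            grid_shape=(64, 64, 64),
            outer_major_axis=0.52,
            outer_minor_axis=0.44,
            cortical_thickness=0.12,
            gap_length=0.21,
        )
        img = build_phantom(geom)
        vox = geom.voxel_size_mm**3
        raster = float((img.values > 0).sum()) * vox
        a, b = geom.outer_major_axis / 2, geom.outer_minor_axis / 2
        ai, bi = a - geom.cortical_thickness, b - geom.cortical_thickness
        ring_area = np.pi * (a * b - ai * bi)
        length = (64 - geom.gap_voxels) * geom.voxel_size_mm
        assert raster == pytest.approx(ring_area * length, rel=0.05)


class TestImageNoise:
    def test_sigma_zero_identity(self, small_phantom):
        out = add_image_noise(small_phantom, 0.0, rng_seed=1)
        np.testing.assert_array_equal(out.values, small_phantom.values)

    def test_negative_sigma_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            add_image_noise(small_phantom, -1.0)

    def test_deterministic_under_seed(self, small_phantom):
        a = add_image_noise(small_phantom, 25.0, rng_seed=5)
        b = add_image_noise(small_phantom, 25.0, rng_seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_mean_clt_bound(self):
        # all-high-density image so clipping at zero never triggers
        from callusmech.imageproc import DensityImage

        n = 101 * 101 * 101  # > 1e6 voxels
        img = DensityImage(np.full((101, 101, 101), 800.0), voxel_size=10.5)
        sigma = 25.0
        noisy = add_image_noise(img, sigma, rng_seed=3)
        diff = noisy.values - img.values
        assert abs(diff.mean()) <= 3 * sigma / np.sqrt(n)


class TestHealingRule:
    def test_flip_noise_bounds(self):
        with pytest.raises(ValueError):
            HealingRule(flip_noise=1.5)

    def test_threshold_ordering(self):
        with pytest.raises(ValueError):
            HealingRule(strain_threshold_form=0.1, strain_threshold_res=0.2)

    def test_seed_density_floor(self):
        with pytest.raises(ValueError):
            HealingRule(seed_density=100.0)


class TestSimulateHealing:
    def test_returns_n_steps_plus_one_frames(self, sim_series):
        frames, log, _ = sim_series
        assert len(frames) == 4
        assert len(log) == 3

    def test_conservation_per_step(self, sim_series):
        frames, log, rule = sim_series
        for t, step in enumerate(log.steps):
            bone_t = (frames[t].values >= rule.bone_threshold).ravel()
            bone_t1 = (frames[t + 1].values >= rule.bone_threshold).ravel()
            expect = bone_t.copy()
            expect[step.resorbed] = False
            expect[step.formed] = True
            np.testing.assert_array_equal(bone_t1, expect)

    def test_formed_disjoint_from_resorbed(self, sim_series):
        _, log, _ = sim_series
        for step in log.steps:
            assert not set(step.formed) & set(step.resorbed)

    def test_formed_voxels_were_background(self, sim_series):
        frames, log, rule = sim_series
        for t, step in enumerate(log.steps):
            before = frames[t].values.ravel()[step.formed]
            after = frames[t + 1].values.ravel()[step.formed]
            assert np.all(before < rule.bone_threshold)
            assert np.all(after == rule.seed_density)

    def test_noise_free_rule_formation_strains(self, small_phantom, fast_loading):
        rule = HealingRule(
            strain_threshold_form=0.30, flip_noise=0.0, conduction_radius=np.inf, rng_seed=0
        )
        frames, log = simulate_healing(small_phantom, rule, fast_loading, n_steps=1)
        step = log.steps[0]
        assert step.formed.size > 0
        assert np.all(step.eff_strain.ravel()[step.formed] > rule.strain_threshold_form)
        assert step.resorbed.size == 0  # T_R = 0 and no flips

    def test_zero_load_no_formation(self, small_phantom):
        loading = HealingLoading(axial_displacement=0.0, fe_coarsen=4)
        rule = HealingRule(flip_noise=0.0, conduction_radius=np.inf, rng_seed=0)
        frames, log = simulate_healing(small_phantom, rule, loading, n_steps=1)
        assert log.steps[0].formed.size == 0
        np.testing.assert_allclose(log.steps[0].eff_strain, 0.0, atol=1e-12)

    def test_deterministic_under_seed(self, small_phantom, fast_loading):
        rule = HealingRule(flip_noise=0.05, conduction_radius=2.0, rng_seed=21)
        f1, l1 = simulate_healing(small_phantom, rule, fast_loading, n_steps=2)
        f2, l2 = simulate_healing(small_phantom, rule, fast_loading, n_steps=2)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.values, b.values)
        for s1, s2 in zip(l1.steps, l2.steps):
            np.testing.assert_array_equal(s1.formed, s2.formed)
            np.testing.assert_array_equal(s1.resorbed, s2.resorbed)

    def test_conduction_radius_limits_reach(self, small_phantom, fast_loading):
        from scipy import ndimage

        rule = HealingRule(flip_noise=0.0, conduction_radius=2.0, rng_seed=0)
        frames, log = simulate_healing(small_phantom, rule, fast_loading, n_steps=1)
        bone0 = small_phantom.values >= rule.bone_threshold
        dist = ndimage.distance_transform_edt(~bone0)
        formed = np.zeros(small_phantom.values.size, bool)
        formed[log.steps[0].formed] = True
        assert np.all(dist.ravel()[log.steps[0].formed] <= 2.0)

    def test_maturation_capped(self, small_phantom, fast_loading):
        rule = HealingRule(
            flip_noise=0.0, conduction_radius=np.inf, maturation_rate=100.0,
            max_density=900.0, rng_seed=0,
        )
        frames, _ = simulate_healing(small_phantom, rule, fast_loading, n_steps=2)
        assert frames[-1].values.max() <= 900.0

    def test_n_steps_validated(self, small_phantom, fast_loading):
        rule = HealingRule(rng_seed=0)
        with pytest.raises(ValueError):
            simulate_healing(small_phantom, rule, fast_loading, n_steps=0)


class TestDoseResponse:
    def test_flip_noise_never_increases_auc(self, small_phantom, fast_loading):
        """Monotone dose-response of the downstream ROC in flip noise."""
        from callusmech.imageproc import BinaryMask, overlay
        from callusmech.mechreg import roc_analysis

        for seed in (1, 2, 3):
            aucs = []
            for p in (0.0, 0.05, 0.2):
                rule = HealingRule(
                    strain_threshold_form=0.30,
                    flip_noise=p,
                    conduction_radius=np.inf,
                    rng_seed=seed,
                )
                frames, log = simulate_healing(small_phantom, rule, fast_loading, n_steps=1)
                m0 = BinaryMask(frames[0].values >= 395.0, 395.0, 0)
                m1 = BinaryMask(frames[1].values >= 395.0, 395.0, 1)
                roc = roc_analysis(log.steps[0].eff_strain.astype(float), overlay(m0, m1))
                aucs.append(roc.auc)
            assert aucs[0] >= aucs[1] >= aucs[2], aucs
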