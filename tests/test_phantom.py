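"""Phantom generator: planted populations and voxel rendering."""

import numpy as np
import pytest
from scipy.stats import norm

from lensxct import (GroundTruth, PhantomConfig, named_config,
                     render_phantom, sample_precipitate_population)
from lensxct.phantom import (analytic_capsule_volume, calibrate_length_median,
                             _segment_distance)


class TestPopulationSampling:
    def test_empty_population(self, tiny_config):
        truth = sample_precipitate_population(tiny_config(n_precipitates=0))
        assert len(truth) == 0
        assert truth.centers_um.shape == (0, 3)

    def test_zero_shell_scatter_gives_exact_radii(self, tiny_config):
        cfg = tiny_config(shell_radii_um=(200.0,), shell_sd_um=0.0,
                          n_precipitates=40, length_max_um=50.0)
        truth = sample_precipitate_population(cfg)
        np.testing.assert_allclose(truth.radii_um, 200.0, rtol=1e-12)

    def test_fixed_seed_bitwise_reproducible(self, tiny_config):
        cfg = tiny_config(n_precipitates=25, noise_sd=0.4)
        a = sample_precipitate_population(cfg)
        b = sample_precipitate_population(cfg)
        np.testing.assert_array_equal(a.centers_um, b.centers_um)
        np.testing.assert_array_equal(a.lengths_um, b.lengths_um)
        np.testing.assert_array_equal(a.mean_absorptions, b.mean_absorptions)
        va = render_phantom(cfg, a)
        vb = render_phantom(cfg, b)
        assert va.grid.tobytes() == vb.grid.tobytes()

    def test_length_cdf_matches_calibrated_fraction(self):
        # isotropic directions: only the length marginal is under test
        cfg = PhantomConfig(n_precipitates=4000, frac_below_40um=0.9,
                            anterior_fraction=0.0, seed=11)
        truth = sample_precipitate_population(cfg)
        frac = (truth.lengths_um < 40.0).mean()
        se = np.sqrt(0.9 * 0.1 / 4000)
        assert abs(frac - 0.9) <= 3 * se

    def test_lengths_and_widths_respect_bounds_and_coupling(self, tiny_config):
        cfg = tiny_config(n_precipitates=60, length_max_um=80.0)
        truth = sample_precipitate_population(cfg)
        assert truth.lengths_um.min() >= cfg.length_min_um
        assert truth.lengths_um.max() <= cfg.length_max_um
        expected = np.minimum(
            1.0, (cfg.width_um / truth.lengths_um) ** cfg.ar_coupling)
        np.testing.assert_allclose(truth.elongations, expected)
        assert np.all(truth.elongations > 0)
        assert np.all(truth.elongations <= 1)

    def test_anterior_fraction_one_restricts_hemisphere_and_sectors(self):
        cfg = PhantomConfig(n_precipitates=300, anterior_fraction=1.0, seed=3)
        truth = sample_precipitate_population(cfg)
        z = truth.centers_um[:, 0]
        assert np.all(z > 0)
        # azimuths folded onto one sector period stay within the half-width
        phi = np.degrees(np.arctan2(truth.centers_um[:, 1],
                                    truth.centers_um[:, 2]))
        period = 360.0 / cfg.suture_sector_count
        folded = (phi + period / 2) % period - period / 2
        assert np.all(np.abs(folded) <= cfg.suture_sector_halfwidth_deg + 1e-9)

    def test_two_shell_radii_recovered_as_histogram_modes(self):
        cfg = PhantomConfig(n_precipitates=800, shell_sd_um=15.0, seed=5)
        truth = sample_precipitate_population(cfg)
        counts, edges = np.histogram(truth.radii_um,
                                     bins=np.arange(0, 700, 10.0))
        centers = (edges[:-1] + edges[1:]) / 2
        for shell in cfg.shell_radii_um:
            near = np.abs(centers - shell) <= 30.0
            mode = centers[near][counts[near].argmax()]
            assert abs(mode - shell) <= 10.0

    def test_min_separation_enforced(self):
        cfg = PhantomConfig(n_precipitates=200, seed=9)
        truth = sample_precipitate_population(cfg)
        w = truth.widths_um
        h = (truth.lengths_um - w) / 2
        n = len(truth)
        for i in range(n):
            for j in range(i + 1, n):
                d = _segment_distance(truth.centers_um[i],
                                      truth.orientations[i], h[i],
                                      truth.centers_um[j],
                                      truth.orientations[j], h[j])
                assert d >= (w[i] + w[j]) / 2 + cfg.min_separation_um - 1e-9

    def test_orientations_are_radial_units(self, tiny_config):
        truth = sample_precipitate_population(tiny_config(n_precipitates=30))
        norms = np.linalg.norm(truth.orientations, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        radial = truth.centers_um / truth.radii_um[:, None]
        np.testing.assert_allclose(truth.orientations, radial, atol=1e-9)

    def test_absorptions_within_declared_bounds(self, tiny_config):
        cfg = tiny_config(n_precipitates=80, absorption_min=12.0,
                          absorption_cap=28.0)
        truth = sample_precipitate_population(cfg)
        assert truth.mean_absorptions.min() >= 12.0
        assert truth.mean_absorptions.max() <= 28.0
        assert np.all(truth.mean_absorptions > cfg.background_mu)

    @pytest.mark.parametrize("bad", [
        dict(shell_radii_um=(400.0,), lens_radius_um=300.0),
        dict(voxel_pitch_um=0.0),
        dict(voxel_pitch_um=-2.0),
        dict(n_precipitates=-1),
        dict(frac_below_40um=1.5),
        dict(absorption_min=4.0),  # below background_mu
    ])
    def test_invalid_configs_rejected(self, tiny_config, bad):
        with pytest.raises(ValueError):
            sample_precipitate_population(tiny_config(**bad))

    def test_overcrowded_config_raises(self, tiny_config):
        cfg = tiny_config(lens_radius_um=120.0, shell_radii_um=(60.0,),
                          shell_sd_um=0.0, n_precipitates=500,
                          suture_sector_halfwidth_deg=5.0)
        with pytest.raises(RuntimeError, match="crowded"):
            sample_precipitate_population(cfg, max_tries=20)


class TestLengthCalibration:
    def test_calibrated_median_hits_target_fraction(self):
        for frac, sigma in [(0.995, 0.55), (0.96, 0.65), (0.9, 0.9)]:
            m = calibrate_length_median(frac, sigma, 15.0, 180.0)
            a = norm.sf(np.log(15.0 / m) / sigma)
            b = norm.sf(np.log(40.0 / m) / sigma)
            c = norm.sf(np.log(180.0 / m) / sigma)
            assert abs((a - b) / (a - c) - frac) < 1e-8

    def test_requires_threshold_inside_bounds(self):
        with pytest.raises(ValueError):
            calibrate_length_median(0.9, 0.5, 45.0, 180.0)


class TestRendering:
    def test_noiseless_sphere_rendered_exactly(self, tiny_config):
        cfg = tiny_config(n_precipitates=0, noise_sd=0.0)
        truth = GroundTruth(
            centers_um=np.array([[0.0, 0.0, 0.0]]),
            lengths_um=np.array([30.0]),
            elongations=np.array([1.0]),
            orientations=np.array([[1.0, 0.0, 0.0]]),
            mean_absorptions=np.array([25.0]),
            shell_indices=np.array([0]),
            config=cfg)
        vol = render_phantom(cfg, truth)
        values = set(np.unique(vol.grid).tolist())
        assert values == {0.0, cfg.background_mu, 25.0}
        # every voxel center within 15 µm of the lens center carries 25
        c = np.array(vol.meta["lens_center_um"])
        idx = np.argwhere(vol.grid == 25.0) * cfg.voxel_pitch_um
        assert np.all(np.linalg.norm(idx - c, axis=1) <= 15.0 + 1e-6)

    def test_foreground_volume_matches_analytic_capsules(self, tiny_config):
        cfg = tiny_config(n_precipitates=40, noise_sd=0.0, seed=21)
        truth = sample_precipitate_population(cfg)
        vol = render_phantom(cfg, truth)
        n_fg = int((vol.grid > cfg.background_mu).sum())
        expected = sum(analytic_capsule_volume(l, w) for l, w in
                       zip(truth.lengths_um, truth.widths_um))
        expected_vox = expected / cfg.voxel_pitch_um ** 3
        assert abs(n_fg - expected_vox) / expected_vox < 0.15

    def test_anterior_fraction_one_leaves_posterior_empty(self):
        cfg = PhantomConfig(n_precipitates=120, anterior_fraction=1.0,
                            noise_sd=0.0, seed=13)
        truth = sample_precipitate_population(cfg)
        vol = render_phantom(cfg, truth)
        assert np.all(truth.centers_um[:, 0] > 0)
        # object voxels may straddle the equator plane, but none may extend
        # deeper posterior than an object's own half-extent
        cz = int(round(vol.meta["lens_center_um"][0] / cfg.voxel_pitch_um))
        reach = (truth.lengths_um.max() + truth.widths_um.max()) / 2
        margin = int(np.ceil(reach / cfg.voxel_pitch_um)) + 1
        posterior = vol.grid[:cz - margin]
        assert not np.any(posterior > cfg.background_mu)

    def test_voxel_budget_guard(self, tiny_config):
        cfg = tiny_config(n_precipitates=0)
        truth = sample_precipitate_population(cfg)
        with pytest.raises(ValueError, match="budget"):
            render_phantom(cfg, truth, voxel_budget=1000)


def test_named_configs_cover_the_four_groups():
    for name in ("P23-B6", "P27-129", "P31-B6", "P31-129"):
        cfg = named_config(name)
        cfg.validate()
        assert cfg.name == name
    with pytest.raises(ValueError, match="P23-B6"):
        named_config("P99-XX")
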