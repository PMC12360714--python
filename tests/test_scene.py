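"""Renderer contracts: geometry, determinism, noise, and config round trip."""

import numpy as np
import pandas as pd
import pytest

from phantomqa import (
    DEFAULT_RCS_CONCENTRATIONS,
    DegenerateSceneError,
    GridSpec,
    InvalidConfigError,
    SceneConfig,
    measure_disk_roi,
    render_cylinders,
    render_rcs,
    render_rud,
)
from phantomqa.scene import DistortionField, IlluminationField

from .conftest import radial_map_oracle, small_config


class TestGridSpec:
    def test_default_grid_has_2601_wells(self):
        g = GridSpec()
        assert g.wells_per_axis == 51
        assert g.total_wells == 2601

    @pytest.mark.parametrize("extent,pitch,expected", [(20.0, 2.0, 11), (100.0, 2.0, 51), (9.0, 2.0, 5)])
    def test_wells_per_axis(self, extent, pitch, expected):
        assert GridSpec(extent_mm=extent, pitch_mm=pitch).wells_per_axis == expected

    def test_rejects_overlapping_wells(self):
        with pytest.raises(InvalidConfigError):
            GridSpec(well_diameter_mm=2.5, pitch_mm=2.0)


class TestRenderRud:
    def test_default_scene_truth_lists_2601_wells(self, default_rud):
        _, _, truth, _ = default_rud
        assert len(truth) == 2601

    def test_uniform_scene_well_intensities_equal(self, small_rud):
        """With identity distortion and uniform illumination the wells are
        interchangeable: the anti-aliasing-only CV of their true means is 0
        and of detected means is below 1%."""
        _, _, truth, wells = small_rud
        assert truth.table["intensity_true"].std() == 0.0
        mi = np.array([w.mean_intensity for w in wells])
        assert mi.std() / mi.mean() < 0.01

    @pytest.mark.parametrize("k1,k2", [(-0.05, 0.0), (0.02, 0.0), (-0.03, 0.01)])
    def test_distorted_centers_match_independent_radial_map(self, k1, k2):
        """Truth distorted centers equal an independently coded Brown map."""
        cfg = small_config(distortion=DistortionField(k1=k1, k2=k2))
        _, truth = render_rud(cfg)
        oracle = radial_map_oracle(k1, k2, cfg.image_shape)
        expected = oracle(truth.table[["x_undist_px", "y_undist_px"]].to_numpy())
        actual = truth.table[["x_true_px", "y_true_px"]].to_numpy()
        assert np.max(np.hypot(*(actual - expected).T)) < 1e-6

    def test_identity_distortion_centers_coincide(self, small_rud):
        _, _, truth, _ = small_rud
        t = truth.table
        assert np.array_equal(t[["x_true_px", "y_true_px"]].to_numpy(), t[["x_undist_px", "y_undist_px"]].to_numpy())

    def test_seed_determinism_bit_identical(self):
        cfg = small_config(noise_model="gaussian", noise_strength=50.0, seed=7)
        img1, _ = render_rud(cfg)
        img2, _ = render_rud(cfg)
        assert np.array_equal(img1, img2)

    def test_seed_change_alters_noise_not_geometry(self):
        cfg = small_config(noise_model="gaussian", noise_strength=50.0, seed=7)
        img1, t1 = render_rud(cfg)
        img2, t2 = render_rud(cfg.replace(seed=8))
        assert not np.array_equal(img1, img2)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_outermost_distortion_monotone_in_k1(self):
        """Stronger barrel coefficients displace the corner well further."""
        prev = -1.0
        for k1 in (-0.01, -0.03, -0.06):
            cfg = small_config(distortion=DistortionField(k1=k1))
            _, truth = render_rud(cfg)
            t = truth.table
            r_u = np.hypot(t.x_undist_px - 127.5, t.y_undist_px - 127.5)
            j = r_u.idxmax()
            disp = np.hypot(t.x_true_px[j] - t.x_undist_px[j], t.y_true_px[j] - t.y_undist_px[j])
            assert disp > prev
            prev = disp

    def test_degenerate_and_invalid_scenes_raise(self):
        with pytest.raises(DegenerateSceneError):
            render_rud(small_config(target_offset_mm=(500.0, 500.0)))
        with pytest.raises(InvalidConfigError):
            render_rud(small_config(mm_per_pixel=1.0))  # 1 px wells

    def test_tilt_separates_distorted_from_undistorted_truth(self):
        cfg = small_config(distortion=DistortionField(tilt_deg=3.0))
        _, truth = render_rud(cfg)
        t = truth.table
        assert not np.allclose(t[["x_true_px", "y_true_px"]], t[["x_undist_px", "y_undist_px"]])


class TestSceneConfigRoundTrip:
    def test_yaml_round_trip_is_lossless(self, tmp_path):
        cfg = small_config(
            illumination=IlluminationField("radial_gaussian", {"sigma_frac": 0.4}),
            distortion=DistortionField(k1=-0.02, tilt_deg=1.5),
            noise_model="poisson_like",
            noise_strength=2.0,
            seed=11,
        )
        path = tmp_path / "scene.yaml"
        cfg.to_yaml(path)
        assert SceneConfig.from_yaml(path) == cfg


class TestRenderRcs:
    def test_linear_response_proportional_to_concentration(self):
        cfg = small_config()
        _, truth = render_rcs(DEFAULT_RCS_CONCENTRATIONS, cfg, m_true=1.0, well_diameter_mm=4.0, pitch_mm=6.0)
        t = truth.table
        ratio = t.intensity_true / t.concentration_nM.replace(0, np.nan)
        ratio = ratio.dropna()
        assert np.allclose(ratio, ratio.iloc[0])

    def test_control_well_required(self):
        cfg = small_config()
        with pytest.raises(InvalidConfigError):
            render_rcs([1, 3, 10, 30, 60, 100, 300, 1000, 2000], cfg, well_diameter_mm=4.0, pitch_mm=6.0)

    def test_global_attenuation_preserves_baselined_ratios(self):
        """Illumination attenuating all wells equally cancels after
        baselining and normalization (direct arithmetic on the truth)."""
        cfg = small_config()
        dim = cfg.replace(illumination=IlluminationField("separable_polynomial", {"coeffs_x": [0.6], "coeffs_y": [1.0]}))
        _, t1 = render_rcs(DEFAULT_RCS_CONCENTRATIONS, cfg, well_diameter_mm=4.0, pitch_mm=6.0)
        _, t2 = render_rcs(DEFAULT_RCS_CONCENTRATIONS, dim, well_diameter_mm=4.0, pitch_mm=6.0)
        b1 = t1.table.intensity_true - t1.table.intensity_true[t1.table.concentration_nM == 0].iloc[0]
        b2 = t2.table.intensity_true - t2.table.intensity_true[t2.table.concentration_nM == 0].iloc[0]
        np.testing.assert_allclose(b1 / b1.max(), b2 / b2.max(), atol=1e-12)


class TestRenderCylinders:
    def test_noise_free_disk_means_match_truth(self):
        cfg = small_config(psf_sigma_px=0.0, background_offset=100.0)
        img, truth = render_cylinders((100.0, 0.0), (0.0, 0.0), cfg, diameter_mm=6.0, separation_mm=8.0)
        t = truth.table
        for _, row in t.iterrows():
            mean, sd, _ = measure_disk_roi(img, (row.x_true_px, row.y_true_px), (2 / 3) * row.radius_px)
            assert mean == pytest.approx(row.intensity_true + 100.0, abs=1e-9)

    def test_edge_illumination_scales_signal_not_background(self):
        """Signal is multiplicative in the efficiency field; the background
        offset is additive and unscaled."""
        illum = IlluminationField("radial_gaussian", {"sigma_frac": 0.35})
        cfg = small_config(psf_sigma_px=0.0, background_offset=100.0, illumination=illum)
        img, truth = render_cylinders((100.0, 0.0), (-6.0, 0.0), cfg, diameter_mm=5.0, separation_mm=6.0)
        t = truth.table
        hot = t.iloc[0]
        mean, _, _ = measure_disk_roi(img, (hot.x_true_px, hot.y_true_px), (2 / 3) * hot.radius_px)
        assert mean == pytest.approx(cfg.peak_intensity * hot.illum + 100.0, rel=1e-6)
        assert hot.illum < 0.95  # the placement really is off-peak

    def test_two_seeds_differ_only_in_noise(self):
        cfg = small_config(noise_model="gaussian", noise_strength=30.0, seed=1)
        img1, t1 = render_cylinders((100.0, 0.0), (0.0, 0.0), cfg, diameter_mm=6.0, separation_mm=8.0)
        img2, t2 = render_cylinders((100.0, 0.0), (0.0, 0.0), cfg.replace(seed=2), diameter_mm=6.0, separation_mm=8.0)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        row = t1.table.iloc[0]
        r = (2 / 3) * row.radius_px
        m1, _, n = measure_disk_roi(img1, (row.x_true_px, row.y_true_px), r)
        m2, _, _ = measure_disk_roi(img2, (row.x_true_px, row.y_true_px), r)
        se = 30.0 / np.sqrt(n)
        assert abs(m1 - m2) < 6 * se  # two independent means: 3 SE each

    def test_out_of_frame_disks_rejected(self):
        cfg = small_config()
        with pytest.raises(InvalidConfigError):
            render_cylinders((100.0, 0.0), (12.0, 0.0), cfg, diameter_mm=6.0, separation_mm=8.0)


class TestIlluminationField:
    def test_uniform_is_one_everywhere(self):
        f = IlluminationField()
        v = f.evaluate(np.array([0.0, 100.0]), np.array([0.0, 50.0]), (256, 256))
        assert np.allclose(v, 1.0)

    def test_normalized_maximum_is_one(self):
        f = IlluminationField("radial_gaussian", {"sigma_frac": 0.3, "center_frac": (0.5, 0.5)})
        assert f.evaluate(127.5, 127.5, (256, 256)) == pytest.approx(1.0)

    def test_nonpositive_field_rejected(self):
        f = IlluminationField("separable_polynomial", {"coeffs_x": [1.0, 0.0], "coeffs_y": [1.0]})  # x crosses 0
        with pytest.raises(InvalidConfigError):
            f.evaluate(10.0, 10.0, (64, 64))
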