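"""Uniformity surface: pooling, fitting, normalization, iso-maps, profiles."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from phantomqa import (
    DetectedWell,
    FrameMismatchError,
    IsoMapSpec,
    detect_wells,
    fit_surface,
    iso_map,
    line_profiles,
    pool_samples,
    render_rud,
)
from phantomqa.scene import IlluminationField
from phantomqa.uniformity import UniformitySamples, check_same_frame

from .conftest import detection_params, small_config


def lattice_samples(field_fn, shape=(256, 256), n=22, margin=6.0, scale=20000.0):
    """Samples of an analytic field on a regular lattice of positions."""
    h, w = shape
    ax = np.linspace(margin, w - 1 - margin, n)
    xx, yy = np.meshgrid(ax, ax)
    z = scale * field_fn(xx, yy)
    return UniformitySamples(xx.ravel(), yy.ravel(), z.ravel(), shape), xx, yy


def radial_gaussian(sigma, cx=127.5, cy=127.5):
    return lambda x, y: np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))


class TestPoolSamples:
    def test_single_image_passthrough(self, small_rud):
        _, img, _, wells = small_rud
        s = pool_samples([wells], img.shape)
        assert len(s) == len(wells)

    def test_duplicate_images_average_idempotently(self, small_rud):
        """Pooling an image with itself merges coincident samples, giving
        the same surface as the single image."""
        _, img, _, wells = small_rud
        s1 = pool_samples([wells], img.shape)
        s2 = pool_samples([wells, wells], img.shape)
        assert len(s1) == len(s2)
        p1 = fit_surface(s1, smoothing=1e3)
        p2 = fit_surface(s2, smoothing=1e3)
        np.testing.assert_allclose(
            np.nan_to_num(p1.values), np.nan_to_num(p2.values), atol=1e-9
        )

    def test_offset_renders_pool_into_denser_sampling(self):
        """Four images of the target at different positions pool into more
        samples and a better (lower-RMSE) fit of the known illumination
        than a single image provides."""
        illum = IlluminationField("radial_gaussian", {"sigma_frac": 0.45})
        base = small_config(illumination=illum, noise_model="gaussian", noise_strength=1000.0)
        offsets = [(-0.5, -0.5), (0.5, -0.5), (-0.5, 0.5), (0.5, 0.5)]
        lists, truths = [], []
        for k, off in enumerate(offsets):
            cfg = base.replace(target_offset_mm=off, seed=k + 1)
            img, truth = render_rud(cfg)
            lists.append(detect_wells(img, detection_params(cfg)))
            truths.append(truth)
        pooled = pool_samples(lists, base.image_shape)
        single = pool_samples(lists[:1], base.image_shape)
        assert len(pooled) > len(single)

        def rmse(profile):
            t = truths[0].table
            pred = profile.evaluate(t.x_true_px.to_numpy(), t.y_true_px.to_numpy())
            true_n = t.illum.to_numpy() / t.illum.max()
            ok = np.isfinite(pred)
            return float(np.sqrt(np.mean((pred[ok] - true_n[ok]) ** 2)))

        assert rmse(fit_surface(pooled)) < rmse(fit_surface(single))

    def test_mixed_frames_rejected(self):
        with pytest.raises(FrameMismatchError):
            check_same_frame([(256, 256), (256, 300)])


class TestFitSurface:
    def test_constant_samples_normalize_to_one(self):
        s, xx, yy = lattice_samples(lambda x, y: np.ones_like(x), scale=0.8)
        prof = fit_surface(s)
        vals = prof.values[np.isfinite(prof.values)]
        np.testing.assert_allclose(vals, 1.0, atol=1e-6)

    def test_bspline_recovers_smooth_field_within_one_percent(self):
        """Noise-free dot-grid render of a radial-Gaussian illumination:
        the normalized b-spline surface matches the normalized truth to
        better than 1% RMS over the valid region."""
        illum = IlluminationField("radial_gaussian", {"sigma_frac": 0.45})
        cfg = small_config(illumination=illum, background_offset=0.0)
        img, truth = render_rud(cfg)
        wells = detect_wells(img, detection_params(cfg))
        prof = fit_surface(pool_samples([wells], img.shape), method="bspline")
        t = truth.table
        pred = prof.evaluate(t.x_true_px.to_numpy(), t.y_true_px.to_numpy())
        true_n = t.illum.to_numpy() / t.illum.max()
        ok = np.isfinite(pred)
        assert np.sqrt(np.mean((pred[ok] - true_n[ok]) ** 2)) < 0.01

    def test_rbf_retains_sharp_dip_bspline_smooths(self):
        """A ring-shaped dip in the illumination survives the RBF fit but is
        attenuated by the smoothing b-spline."""

        def dipped(x, y):
            r = np.hypot(x - 127.5, y - 127.5)
            return 1.0 - 0.4 * np.exp(-((r - 80) ** 2) / (2 * 15**2))

        s, xx, yy = lattice_samples(dipped, n=26)
        r = np.hypot(xx - 127.5, yy - 127.5)
        ring = (r > 70) & (r < 90)
        true_n = dipped(xx, yy)[ring] / dipped(xx, yy).max()

        def dip_resid(method):
            prof = fit_surface(s, method=method)
            pred = prof.evaluate(xx[ring], yy[ring])
            ok = np.isfinite(pred)
            return float(np.sqrt(np.mean((pred[ok] - true_n[ok]) ** 2)))

        assert dip_resid("rbf") < dip_resid("bspline")

    def test_gain_invariance_of_normalized_surface(self):
        s, _, _ = lattice_samples(radial_gaussian(100.0))
        s_scaled = UniformitySamples(s.x, s.y, s.intensity * 37.0, s.image_shape)
        p1 = fit_surface(s)
        p2 = fit_surface(s_scaled)
        np.testing.assert_allclose(np.nan_to_num(p1.values), np.nan_to_num(p2.values), atol=1e-6)

    def test_normalized_maximum_is_exactly_one(self):
        s, _, _ = lattice_samples(radial_gaussian(100.0))
        prof = fit_surface(s)
        assert np.nanmax(prof.values) == 1.0

    def test_too_few_samples_rejected(self):
        from phantomqa.errors import FitError

        s = UniformitySamples(np.arange(10.0), np.arange(10.0) % 3 * 5, np.full(10, 5.0), (64, 64))
        with pytest.raises(FitError):
            fit_surface(s)

    def test_csv_round_trip_evaluates_consistently(self, tmp_path):
        s, _, _ = lattice_samples(radial_gaussian(100.0))
        prof = fit_surface(s)
        prof.to_csv(tmp_path / "surf.csv", tmp_path / "surf.json")
        from phantomqa.uniformity import UniformityProfile

        back = UniformityProfile.from_csv(tmp_path / "surf.csv", tmp_path / "surf.json")
        pts = np.linspace(40, 200, 9)
        a = prof.evaluate(pts, pts)
        b = back.evaluate(pts, pts, extrapolate=True)
        np.testing.assert_allclose(a[np.isfinite(a)], b[np.isfinite(a)], atol=5e-3)


class TestIsoMap:
    def test_flat_profile_all_fractions_one(self):
        s, _, _ = lattice_samples(lambda x, y: np.ones_like(x))
        res = iso_map(fit_surface(s))
        assert all(f == 1.0 for f in res.fractions.values())

    def test_gaussian_level_set_area_matches_analytic(self):
        """For a radial Gaussian whose 60% level set fits inside the sampled
        square, the fraction above each threshold is the analytic disk area
        over the square area."""
        sigma = 55.0
        s, xx, _ = lattice_samples(radial_gaussian(sigma), n=40)
        prof = fit_surface(s, method="bspline")
        res = iso_map(prof)
        side = xx.max() - xx.min()
        for thr, measured in res.fractions.items():
            r_t = sigma * np.sqrt(2 * np.log(1 / thr))
            analytic = np.pi * r_t**2 / side**2
            assert measured == pytest.approx(analytic, abs=0.02)

    def test_threshold_masks_are_nested(self):
        s, _, _ = lattice_samples(radial_gaussian(100.0))
        res = iso_map(fit_surface(s), IsoMapSpec((0.3, 0.5, 0.7, 0.9)))
        ts = sorted(res.masks)
        for lo, hi in zip(ts, ts[1:]):
            assert np.all(res.masks[lo] | ~res.masks[hi])  # hi subset of lo

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            IsoMapSpec((0.95, 0.60))


class TestLineProfiles:
    def test_flat_profile_curves_at_one(self):
        s, _, _ = lattice_samples(lambda x, y: np.ones_like(x))
        profs = line_profiles(fit_surface(s), "horizontal")
        for df in profs.values():
            vals = df["value"].dropna()
            np.testing.assert_allclose(vals, 1.0, atol=1e-6)

    def test_separable_field_horizontal_curves_proportional_to_factor(self):
        fx = lambda x: 1.0 - 0.5 * ((x - 127.5) / 127.5) ** 2
        fy = lambda y: 1.0 - 0.3 * ((y - 127.5) / 127.5) ** 2
        s, _, _ = lattice_samples(lambda x, y: fx(x) * fy(y), n=30)
        profs = line_profiles(fit_surface(s), "horizontal", positions=(0.3, 0.6))
        for df in profs.values():
            df = df.dropna()
            ratio = df["value"].to_numpy() / fx(df["coord_px"].to_numpy())
            assert ratio.std() / ratio.mean() < 0.01

    def test_symmetric_field_center_profile_symmetric(self):
        s, _, _ = lattice_samples(radial_gaussian(90.0), n=30)
        profs = line_profiles(fit_surface(s), "vertical", positions=(0.5,))
        vals = profs[0.5]["value"].to_numpy()
        vals = vals[np.isfinite(vals)]
        assert np.max(np.abs(vals - vals[::-1])) < 0.01

    def test_invalid_positions_rejected(self):
        s, _, _ = lattice_samples(radial_gaussian(90.0))
        with pytest.raises(ValueError):
            line_profiles(fit_surface(s), "horizontal", positions=(1.5,))
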