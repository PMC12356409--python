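import numpy as np
import pytest

import embryograd as eg
from embryograd.profiles import PCT_EL

from conftest import ap_ztsh2_profile


def _integral_bin_mean(gp, background, d_lo, d_hi, n=2001):
    """Oracle: exact bin average of background + gradient over [d_lo, d_hi)."""
    d = np.linspace(d_lo, d_hi, n)
    return background + np.trapezoid(gp(d), d) / (d_hi - d_lo)


class TestApLineProfile:
    def test_constant_image_gives_constant_bins(self):
        img = np.full((60, 120), 42.0)
        scene = eg.ImageScene(img, "YX", pixel_size_um=1.0)
        geo = eg.EmbryoGeometry((30.0, 5.0), (30.0, 115.0), 110.0)
        prof = eg.ap_line_profile(scene, geo, width_px=20, n_bins=50)
        assert np.all(prof.values[prof.defined] == 42.0)
        assert prof.defined.all()

    def test_gradient_bin_matches_closed_form(self):
        """Noise-free plateau-25/decay-20 gradient over background 60: the
        bin at 9 %EL (45-50 um from the pole) must equal the exact bin
        average of 60 + 100*exp(-(d-25)/20), close to the bin-edge value
        60 + 100/e ~ 96.8."""
        gp = eg.GradientParams(25.0, 20.0, 100.0)
        cfg = eg.SceneConfig(torso=gp, erk=gp, cytosol_background=60.0, dperk_background=60.0, seed=0)
        scene, truth = eg.render_embryo(cfg)
        # the downstream channel carries the gradient across the full
        # cytoplasm, so bin values follow the closed form directly
        prof = eg.ap_line_profile(
            scene, truth.geometry, channel="dperk", exclude_mask=truth.exclusion_mask()
        )
        oracle = _integral_bin_mean(gp, 60.0, 45.0, 50.0)
        assert prof.values[9] == pytest.approx(oracle, rel=0.01)
        assert prof.values[9] == pytest.approx(60.0 + 100.0 * np.exp(-1.0), abs=5.0)

    def test_unimaged_ends_undefined(self, wt_scene):
        scene, truth = wt_scene
        prof = eg.ap_line_profile(scene, truth.geometry, channel="ztsh2")
        # generator default images 98% of each half-axis: 1 %EL lost per end
        assert np.isnan(prof.values[0]) and np.isnan(prof.values[99])
        assert prof.defined[1] and prof.defined[98]

    def test_mean_conservation(self):
        """Mean of defined bins ~ mean of the band pixels used (uniform
        band coverage; noise off)."""
        rng = np.random.default_rng(7)
        yy, xx = np.mgrid[0:80, 0:500].astype(float)
        img = 50.0 + 0.3 * xx + 10.0 * np.sin(xx / 30.0) + rng.normal(0, 0.0, (80, 500))
        scene = eg.ImageScene(img, "YX", pixel_size_um=1.0)
        geo = eg.EmbryoGeometry((40.0, 0.0), (40.0, 499.999), 500.0)
        prof = eg.ap_line_profile(scene, geo, width_px=40, n_bins=100)
        band_mean = prof.provenance["band_pixel_mean"]
        assert np.nanmean(prof.values) == pytest.approx(band_mean, rel=0.005)

    def test_bin_count_invariance(self, wt_scene):
        """Doubling n_bins then block-averaging pairs reproduces the
        coarser profile within interpolation tolerance."""
        scene, truth = wt_scene
        ex = truth.exclusion_mask()
        p100 = eg.ap_line_profile(scene, truth.geometry, channel="dperk", n_bins=100, exclude_mask=ex)
        p200 = eg.ap_line_profile(scene, truth.geometry, channel="dperk", n_bins=200, exclude_mask=ex)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            paired = np.nanmean(p200.values.reshape(100, 2), axis=1)
        both = p100.defined & ~np.isnan(paired)
        np.testing.assert_allclose(paired[both], p100.values[both], rtol=0.01)

    def test_degenerate_band_rejected(self, wt_scene):
        scene, truth = wt_scene
        with pytest.raises(ValueError, match="width"):
            eg.ap_line_profile(scene, truth.geometry, width_px=0)


class TestPerimeterProfile:
    def test_uniform_embryo_flat_profile(self):
        zero = eg.GradientParams(10.0, 10.0, 0.0)
        cfg = eg.SceneConfig(torso=zero, erk=zero, cytosol_background=70.0, view="sagittal", seed=0)
        scene, truth = eg.render_embryo(cfg)
        prof = eg.perimeter_profile(
            scene, truth.geometry, channel="ztsh2", contour_mask=truth.embryo_mask
        )
        assert np.allclose(prof.values[prof.defined], 70.0, rtol=1e-6)

    def test_two_elevated_runs_at_pole_arc_positions(self, sagittal_scene):
        scene, truth = sagittal_scene
        prof = eg.perimeter_profile(
            scene, truth.geometry, channel="ztsh2", contour_mask=truth.embryo_mask
        )
        bg = truth.parameters.cytosol_background
        peak = truth.parameters.torso_pair[1].peak_level
        elevated = prof.values > bg + 0.5 * peak
        # exactly two contiguous circular runs of elevated bins
        n_runs = int(np.sum(elevated & ~np.roll(elevated, 1)))
        assert n_runs == 2
        bin_ant, bin_post = prof.provenance["pole_bins"]
        assert elevated[bin_ant] and elevated[bin_post]

    def test_zero_gradient_profile_flat_at_background(self):
        zero = eg.GradientParams(10.0, 10.0, 0.0)
        cfg = eg.SceneConfig(torso=zero, erk=zero, view="sagittal", seed=11)
        scene, truth = eg.render_embryo(cfg)
        prof = eg.perimeter_profile(
            scene, truth.geometry, channel="ztsh2", contour_mask=truth.embryo_mask
        )
        bg = truth.parameters.cytosol_background
        np.testing.assert_allclose(prof.values[prof.defined], bg, rtol=1e-6)


class TestSubtractCenterBackground:
    def test_constant_profile_becomes_zero(self):
        prof = eg.BinnedProfile(np.full(100, 7.5))
        out = eg.subtract_center_background(prof)
        assert np.allclose(out.values, 0.0)
        assert out.background_subtracted

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 50, 100)
        a = eg.subtract_center_background(eg.BinnedProfile(base))
        b = eg.subtract_center_background(eg.BinnedProfile(base + 13.25))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_split_centers_each_half(self):
        base = np.concatenate([np.full(50, 30.0), np.full(50, 20.0)])
        out = eg.subtract_center_background(eg.BinnedProfile(base), split_ap=True)
        assert np.allclose(out.values, 0.0)
        bg_a, bg_p = out.provenance["center_background_au"]
        assert (bg_a, bg_p) == (30.0, 20.0)

    def test_double_subtraction_rejected(self):
        prof = eg.subtract_center_background(eg.BinnedProfile(np.ones(100)))
        with pytest.raises(ValueError, match="already"):
            eg.subtract_center_background(prof)

    def test_all_center_bins_undefined_rejected(self):
        vals = np.ones(100)
        vals[30:70] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            eg.subtract_center_background(eg.BinnedProfile(vals))


class TestCenterBoxBackground:
    def test_series_ratios_to_nc11(self):
        series = {"NC11": 60.0, "NC12": 75.0, "NC13": 95.0, "NC14": 130.0}
        ratios = eg.normalize_background_series(series)
        assert ratios["NC11"] == 1.0
        assert ratios["NC12"] == pytest.approx(1.25)
        assert ratios["NC13"] == pytest.approx(95 / 60)
        assert ratios["NC14"] == pytest.approx(130 / 60)

    def test_all_equal_series_all_unity(self):
        assert set(eg.normalize_background_series([5.0, 5.0, 5.0]).values()) == {1.0}

    def test_yolk_mask_recovers_clean_background(self):
        """A bright yolk granule under the box biases the mean unless the
        yolk mask is supplied."""
        cfg = eg.SceneConfig(
            nc_stage="NC12", seed=5, yolk_count=60, yolk_level=800.0
        )
        scene, truth = eg.render_embryo(cfg)
        h, w = scene.pixels.shape[-2:]
        box = eg.RoiBox((h / 2, w / 2), side_um=50.0, purpose="center background")
        sl = box.slices(scene.pixel_size_um, (h, w))
        assert truth.yolk_mask[sl].any(), "fixture must place yolk under the box"
        clean = eg.center_box_background(scene, box, yolk_mask=truth.yolk_mask, channel="ztsh2")
        dirty = eg.center_box_background(scene, box, channel="ztsh2")
        assert clean == pytest.approx(truth.parameters.cytosol_background, rel=0.01)
        assert dirty > clean + 10


class TestBoxPairQuant:
    def _scene(self, img):
        return eg.ImageScene(img, "YX", pixel_size_um=1.0)

    def test_flat_image_gives_zero(self):
        scene = self._scene(np.full((150, 150), 90.0))
        a = eg.RoiBox((40.0, 40.0), 25.0)
        b = eg.RoiBox((110.0, 110.0), 25.0)
        assert eg.box_pair_quant(scene, a, b) == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_offset_over_smooth_background(self):
        """Signal spot +80 AU on a tilted background removed equally from
        both boxes by the rolling ball."""
        yy, xx = np.mgrid[0:150, 0:150].astype(float)
        img = 100.0 + 0.1 * xx
        spot = (yy - 40) ** 2 + (xx - 40) ** 2 <= 18**2
        img[spot] += 80.0
        scene = self._scene(img)
        a = eg.RoiBox((40.0, 40.0), 25.0, "signal")
        b = eg.RoiBox((110.0, 110.0), 25.0, "background")
        out = eg.box_pair_quant(scene, a, b)
        assert out == pytest.approx(80.0, rel=0.10)

    def test_swapping_boxes_flips_sign(self):
        rng = np.random.default_rng(3)
        scene = self._scene(rng.uniform(50, 60, (150, 150)))
        a = eg.RoiBox((40.0, 40.0), 25.0)
        b = eg.RoiBox((110.0, 110.0), 25.0)
        assert eg.box_pair_quant(scene, a, b) == pytest.approx(
            -eg.box_pair_quant(scene, b, a), abs=1e-9
        )

    def test_overlapping_boxes_warn(self):
        scene = self._scene(np.zeros((100, 100)))
        a = eg.RoiBox((50.0, 50.0), 25.0)
        b = eg.RoiBox((55.0, 55.0), 25.0)
        with pytest.warns(UserWarning, match="overlap"):
            eg.box_pair_quant(scene, a, b)


class TestProfileCsv:
    def test_round_trip_preserves_values_and_flags(self, tmp_path, wt_scene):
        scene, truth = wt_scene
        prof = ap_ztsh2_profile(scene, truth)
        path = tmp_path / "profile.csv"
        prof.to_csv(path)
        # undefined bins are empty cells, not zeros
        text = path.read_text().splitlines()
        assert text[1].endswith(",")
        back = eg.BinnedProfile.from_csv(path)
        np.testing.assert_allclose(back.values, prof.values, equal_nan=True)
        assert back.background_subtracted
        assert back.axis_kind == PCT_EL
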