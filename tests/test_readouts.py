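import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import embryograd as eg


class TestApicalEnrichment:
    def _lines(self, n=12):
        apical = np.column_stack([np.full(n, 2.0), np.arange(n, dtype=float)])
        cyto = np.column_stack([np.full(n, 6.0), np.arange(n, dtype=float)])
        return apical, cyto

    def test_equal_lines_ratio_one(self):
        img = np.full((10, 15), 50.0)
        apical, cyto = self._lines()
        out = eg.apical_enrichment(img, apical, cyto, line_width_px=1, bin_px=3)
        np.testing.assert_allclose(out, 1.0)

    def test_double_membrane_ratio_two(self):
        img = np.full((10, 15), 40.0)
        img[:4] = 80.0
        apical, cyto = self._lines()
        out = eg.apical_enrichment(img, apical, cyto, line_width_px=1, bin_px=3)
        np.testing.assert_allclose(out, 2.0)

    def test_block_means(self):
        """Per-position ratios [1,2,3,4,4,4] with 3-px blocks -> [2, 4]."""
        img = np.zeros((10, 6))
        img[2] = [10.0, 20.0, 30.0, 40.0, 40.0, 40.0]
        img[6] = 10.0
        apical, cyto = self._lines(6)
        out = eg.apical_enrichment(img, apical, cyto, line_width_px=1, bin_px=3)
        np.testing.assert_allclose(out, [2.0, 4.0])

    def test_zero_cytoplasm_position_excluded(self):
        img = np.full((10, 6), 30.0)
        img[6, 2] = 0.0  # one invalid cytoplasmic position
        apical, cyto = self._lines(6)
        out = eg.apical_enrichment(img, apical, cyto, line_width_px=1, bin_px=3)
        np.testing.assert_allclose(out, 1.0)  # excluded from its block mean


class TestTiledPearson:
    def _axis(self, shape, n, side_px):
        return ((shape[0] / 2, side_px / 2), (shape[0] / 2, shape[1] - side_px / 2))

    def test_identical_channels_r_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 100, (20, 140))
        pr = eg.tiled_pearson(a, a, self._axis(a.shape, 8, 15), 8, box_side_um=4.5, pixel_size_um=0.3)
        np.testing.assert_allclose(pr.correlations, 1.0, atol=1e-12)

    def test_negated_channel_r_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 100, (20, 140))
        b = -a + 250.0
        pr = eg.tiled_pearson(a, b, self._axis(a.shape, 8, 15), 8, box_side_um=4.5, pixel_size_um=0.3)
        np.testing.assert_allclose(pr.correlations, -1.0, atol=1e-12)

    def test_hand_computed_r(self):
        """Textbook Pearson on a 2x2 box: A=[1,2,3,4], B=[1,3,2,5]."""
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[1.0, 3.0], [2.0, 5.0]])
        A = np.tile(a, (4, 7))  # 8x14 image so boxes fit
        B = np.tile(b, (4, 7))
        # hand calculation
        xa, xb = a.ravel(), b.ravel()
        r_hand = np.sum((xa - xa.mean()) * (xb - xb.mean())) / np.sqrt(
            np.sum((xa - xa.mean()) ** 2) * np.sum((xb - xb.mean()) ** 2)
        )
        pr = eg.tiled_pearson(
            A, B, ((4.0, 1.0), (4.0, 13.0)), 7, box_side_um=2.0, pixel_size_um=1.0
        )
        # every 2x2-periodic box contains the same joint distribution
        np.testing.assert_allclose(pr.correlations, r_hand, atol=1e-9)

    def test_zero_variance_box_reported_missing(self):
        a = np.zeros((20, 140))
        b = np.ones((20, 140))
        pr = eg.tiled_pearson(a, b, self._axis(a.shape, 7, 15), 7, box_side_um=4.5, pixel_size_um=0.3)
        assert np.all(np.isnan(pr.correlations))

    def test_box_count_bounds(self):
        a = np.zeros((20, 140))
        with pytest.raises(ValueError, match="n_boxes"):
            eg.tiled_pearson(a, a, self._axis(a.shape, 6, 15), 6, pixel_size_um=0.3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        gain=st.floats(-3, 3).filter(lambda g: abs(g) > 1e-3),
        offset=st.floats(-50, 50),
        seed=st.integers(0, 1000),
    )
    def test_affine_covariance(self, gain, offset, seed):
        """r(A, gain*B + offset) = sign(gain) * r(A, B), and |r| <= 1."""
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 100, (16, 120))
        b = rng.uniform(0, 100, (16, 120)) + 0.5 * a
        axis = ((8.0, 8.0), (8.0, 112.0))
        r1 = eg.tiled_pearson(a, b, axis, 8, box_side_um=4.0, pixel_size_um=1.0).correlations
        r2 = eg.tiled_pearson(a, gain * b + offset, axis, 8, box_side_um=4.0, pixel_size_um=1.0).correlations
        assert np.all(np.abs(r1) <= 1.0 + 1e-12)
        np.testing.assert_allclose(r2, np.sign(gain) * r1, atol=1e-9)


def _nucleus_grid(shape=(60, 200), radius=3, spacing=12):
    labels = np.zeros(shape, dtype=np.int64)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    lab = 0
    for cy in range(spacing, shape[0] - spacing, spacing):
        for cx in range(spacing, shape[1] - spacing, spacing):
            lab += 1
            labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = lab
    return labels


class TestCytoNuclearRatio:
    GEO = eg.EmbryoGeometry((30.0, 0.0), (30.0, 199.0), 200.0)

    def test_uniform_image_unit_ratio(self):
        labels = _nucleus_grid()
        img = np.full(labels.shape, 80.0)
        prof = eg.cyto_nuclear_ratio(img, labels, self.GEO, pixel_size_um=1.0)
        np.testing.assert_allclose(prof.ratios[~np.isnan(prof.ratios)], 1.0)

    def test_constructed_export_ratio_two(self):
        """Reporter exported from nuclei: nuclear 40 AU, surround 80 AU."""
        labels = _nucleus_grid()
        img = np.full(labels.shape, 80.0)
        img[labels > 0] = 40.0
        prof = eg.cyto_nuclear_ratio(img, labels, self.GEO, pixel_size_um=1.0)
        np.testing.assert_allclose(prof.ratios[~np.isnan(prof.ratios)], 2.0)

    def test_scale_invariance(self):
        labels = _nucleus_grid()
        rng = np.random.default_rng(4)
        img = rng.uniform(20, 120, labels.shape)
        a = eg.cyto_nuclear_ratio(img, labels, self.GEO, pixel_size_um=1.0).ratios
        b = eg.cyto_nuclear_ratio(3.7 * img, labels, self.GEO, pixel_size_um=1.0).ratios
        np.testing.assert_allclose(a, b, equal_nan=True, rtol=1e-12)

    def test_terminal_mutant_scene_all_nuclear(self):
        """No terminal kinase activity: reporter nuclear everywhere, so all
        ratios < 1 and the ERK-off fraction is 1."""
        zero = eg.GradientParams(10.0, 10.0, 0.0)
        cfg = eg.SceneConfig(torso=zero, erk=zero, seed=9)
        scene, truth = eg.render_embryo(cfg)
        prof = eg.cyto_nuclear_ratio(
            scene.plane("minicic"), truth.nuclear_mask, truth.geometry,
            pixel_size_um=scene.pixel_size_um,
        )
        defined = prof.ratios[~np.isnan(prof.ratios)]
        assert np.all(defined < 1.0)
        assert eg.erk_off_fraction(prof) == 1.0

    def test_wild_type_scene_poles_cytoplasmic(self, wt_scene):
        scene, truth = wt_scene
        prof = eg.cyto_nuclear_ratio(
            scene.plane("minicic"), truth.nuclear_mask, truth.geometry,
            pixel_size_um=scene.pixel_size_um,
        )
        defined = np.nonzero(~np.isnan(prof.ratios))[0]
        assert prof.ratios[defined[0]] > 1.0  # anterior pole: kinase on
        assert np.nanmean(prof.ratios[20:30]) < 1.0  # center: off
        norm = prof.normalized()
        assert np.nanmean(norm[20:30]) == pytest.approx(0.0, abs=0.05)
        assert norm[defined[0]] == pytest.approx(1.0)


class TestErkOffFraction:
    def _prof(self, ratios):
        return eg.NuclearRatioProfile(ratios=np.asarray(ratios, dtype=float), n_bins=len(ratios))

    def test_all_nuclear_is_one(self):
        assert eg.erk_off_fraction(self._prof([0.5] * 50)) == 1.0

    def test_all_cytoplasmic_is_zero(self):
        assert eg.erk_off_fraction(self._prof([2.0] * 50)) == 0.0

    def test_partial_fraction(self):
        ratios = [2.0] * 10 + [0.5] * 40
        assert eg.erk_off_fraction(self._prof(ratios)) == pytest.approx(0.8)


class TestDetectBursts:
    GEO = eg.EmbryoGeometry((50.0, 0.0), (50.0, 199.0), 200.0)

    def test_blank_image_empty_table(self):
        table = eg.detect_bursts(np.zeros((100, 200)), 10.0, self.GEO, pixel_size_um=1.0)
        assert len(table) == 0

    def test_placement_and_binning(self):
        """Spots at 10, 22, 48 um from the posterior pole land in the
        [10,15), [20,25) and [45,50) bins."""
        img = np.zeros((100, 200))
        for d in (10, 22, 48):
            img[50, 199 - d] = 100.0
            img[51, 199 - d] = 100.0  # 2-px spots pass the size filter
        table = eg.detect_bursts(img, 50.0, self.GEO, min_spot_px=2, pixel_size_um=1.0)
        assert len(table) == 3
        edges, counts = table.histogram()
        assert counts.sum() == 3
        hist = dict(zip(edges[:-1], counts))
        assert hist[10.0] == 1 and hist[20.0] == 1 and hist[45.0] == 1

    def test_touching_spots_merge(self):
        img = np.zeros((100, 200))
        img[50, 100:104] = 100.0  # one connected run
        table = eg.detect_bursts(img, 50.0, self.GEO, pixel_size_um=1.0)
        assert len(table) == 1

    def test_size_filter(self):
        img = np.zeros((100, 200))
        img[50, 100] = 100.0  # single-pixel speckle
        table = eg.detect_bursts(img, 50.0, self.GEO, min_spot_px=2, pixel_size_um=1.0)
        assert len(table) == 0

    def test_count_conservation_on_synthetic_scene(self):
        positions = tuple(float(d) for d in range(5, 90, 7))
        cfg = eg.SceneConfig(seed=6, burst_positions_um=positions)
        scene, truth = eg.render_embryo(cfg)
        table = eg.detect_bursts(scene, 150.0, truth.geometry, channel="ms2")
        assert len(table) == len(positions)
        _, counts = table.histogram()
        assert counts.sum() == len(table)
        assert table.max_distance_um() == pytest.approx(max(positions), abs=1.0)
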