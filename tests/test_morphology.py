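"""Otsu thresholding, vegetation segmentation, HSI, VCEA, CHM and H/CC/CV."""

import numpy as np
import pytest

import uavpheno as up
from uavpheno.errors import (
    DegenerateInputError,
    DegenerateSceneWarning,
    EmptyMaskWarning,
    ValidationError,
)


def brute_force_otsu(values, bins=256):
    """Independent oracle: score all 255 histogram cuts directly."""
    v = np.asarray(values, float).ravel()
    v = v[np.isfinite(v)]
    hist, edges = np.histogram(v, bins=bins, range=(v.min(), v.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    scores = []
    for t in range(bins - 1):
        n0 = hist[: t + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            scores.append(0.0)
        else:
            mu0 = (hist[: t + 1] * centers[: t + 1]).sum() / n0
            mu1 = (hist[t + 1 :] * centers[t + 1 :]).sum() / n1
            scores.append((n0 / total) * (n1 / total) * (mu0 - mu1) ** 2)
    best = max(scores)
    # smallest maximizer, with the same plateau tolerance as the implementation
    for t, s in enumerate(scores):
        if s >= best - 1e-9 * max(1.0, abs(best)):
            return float(edges[t + 1])


class TestOtsu:
    def test_two_valued_input(self):
        vals = np.array([10.0] * 50 + [200.0] * 50)
        thr = up.otsu_threshold(vals)
        assert 10 < thr < 200
        assert ((vals > thr) == (vals == 200.0)).all()

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            up.otsu_threshold(np.full(10, 3.0))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        if kind == 0:
            vals = rng.normal(size=500)
        elif kind == 1:
            vals = np.concatenate([rng.normal(-1, 0.3, 300), rng.normal(2, 0.5, 200)])
        else:
            vals = rng.integers(0, 50, size=400).astype(float)
        assert up.otsu_threshold(vals) == brute_force_otsu(vals)

    def test_bimodal_misclassification_below_one_percent(self):
        rng = np.random.default_rng(1)
        soil = rng.normal(-0.1, 0.03, 5000)
        veg = rng.normal(0.3, 0.05, 5000)
        vals = np.concatenate([soil, veg])
        labels = np.concatenate([np.zeros(5000, bool), np.ones(5000, bool)])
        thr = up.otsu_threshold(vals)
        assert ((vals > thr) != labels).mean() < 0.01

    def test_against_skimage(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(40, 8, 1000), rng.normal(170, 15, 800)])
        bin_width = (vals.max() - vals.min()) / 256
        assert abs(up.otsu_threshold(vals) - threshold_otsu(vals, nbins=256)) <= bin_width


class TestSegmentation:
    def test_zero_noise_recovers_truth_mask(self, s1_zero_noise_scene):
        seg = up.segment_vegetation_uav(s1_zero_noise_scene["dom"])
        assert np.array_equal(seg.values, s1_zero_noise_scene["mask"].values)

    def test_bare_scene_flagged_empty(self, design):
        dom, _, _ = up.render_bare_scene(design, seed=40, dn_jitter_sd=0.0)
        with pytest.warns(DegenerateSceneWarning):
            seg = up.segment_vegetation_uav(dom)
        assert not seg.values.any()

    def test_noisy_scene_pixel_accuracy(self, s1_scene):
        seg = up.segment_vegetation_uav(s1_scene["dom"])
        acc = (seg.values == s1_scene["mask"].values).mean()
        assert acc >= 0.98


class TestHSI:
    def to_grid(self, triple):
        return up.RasterGrid(values=np.array(triple, dtype=np.uint8).reshape(1, 1, 3), units="DN8")

    def test_gray(self):
        hsi = up.rgb_to_hsi(self.to_grid((128, 128, 128)))
        assert hsi.saturation[0, 0] == 0
        assert not hsi.hue_valid[0, 0]
        assert hsi.intensity[0, 0] == pytest.approx(0.502, abs=1e-3)

    @pytest.mark.parametrize(
        "triple, hue, sat",
        [((0, 255, 0), 120.0, 1.0), ((0, 0, 255), 240.0, 1.0), ((255, 0, 0), 0.0, 1.0)],
    )
    def test_primary_colors(self, triple, hue, sat):
        hsi = up.rgb_to_hsi(self.to_grid(triple))
        assert hsi.hue[0, 0] == pytest.approx(hue, abs=1e-6)
        assert hsi.saturation[0, 0] == pytest.approx(sat, abs=1e-9)

    def test_ranges_on_random(self):
        rng = np.random.default_rng(5)
        grid = up.RasterGrid(values=rng.integers(0, 256, (16, 16, 3), dtype=np.uint8), units="DN8")
        hsi = up.rgb_to_hsi(grid)
        assert ((hsi.hue >= 0) & (hsi.hue < 360)).all()
        assert ((hsi.saturation >= -1e-9) & (hsi.saturation <= 1 + 1e-9)).all()
        assert ((hsi.intensity >= 0) & (hsi.intensity <= 1)).all()


@pytest.fixture(scope="module")
def quiet_truth(design):
    t = up.sample_truth(design, "S1", seed=50, dn_jitter_sd=0.0)
    up.render_scene(t, seed=51)  # back-fill achievable coverage
    return t


class TestVCEA:
    def test_zero_noise_coverage_recovery(self, quiet_truth):
        ti = quiet_truth.plots.set_index("plot_id")
        for pid in ("s01", "s20", "s44"):
            photo = up.render_ground_photo(quiet_truth, pid, seed=52)
            cc = up.coverage_from_mask(up.vcea_ground_mask(photo))
            assert cc == pytest.approx(ti.loc[pid, "true_cc"], abs=0.005)

    def test_weed_specks_removed(self, quiet_truth):
        clean = up.render_ground_photo(quiet_truth, "s10", seed=53)
        weedy = up.render_ground_photo(quiet_truth, "s10", seed=53, n_weed_specks=10)
        cc_clean = up.coverage_from_mask(up.vcea_ground_mask(clean))
        cc_weedy = up.coverage_from_mask(up.vcea_ground_mask(weedy))
        assert cc_weedy == pytest.approx(cc_clean, abs=0.005)

    def test_all_soil_photo_empty_mask(self, design):
        t = up.sample_truth(design, "S1", seed=54, dn_jitter_sd=0.0)
        t.plots["true_cc"] = 0.0
        photo = up.render_ground_photo(t, "s01", seed=55)
        with pytest.warns((EmptyMaskWarning, DegenerateSceneWarning)):
            mask = up.vcea_ground_mask(photo)
        interior = mask.values != mask.nodata
        assert not mask.values[interior].any()


class TestCoverage:
    def test_extremes(self):
        ones = up.RasterGrid(values=np.ones((5, 5), dtype=np.uint8), units="binary")
        zeros = up.RasterGrid(values=np.zeros((5, 5), dtype=np.uint8), units="binary")
        assert up.coverage_from_mask(ones) == 1.0
        assert up.coverage_from_mask(zeros) == 0.0

    def test_truth_mask_reproduces_truth(self, s1_scene, design, truth_index):
        for poly, rec in design[:8]:
            cc = up.coverage_from_mask(s1_scene["mask"], region=poly)
            assert cc == pytest.approx(truth_index.loc[rec.plot_id, "true_cc"], abs=1e-12)

    def test_zero_valid_pixels_rejected(self):
        empty = up.RasterGrid(values=np.full((3, 3), 9, dtype=np.uint8), nodata=9)
        with pytest.raises(DegenerateInputError):
            up.coverage_from_mask(empty)


class TestCHM:
    def grid(self, vals):
        return up.RasterGrid(values=np.asarray(vals, float), units="m")

    def test_self_difference_is_zero(self):
        dsm = self.grid(np.random.default_rng(0).normal(36, 0.2, (10, 10)))
        chm = up.canopy_height_model(dsm, dsm)
        assert (chm.values == 0).all()

    def test_subtraction_and_clamp(self):
        stage = self.grid([[36.45, 36.13]])
        bare = self.grid([[36.15, 36.15]])
        chm = up.canopy_height_model(stage, bare)
        assert chm.values[0, 0] == pytest.approx(0.30)
        assert chm.values[0, 1] == 0.0  # 2 cm below bare soil, clamped

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            up.canopy_height_model(self.grid(np.zeros((3, 3))), self.grid(np.zeros((4, 3))))

    def test_transform_mismatch_rejected(self):
        a = up.RasterGrid(values=np.zeros((3, 3)), transform=up.Affine.identity(), units="m")
        b = up.RasterGrid(values=np.zeros((3, 3)), transform=up.Affine.north_up(0, 0, 2.0), units="m")
        with pytest.raises(ValidationError):
            up.canopy_height_model(a, b)


class TestPlotHeight:
    def test_constant_chm(self):
        chm = up.RasterGrid(values=np.full((20, 20), 0.30), transform=up.Affine.north_up(0.5, 19.5, 1.0), units="m")
        mask = up.RasterGrid(values=np.ones((20, 20), dtype=np.uint8), transform=chm.transform, units="binary")
        poly = up.PlotPolygon(plot_id="p", ring=[(0, 0), (10, 0), (10, 10), (0, 10)])
        assert up.plot_height(chm, poly, mask=mask) == pytest.approx(30.0)

    def test_zero_noise_scene_within_one_percent(self, s1_zero_noise_scene, design):
        scn = s1_zero_noise_scene
        chm = up.canopy_height_model(scn["dsm"], scn["bare"])
        seg = up.segment_vegetation_uav(scn["dom"])
        ti = scn["truth"].plots.set_index("plot_id")
        for poly, rec in design[:10]:
            h = up.plot_height(chm, poly, mask=seg)
            assert h == pytest.approx(ti.loc[rec.plot_id, "true_h_cm"], rel=0.01)

    def test_p90_exceeds_mean_on_skewed(self):
        vals = np.zeros((20, 20))
        vals[:5] = 0.5
        chm = up.RasterGrid(values=vals, transform=up.Affine.north_up(0.5, 19.5, 1.0), units="m")
        poly = up.PlotPolygon(plot_id="p", ring=[(0, 0), (20, 0), (20, 20), (0, 20)])
        assert up.plot_height(chm, poly, stat="p90") > up.plot_height(chm, poly, stat="mean")

    def test_empty_mask_falls_back_with_warning(self):
        chm = up.RasterGrid(values=np.full((10, 10), 0.2), transform=up.Affine.north_up(0.5, 9.5, 1.0), units="m")
        mask = up.RasterGrid(values=np.zeros((10, 10), dtype=np.uint8), transform=chm.transform, units="binary")
        poly = up.PlotPolygon(plot_id="p", ring=[(0, 0), (5, 0), (5, 5), (0, 5)])
        with pytest.warns(EmptyMaskWarning):
            h = up.plot_height(chm, poly, mask=mask)
        assert h == pytest.approx(20.0)


class TestCanopyVolume:
    @pytest.mark.parametrize("cc, h, expected", [(0.5, 30.0, 15.0), (1.0, 27.3, 27.3), (0.0, 30.0, 0.0)])
    def test_product(self, cc, h, expected):
        assert up.canopy_volume(cc, h) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            up.canopy_volume(1.2, 10.0)
        with pytest.raises(ValidationError):
            up.canopy_volume(0.5, -1.0)

    def test_morphological_features_invariants(self, s1_scene, design):
        seg = up.segment_vegetation_uav(s1_scene["dom"])
        chm = up.canopy_height_model(s1_scene["dsm"], s1_scene["bare"])
        table = up.morphological_features(chm, seg, design[:6], "S1")
        assert np.allclose(table["CV"], table["CC"] * table["H_cm"], atol=1e-9)
        assert (table["CV"] <= table["H_cm"] + 1e-9).all()
        assert table["CC"].between(0, 1).all()
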