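"""Pixel classification, canopy coverage and plant-height extraction."""

import numpy as np
import pytest
from shapely.geometry import box

from phenofuse import (Affine, CLASS_CODES, PlotIndex, RasterGrid,
                       classify_pixels, compute_coverage,
                       compute_plant_height, train_pixel_classifier)
from phenofuse.canopy import maize_mask
from phenofuse.geo import AlignmentError

CLUSTER_COLORS = {
    "maize": (45, 90, 35),
    "soil": (110, 90, 65),
    "shadow": (28, 24, 18),
    "other": (228, 222, 210),
}


def cluster_pixels(n_per_class=200, noise=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for name, color in CLUSTER_COLORS.items():
        X.append(rng.normal(color, noise, size=(n_per_class, 3)))
        y.append(np.full(n_per_class, CLASS_CODES[name]))
    return np.clip(np.vstack(X), 0, 255), np.concatenate(y)


class TestPixelClassifier:
    def test_separable_clusters_high_heldout_accuracy(self):
        X, y = cluster_pixels(400, seed=0)
        tr = np.arange(len(y)) % 2 == 0
        clf = train_pixel_classifier(X[tr], y[tr])
        acc = (clf.predict_codes(X[~tr]) == y[~tr]).mean()
        assert acc >= 0.99

    def test_training_pixels_reclassified_perfectly(self):
        X, y = cluster_pixels(100, noise=1.0, seed=1)
        clf = train_pixel_classifier(X, y)
        assert clf.training_accuracy == 1.0
        assert (clf.predict_codes(X) == y).all()

    def test_single_class_rejected(self):
        X, _ = cluster_pixels(50, seed=2)
        with pytest.raises(ValueError, match="two classes"):
            train_pixel_classifier(X[:50], np.zeros(50))

    def test_too_few_samples_per_class_rejected(self):
        X, y = cluster_pixels(10, seed=3)
        with pytest.raises(ValueError, match="20 samples"):
            train_pixel_classifier(X, y)

    def test_constant_colour_degenerate_input_rejected(self):
        X = np.full((80, 3), 100.0)
        y = np.repeat([0, 1], 40)
        with pytest.raises(ValueError, match="degenerate"):
            train_pixel_classifier(X, y)

    def test_classify_pure_cluster_raster_exact(self):
        X, y = cluster_pixels(200, noise=2.0, seed=4)
        clf = train_pixel_classifier(X, y)
        h, w = 8, 10
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 4, size=(h, w))
        arr = np.zeros((3, h, w))
        for name, color in CLUSTER_COLORS.items():
            m = codes == CLASS_CODES[name]
            for i in range(3):
                arr[i][m] = color[i]
        raster = RasterGrid(bands={"red": arr[0], "green": arr[1],
                                   "blue": arr[2]},
                            transform=Affine.from_origin(0, h, 1.0))
        out = classify_pixels(clf, raster)
        np.testing.assert_array_equal(out.band("class"), codes)

    def test_synthetic_scene_pixel_accuracy(self, small_scene,
                                            small_classifier):
        st = small_scene.stages[56]
        out = classify_pixels(small_classifier, st.rgb)
        acc = (out.band("class") == st.labels.band("class")).mean()
        assert acc >= 0.95

    def test_nodata_classified_as_other(self):
        X, y = cluster_pixels(100, seed=6)
        clf = train_pixel_classifier(X, y)
        arr = np.full((3, 4, 4), 45.0)
        arr[:, 0, 0] = -1.0
        raster = RasterGrid(bands={"red": arr[0], "green": arr[1],
                                   "blue": arr[2]},
                            transform=Affine.from_origin(0, 4, 1.0),
                            nodata=-1.0)
        out = classify_pixels(clf, raster)
        assert out.band("class")[0, 0] == CLASS_CODES["other"]


def class_raster(codes):
    codes = np.asarray(codes, dtype=np.uint8)
    h, w = codes.shape
    return RasterGrid(bands={"class": codes},
                      transform=Affine.from_origin(0, h, 1.0))


class TestCoverage:
    def test_counting_oracle(self):
        codes = np.zeros((10, 10), dtype=np.uint8)
        codes[:4, :] = CLASS_CODES["maize"]  # 40 of 100 pixels
        plot = PlotIndex("P", box(0.4, 0.4, 9.6, 9.6))  # all 100 centres
        cov = compute_coverage(class_raster(codes), plot)
        assert cov == pytest.approx(0.4)

    def test_extremes(self):
        plot = PlotIndex("P", box(1, 1, 9, 9))
        all_maize = np.full((10, 10), CLASS_CODES["maize"], dtype=np.uint8)
        assert compute_coverage(class_raster(all_maize), plot) == 1.0
        none = np.zeros((10, 10), dtype=np.uint8)
        assert compute_coverage(class_raster(none), plot) == 0.0

    def test_sunlit_denominator_excludes_shadow(self):
        codes = np.zeros((10, 10), dtype=np.uint8)
        codes[0:5] = CLASS_CODES["maize"]
        codes[5:8] = CLASS_CODES["shadow"]
        plot = PlotIndex("P", box(0.0, 0.0, 10.0, 10.0))
        r = class_raster(codes)
        assert compute_coverage(r, plot) == pytest.approx(0.5)
        assert compute_coverage(r, plot, denominator="sunlit") == \
            pytest.approx(50 / 70)

    def test_coverage_resolution_invariance(self):
        """Doubling raster resolution changes coverage by <= 0.01."""
        import pandas as pd
        from phenofuse import SceneConfig, render_scene
        from phenofuse.config import NoiseParams, TraitParams
        truth = pd.DataFrame([{
            "plot_id": "P001", "plot_row": 0, "plot_col": 0,
            "stage_das": 27, "growth": 0.5, "LAI": 2.5, "PH_m": 1.0,
            "coverage": 1.0 - np.exp(-0.7 * 2.5)}])
        covs = []
        for gsd in (0.01, 0.005):
            cfg = SceneConfig(
                n_plot_rows=1, n_plot_cols=1, gsd_rgb=gsd, gsd_ms=0.03,
                stages=(27,), seed=3,
                noise_params=NoiseParams(0, 0, 0),
                trait_params=TraitParams(lai_noise_sd=0, ph_noise_sd=0,
                                         fw_noise_sd=0, dmf_noise_sd=0,
                                         dry_matter_fractions=(0.2,)))
            scene = render_scene(truth, cfg)
            st = scene.stages[27]
            covs.append(compute_coverage(st.labels, scene.plots[0]))
    # rendering targets truth coverage at either resolution
        assert abs(covs[0] - covs[1]) <= 0.01


def height_rasters(chm, base=100.0):
    h, w = chm.shape
    t = Affine.from_origin(0, h, 1.0)
    dem = RasterGrid({"dem": np.full((h, w), base)}, t, units={"dem": "m"})
    dsm = RasterGrid({"dsm": base + np.asarray(chm, dtype=float)}, t,
                     units={"dsm": "m"})
    return dsm, dem


class TestPlantHeight:
    def test_flat_field_zero_height(self):
        dsm, dem = height_rasters(np.zeros((10, 10)))
        plot = PlotIndex("P", box(1, 1, 9, 9))
        mask = np.ones((10, 10), dtype=bool)
        assert compute_plant_height(dsm, dem, mask, plot) == 0.0

    def test_constant_canopy_any_percentile(self):
        dsm, dem = height_rasters(np.full((10, 10), 1.5))
        plot = PlotIndex("P", box(1, 1, 9, 9))
        mask = np.ones((10, 10), dtype=bool)
        for pct in (60, 90, 99, 100):
            assert compute_plant_height(dsm, dem, mask, plot,
                                        percentile=pct) == \
                pytest.approx(1.5)

    def test_matches_brute_force_percentile(self, rng):
        chm = rng.uniform(0, 2, (30, 30))
        dsm, dem = height_rasters(chm)
        plot = PlotIndex("P", box(3, 3, 27, 27))
        mask = rng.random((30, 30)) < 0.5
        got = compute_plant_height(dsm, dem, mask, plot, percentile=99)
        sel = plot.pixel_mask(dsm) & mask
        expect = np.percentile(chm[sel], 99, method="linear")
        assert got == pytest.approx(expect, abs=1e-12)

    def test_negative_chm_truncated(self):
        dsm, dem = height_rasters(np.full((10, 10), -0.3))
        plot = PlotIndex("P", box(1, 1, 9, 9))
        mask = np.ones((10, 10), dtype=bool)
        assert compute_plant_height(dsm, dem, mask, plot) == 0.0

    def test_no_maize_pixels_gives_zero(self):
        dsm, dem = height_rasters(np.full((10, 10), 1.0))
        plot = PlotIndex("P", box(1, 1, 9, 9))
        assert compute_plant_height(dsm, dem,
                                    np.zeros((10, 10), dtype=bool),
                                    plot) == 0.0

    def test_misaligned_rasters_rejected(self):
        dsm, _ = height_rasters(np.zeros((10, 10)))
        _, dem = height_rasters(np.zeros((8, 8)))
        plot = PlotIndex("P", box(1, 1, 7, 7))
        with pytest.raises(AlignmentError):
            compute_plant_height(dsm, dem, np.ones((10, 10), bool), plot)

    def test_percentile_validated(self):
        dsm, dem = height_rasters(np.zeros((10, 10)))
        plot = PlotIndex("P", box(1, 1, 9, 9))
        with pytest.raises(ValueError):
            compute_plant_height(dsm, dem, np.ones((10, 10), bool), plot,
                                 percentile=40)


def test_structure_recovery_on_small_scene(small_scene, small_classifier,
                                           small_truth):
    """Classified coverage and extracted PH track the generator's truth."""
    cov_err, ph_sq = [], []
    for das, st in small_scene.stages.items():
        cr = classify_pixels(small_classifier, st.rgb)
        mask = maize_mask(cr)
        for p in small_scene.plots:
            rec = small_truth[(small_truth.plot_id == p.plot_id)
                              & (small_truth.stage_das == das)].iloc[0]
            cov_err.append(abs(compute_coverage(cr, p) - rec.coverage))
            ph_sq.append((compute_plant_height(st.dsm, st.dem, mask, p)
                          - rec.PH_m) ** 2)
    assert np.mean(cov_err) <= 0.03
    assert np.sqrt(np.mean(ph_sq)) <= 0.05
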