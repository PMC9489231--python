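"""Generator and renderer: determinism, trait dispersion, coverage link,
height injection and spectral saturation."""

import numpy as np
import pandas as pd
import pytest

from phenofuse import (CLASS_CODES, SceneConfig, generate_ground_truth,
                       render_scene, zonal_pixels)
from phenofuse.config import NoiseParams, TraitParams


def zero_noise_config(**kw) -> SceneConfig:
    tp = kw.pop("trait_params",
                TraitParams(lai_noise_sd=0, ph_noise_sd=0, fw_noise_sd=0,
                            dmf_noise_sd=0))
    return SceneConfig(trait_params=tp, noise_params=NoiseParams(0, 0, 0),
                       **kw)


def ladder_truth(lais, ph=1.0, k_ext=0.7) -> pd.DataFrame:
    """Hand-built truth: one stage, one plot row, prescribed LAI ladder."""
    rows = []
    for i, lai in enumerate(lais):
        rows.append({"plot_id": f"P{i + 1:03d}", "plot_row": 0,
                     "plot_col": i, "stage_das": 27, "growth": 0.5,
                     "LAI": lai, "PH_m": ph,
                     "coverage": 1.0 - np.exp(-k_ext * lai)})
    return pd.DataFrame(rows)


class TestGroundTruth:
    def test_default_design_yields_220_samples(self):
        gt = generate_ground_truth(SceneConfig(seed=7))
        assert len(gt) == 220
        assert gt["plot_id"].nunique() == 55
        assert sorted(gt["stage_das"].unique()) == [27, 37, 56, 87]

    def test_deterministic_under_fixed_seed(self):
        cfg = SceneConfig(seed=7)
        assert generate_ground_truth(cfg).equals(generate_ground_truth(cfg))

    def test_different_seeds_differ(self):
        a = generate_ground_truth(SceneConfig(seed=7))
        b = generate_ground_truth(SceneConfig(seed=8))
        assert not a["LAI"].equals(b["LAI"])

    def test_pooled_dispersion_exceeds_half(self):
        gt = generate_ground_truth(SceneConfig(seed=7))
        for col in ("LAI", "PH_m", "FW_g_m2", "DW_g_m2"):
            v = gt[col]
            assert v.std(ddof=1) / v.mean() >= 0.50, col

    def test_trait_invariants(self):
        gt = generate_ground_truth(SceneConfig(seed=3))
        assert (gt[["LAI", "PH_m", "FW_g_m2", "DW_g_m2"]] >= 0).all().all()
        assert (gt["DW_g_m2"] <= gt["FW_g_m2"]).all()
        assert gt["coverage"].between(0, 1).all()
        for _, sub in gt.groupby("plot_id"):
            sub = sub.sort_values("stage_das")
            assert sub["LAI"].is_monotonic_increasing
            assert sub["PH_m"].is_monotonic_increasing

    def test_beer_lambert_coverage_closed_form(self):
        cfg = zero_noise_config(seed=5)
        gt = generate_ground_truth(cfg)
        np.testing.assert_allclose(gt["coverage"],
                                   1.0 - np.exp(-0.7 * gt["LAI"]))
        # LAI = 3, k_ext = 0.7  ->  1 - e^-2.1
        assert 1.0 - np.exp(-0.7 * 3.0) == pytest.approx(0.87754, abs=1e-4)

    def test_rejects_bad_distribution_parameters(self):
        with pytest.raises(ValueError):
            SceneConfig(trait_params=TraitParams(lai_max_mean=-1.0))
        with pytest.raises(ValueError):
            SceneConfig(trait_params=TraitParams(growth_rate_sd=-0.1))


class TestRenderScene:
    def test_empty_canopy_renders_bare_field(self):
        cfg = zero_noise_config(n_plot_rows=1, n_plot_cols=2, seed=1)
        truth = generate_ground_truth(cfg)
        truth[["LAI", "PH_m", "coverage"]] = 0.0
        scene = render_scene(truth, cfg)
        for st in scene.stages.values():
            assert (st.labels.band("class") != CLASS_CODES["maize"]).all()
            np.testing.assert_array_equal(st.dsm.band("dsm"),
                                          st.dem.band("dem"))

    def test_noiseless_height_injection(self):
        cfg = zero_noise_config(n_plot_rows=1, n_plot_cols=1, seed=1,
                                stages=(27,),
                                trait_params=TraitParams(
                                    lai_noise_sd=0, ph_noise_sd=0,
                                    fw_noise_sd=0, dmf_noise_sd=0,
                                    dry_matter_fractions=(0.2,)))
        truth = ladder_truth([3.0], ph=1.5)
        scene = render_scene(truth, cfg)
        st = scene.stages[27]
        chm = st.dsm.band("dsm") - st.dem.band("dem")
        win = scene.plots[0].pixel_window(st.dsm)
        assert win.extract(chm).max() == pytest.approx(1.5, abs=1e-9)

    def test_rendered_coverage_matches_truth(self, small_scene, small_truth):
        """Pixel-counting oracle: label fraction vs Beer-Lambert coverage."""
        rng = np.random.default_rng(0)
        recs = small_truth.sample(20, random_state=1)
        errs = []
        for rec in recs.itertuples():
            st = small_scene.stages[rec.stage_das]
            labels = zonal_pixels(st.labels, small_scene.plot(rec.plot_id))
            frac = (labels["class"] == CLASS_CODES["maize"]).mean()
            errs.append(abs(frac - rec.coverage))
        assert np.mean(errs) <= 0.01

    def test_determinism_byte_identical_rasters(self):
        cfg = SceneConfig(n_plot_rows=1, n_plot_cols=2, seed=9,
                          stages=(27, 37),
                          trait_params=TraitParams(
                              dry_matter_fractions=(0.1, 0.2)))
        t = generate_ground_truth(cfg)
        a = render_scene(t, cfg)
        b = render_scene(t, cfg)
        for das in a.stages:
            for kind in ("rgb", "ms", "dsm", "dem", "labels"):
                ra, rb = getattr(a.stages[das], kind), \
                    getattr(b.stages[das], kind)
                for name in ra.band_names:
                    np.testing.assert_array_equal(ra.band(name),
                                                  rb.band(name))

    def test_canopy_fraction_monotone_in_lai(self):
        cfg = zero_noise_config(n_plot_rows=1, n_plot_cols=6, seed=2,
                                stages=(27,),
                                trait_params=TraitParams(
                                    lai_noise_sd=0, ph_noise_sd=0,
                                    fw_noise_sd=0, dmf_noise_sd=0,
                                    dry_matter_fractions=(0.2,)))
        lais = [0.5, 1.0, 2.0, 3.5, 5.0, 8.0]
        scene = render_scene(ladder_truth(lais), cfg)
        st = scene.stages[27]
        fracs = []
        for i in range(6):
            lab = zonal_pixels(st.labels, scene.plot(f"P{i + 1:03d}"))
            fracs.append(float((lab["class"] == CLASS_CODES["maize"]).mean()))
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_nir_saturates_with_lai(self):
        """Mean plot nir rises with LAI with diminishing increments."""
        cfg = zero_noise_config(n_plot_rows=1, n_plot_cols=8, seed=2,
                                stages=(27,),
                                trait_params=TraitParams(
                                    lai_noise_sd=0, ph_noise_sd=0,
                                    fw_noise_sd=0, dmf_noise_sd=0,
                                    dry_matter_fractions=(0.2,)))
        lais = np.arange(1.0, 9.0)
        scene = render_scene(ladder_truth(list(lais)), cfg)
        st = scene.stages[27]
        nir = np.array([zonal_pixels(st.ms, scene.plot(f"P{i + 1:03d}"))
                        ["nir"].mean() for i in range(8)])
        diffs = np.diff(nir)
        assert (diffs > 0).all()
        # second differences <= 0 up to pixel-discretization jitter
        assert (np.diff(diffs) <= 5e-4).all()

    def test_dsm_above_dem_on_maize(self, small_scene):
        for st in small_scene.stages.values():
            maize = st.labels.band("class") == CLASS_CODES["maize"]
            assert (st.dsm.band("dsm")[maize]
                    >= st.dem.band("dem")[maize]).all()

    def test_reflectance_clipped_to_unit_interval(self, small_scene):
        for st in small_scene.stages.values():
            for name in st.ms.band_names:
                band = st.ms.band(name)
                assert band.min() >= 0.0 and band.max() <= 1.0


class TestSceneConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(gsd_rgb=0.05, gsd_ms=0.03),
        dict(stages=(27, 27)),
        dict(stages=()),
        dict(plot_width=-1.0),
        dict(plot_buffer=0.7),
        dict(n_plot_rows=0),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SceneConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SceneConfig(n_plot_rows=2, n_plot_cols=3, seed=42)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SceneConfig.from_yaml(tmp_path / "c.yaml") == cfg
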