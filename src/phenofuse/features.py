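"""Plot-level feature table: extraction, named feature sets, preprocessing.

The full table holds 49 variables per (plot, stage) sample:

* 16 RGB spectral (3 band means + 13 indices),
* 2 structural (canopy coverage, plant height),
* 9 GLCM texture metrics,
* 22 multispectral spectral (4 band means + 18 indices).

Named feature sets mirror the sensor/feature-type combinations used for
model comparison; their cardinalities are 16 / 2 / 9 / 18 / 25 / 11 / 27 /
22 / 49.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .canopy import (PixelClassifier, classify_pixels, compute_coverage,
                     compute_plant_height, maize_mask)
from .scene import FieldScene
from .spectral import (MS_SPECTRAL_FEATURES, RGB_SPECTRAL_FEATURES,
                       ms_spectral_features, rgb_spectral_features)
from .texture import GLCMParams, TEXTURE_NAMES, plot_texture_features, \
    to_grayscale

STRUCTURE_FEATURES = ("coverage", "PH")
TEXTURE_FEATURES = tuple(f"tex_{n}" for n in TEXTURE_NAMES)

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "Spe": RGB_SPECTRAL_FEATURES,
    "Str": STRUCTURE_FEATURES,
    "Tex": TEXTURE_FEATURES,
    "Spe+Str": RGB_SPECTRAL_FEATURES + STRUCTURE_FEATURES,
    "Spe+Tex": RGB_SPECTRAL_FEATURES + TEXTURE_FEATURES,
    "Str+Tex": STRUCTURE_FEATURES + TEXTURE_FEATURES,
    "Spe+Str+Tex": (RGB_SPECTRAL_FEATURES + STRUCTURE_FEATURES
                    + TEXTURE_FEATURES),
    "MS-Spe": MS_SPECTRAL_FEATURES,
    "RGB+MS": (RGB_SPECTRAL_FEATURES + STRUCTURE_FEATURES
               + TEXTURE_FEATURES + MS_SPECTRAL_FEATURES),
}
FEATURE_SETS["RGB-Spe"] = FEATURE_SETS["Spe"]          # alias
FEATURE_SETS["RGB+MS all"] = FEATURE_SETS["RGB+MS"]    # alias

ALL_FEATURES = FEATURE_SETS["RGB+MS"]
ID_COLUMNS = ("plot_id", "stage_das")


def feature_set(name: str) -> tuple[str, ...]:
    try:
        return FEATURE_SETS[name]
    except KeyError:
        raise KeyError(f"unknown feature set {name!r}; known: "
                       f"{sorted(set(FEATURE_SETS))}") from None


def select_features(table: pd.DataFrame, set_name: str) -> pd.DataFrame:
    """Feature-set columns of an assembled table (id columns excluded)."""
    return table[list(feature_set(set_name))]


def assemble_feature_table(rows: list[dict]) -> pd.DataFrame:
    """Stack per-sample feature dicts into the canonical table layout."""
    df = pd.DataFrame(rows)
    cols = [c for c in ID_COLUMNS if c in df.columns] + \
        [c for c in ALL_FEATURES if c in df.columns]
    return df[cols]


def write_feature_manifest(path: str | Path) -> None:
    """JSON manifest documenting feature-set membership."""
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in FEATURE_SETS.items()}, fh,
                  indent=1)


def _downsample_mask(mask: np.ndarray, ms_shape: tuple[int, int]
                     ) -> np.ndarray:
    """Fine-grid boolean mask -> coarse-grid mask (majority of each block)."""
    h, w = mask.shape
    mh, mw = ms_shape
    if h % mh == 0 and w % mw == 0:
        rh, rw = h // mh, w // mw
        frac = mask.reshape(mh, rh, mw, rw).mean(axis=(1, 3))
        return frac >= 0.5
    # non-nested grids: nearest-neighbour sampling at coarse pixel centres
    rows = np.clip((np.arange(mh) + 0.5) * h / mh, 0, h - 1).astype(int)
    cols = np.clip((np.arange(mw) + 0.5) * w / mw, 0, w - 1).astype(int)
    return mask[np.ix_(rows, cols)]


def extract_feature_table(scene: FieldScene, classifier: PixelClassifier,
                          glcm_params: GLCMParams = GLCMParams(),
                          ph_percentile: float = 99.0,
                          coverage_denominator: str = "all",
                          spectral_mode: str = "index_of_means",
                          texture_canopy_only: bool = True) -> pd.DataFrame:
    """Run the full feature pipeline over every plot and stage of a scene."""
    rows: list[dict] = []
    for das in scene.stage_list:
        st = scene.stages[das]
        class_raster = classify_pixels(classifier, st.rgb)
        mask = maize_mask(class_raster)
        gray = to_grayscale(st.rgb)
        mask_ms = _downsample_mask(mask, st.ms.shape)
        for plot in scene.plots:
            row: dict = {"plot_id": plot.plot_id, "stage_das": das}
            row["coverage"] = compute_coverage(
                class_raster, plot, denominator=coverage_denominator)
            row["PH"] = compute_plant_height(
                st.dsm, st.dem, mask, plot, percentile=ph_percentile)
            tex = plot_texture_features(gray, mask, plot, glcm_params,
                                        canopy_only=texture_canopy_only)
            row.update({f"tex_{k}": v for k, v in tex.items()})
            row.update(rgb_spectral_features(st.rgb, mask, plot,
                                             mode=spectral_mode))
            row.update(ms_spectral_features(st.ms, mask_ms, plot,
                                            mode=spectral_mode))
            rows.append(row)
    return assemble_feature_table(rows)


@dataclass
class Preprocessor:
    """Median imputation + standardization fitted on training data only.

    The fitted statistics (``medians_``, ``means_``, ``scales_``) are
    recorded so leakage checks can verify they derive from the training
    partition alone.
    """

    columns: tuple[str, ...] = ()
    medians_: pd.Series | None = None
    means_: pd.Series | None = None
    scales_: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "Preprocessor":
        self.columns = tuple(X.columns)
        self.medians_ = X.median()
        filled = X.fillna(self.medians_)
        self.means_ = filled.mean()
        scales = filled.std(ddof=0)
        self.scales_ = scales.where(scales > 0, 1.0)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if self.medians_ is None:
            raise RuntimeError("Preprocessor is not fitted")
        if tuple(X.columns) != self.columns:
            raise ValueError("feature schema mismatch")
        filled = X.fillna(self.medians_)
        # a column that is all-NaN in training stays NaN: surface it early
        z = (filled - self.means_) / self.scales_
        return z.to_numpy(dtype=float)

    def fit_transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.fit(X).transform(X)
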