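"""End-to-end conveniences tying the stages together.

These helpers implement the common flows: sample classifier training pixels
from a synthetic scene's label raster, align a trait table to a feature
table, and train the per-trait ensembles used for mapping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .canopy import PixelClassifier, train_pixel_classifier
from .ensemble import FittedEnsembleBase, fit_base_learners, fit_bma, \
    fit_stacking_meta
from .features import Preprocessor, select_features
from .scene import FieldScene

TRAIT_COLUMNS = {"LAI": "LAI", "FW": "FW_g_m2", "DW": "DW_g_m2"}


def sample_training_pixels(scene: FieldScene, n_per_class: int = 400,
                           stage: int | None = None, seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Draw labelled RGB pixels from a synthetic scene's class raster."""
    das = stage if stage is not None else scene.stage_list[-1]
    st = scene.stages[das]
    if st.labels is None:
        raise ValueError("scene has no label raster to sample from")
    rng = np.random.default_rng(seed)
    labels = st.labels.band("class")
    rgb = np.moveaxis(st.rgb.stack(("red", "green", "blue")), 0, -1)
    xs, ys = [], []
    for code in np.unique(labels):
        flat = np.flatnonzero(labels.ravel() == code)
        take = min(n_per_class, flat.size)
        pick = rng.choice(flat, size=take, replace=False)
        rr, cc = np.unravel_index(pick, labels.shape)
        xs.append(rgb[rr, cc].astype(float))
        ys.append(np.full(take, code))
    return np.vstack(xs), np.concatenate(ys)


def train_classifier_from_scene(scene: FieldScene, n_per_class: int = 400,
                                stage: int | None = None,
                                seed: int = 0) -> PixelClassifier:
    X, y = sample_training_pixels(scene, n_per_class, stage, seed)
    return train_pixel_classifier(X, y)


def align_traits(features: pd.DataFrame, truth: pd.DataFrame
                 ) -> pd.DataFrame:
    """Trait table row-aligned to a feature table via (plot_id, stage_das).

    Returns columns LAI, FW, DW (and PH_m / coverage when present)."""
    merged = features[["plot_id", "stage_das"]].merge(
        truth, on=["plot_id", "stage_das"], how="left", validate="1:1")
    out = pd.DataFrame({t: merged[c] for t, c in TRAIT_COLUMNS.items()
                        if c in merged.columns})
    for extra in ("PH_m", "coverage"):
        if extra in merged.columns:
            out[extra] = merged[extra]
    return out


def train_trait_ensembles(features: pd.DataFrame, traits: pd.DataFrame,
                          set_name: str = "RGB+MS", meta: str = "BMA",
                          k: int = 5, seed: int = 0
                          ) -> dict[str, tuple[Preprocessor,
                                               FittedEnsembleBase, object]]:
    """Fit one full ensemble per trait on all provided samples."""
    out = {}
    X = select_features(features, set_name)
    for i, trait in enumerate(c for c in ("LAI", "FW", "DW")
                              if c in traits.columns):
        y = traits[trait].to_numpy(dtype=float)
        ok = np.isfinite(y)
        prep = Preprocessor().fit(X.loc[ok])
        Z = prep.transform(X.loc[ok])
        base = fit_base_learners(Z, y[ok], k=k, seed=seed + i)
        if meta == "BMA":
            ml = fit_bma(base.oof, y[ok])
        elif meta == "Stacking":
            ml = fit_stacking_meta(base.oof, y[ok])
        else:
            raise ValueError(f"unknown meta-learner {meta!r}")
        out[trait] = (prep, base, ml)
    return out
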