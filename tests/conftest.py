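"""Shared fixtures: one small synthetic scene drives most integration tests.

Everything is generated at test time from fixed seeds; nothing is read from
disk except what the tests themselves write to tmp paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenofuse import (SceneConfig, extract_feature_table,
                       generate_ground_truth, render_scene,
                       train_classifier_from_scene)
from phenofuse.pipeline import align_traits

SMALL_SEED = 11


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """16 plots x 4 stages at default noise: big enough for model fitting,
    small enough to render and extract in seconds."""
    return SceneConfig(n_plot_rows=4, n_plot_cols=4, seed=SMALL_SEED)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_scene(small_config, small_truth):
    return render_scene(small_truth, small_config)


@pytest.fixture(scope="session")
def small_classifier(small_scene):
    return train_classifier_from_scene(small_scene, seed=1)


@pytest.fixture(scope="session")
def small_features(small_scene, small_classifier) -> pd.DataFrame:
    return extract_feature_table(small_scene, small_classifier)


@pytest.fixture(scope="session")
def small_traits(small_features, small_truth) -> pd.DataFrame:
    return align_traits(small_features, small_truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
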