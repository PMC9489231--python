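"""Pixel classification and canopy structure features.

Canopy coverage is the fraction of a plot's pixels classified as maize;
plant height is a high percentile of the canopy height model (DSM - DEM)
over the plot's maize pixels.  The pixel classifier is a radial-kernel
support-vector machine (one-vs-one multiclass, C = 10) on standardized
per-pixel colour features: the raw R, G, B digital numbers plus the
chromatic coordinates R/(R+G+B), G/(R+G+B), B/(R+G+B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .geo import PlotIndex, RasterGrid
from .scene import CLASS_CODES

FEATURE_RECIPE = "R,G,B,R/(R+G+B),G/(R+G+B),B/(R+G+B)"


def pixel_features(rgb_pixels: np.ndarray) -> np.ndarray:
    """(n, 3) RGB digital numbers -> (n, 6) colour features."""
    rgb = np.asarray(rgb_pixels, dtype=float)
    total = rgb.sum(axis=1, keepdims=True)
    chrom = np.divide(rgb, total, out=np.full_like(rgb, 1.0 / 3.0),
                      where=total > 0)
    return np.hstack([rgb, chrom])


@dataclass
class PixelClassifier:
    """Four-class (maize/soil/shadow/other) per-pixel discriminator."""

    model: object
    classes: tuple[str, ...]
    feature_recipe: str = FEATURE_RECIPE
    training_accuracy: float = float("nan")

    def predict_codes(self, rgb_pixels: np.ndarray) -> np.ndarray:
        return self.model.predict(pixel_features(rgb_pixels))


def train_pixel_classifier(rgb_pixels: np.ndarray,
                           labels: np.ndarray,
                           C: float = 10.0) -> PixelClassifier:
    """Fit the SVM pixel classifier on labelled RGB samples.

    ``labels`` are class codes (see ``scene.CLASS_CODES``) or class-name
    strings.  Requires at least two classes and 20 samples per present
    class; degenerate (constant-colour) training sets are rejected.
    """
    rgb_pixels = np.asarray(rgb_pixels, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        labels = np.array([CLASS_CODES[str(l)] for l in labels])
    present, counts = np.unique(labels, return_counts=True)
    if len(present) < 2:
        raise ValueError("need at least two classes to train the classifier")
    if counts.min() < 20:
        raise ValueError("need at least 20 samples per present class")
    X = pixel_features(rgb_pixels)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate training set: all pixels share one "
                         "colour; classes are not separable")
    clf = make_pipeline(StandardScaler(),
                        SVC(C=C, kernel="rbf", gamma="scale",
                            cache_size=200))
    clf.fit(X, labels)
    acc = float((clf.predict(X) == labels).mean())
    names = tuple(sorted(CLASS_CODES, key=CLASS_CODES.get))
    return PixelClassifier(model=clf, classes=names, training_accuracy=acc)


def classify_pixels(classifier: PixelClassifier, rgb: RasterGrid,
                    chunk: int = 262144) -> RasterGrid:
    """Classify every pixel of an RGB raster into a class-code raster.

    Nodata or non-finite pixels are assigned class ``other``.
    """
    stack = rgb.stack(("red", "green", "blue")).astype(float)
    h, w = rgb.shape
    flat = stack.reshape(3, -1).T
    ok = np.isfinite(flat).all(axis=1)
    if rgb.nodata is not None:
        ok &= ~(flat == rgb.nodata).all(axis=1)
    out = np.full(h * w, CLASS_CODES["other"], dtype=np.uint8)
    idx = np.flatnonzero(ok)
    for start in range(0, idx.size, chunk):
        sel = idx[start:start + chunk]
        out[sel] = classifier.predict_codes(flat[sel])
    return RasterGrid(bands={"class": out.reshape(h, w)},
                      transform=rgb.transform, units={"class": "class"})


def maize_mask(class_raster: RasterGrid) -> np.ndarray:
    return class_raster.band("class") == CLASS_CODES["maize"]


def compute_coverage(class_raster: RasterGrid, plot: PlotIndex,
                     denominator: str = "all") -> float:
    """Canopy coverage of one plot: maize pixels / plot pixels.

    ``denominator`` is ``"all"`` (every plot pixel; default) or
    ``"sunlit"`` (excludes shadow pixels from the denominator).
    """
    win = plot.pixel_window(class_raster)
    vals = win.extract(class_raster.band("class"))
    if vals.size == 0:
        raise ValueError(f"plot {plot.plot_id!r} contains no pixels")
    n_maize = int((vals == CLASS_CODES["maize"]).sum())
    if denominator == "all":
        denom = vals.size
    elif denominator == "sunlit":
        denom = int((vals != CLASS_CODES["shadow"]).sum())
        if denom == 0:
            raise ValueError("no non-shadow pixels in plot")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return n_maize / denom


def compute_plant_height(dsm: RasterGrid, dem: RasterGrid,
                         maize: np.ndarray, plot: PlotIndex,
                         percentile: float = 99.0) -> float:
    """Plant height: a high percentile of the canopy height model.

    CHM = DSM - DEM, truncated below at 0 (sub-ground DSM noise is
    physically meaningless).  The statistic is the linearly interpolated
    ``percentile`` of CHM over the plot's maize pixels; 0 when the plot has
    no maize pixels.
    """
    dsm.require_aligned(dem)
    if not 50.0 < percentile <= 100.0:
        raise ValueError("percentile must lie in (50, 100]")
    if maize.shape != dsm.shape:
        raise ValueError("maize mask shape differs from raster shape")
    win = plot.pixel_window(dsm)
    sel = win.full_mask(dsm.shape) & maize
    if not sel.any():
        return 0.0
    chm = np.clip(dsm.band("dsm")[sel] - dem.band("dem")[sel], 0.0, None)
    return float(np.percentile(chm, percentile, method="linear"))
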