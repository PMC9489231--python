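"""Gray-level co-occurrence (GLCM) texture features.

Plot-level texture is the unweighted mean, over canopy-centred sliding
windows, of nine Haralick-style metrics computed from one symmetric GLCM per
window.  The GLCM accumulates gray-level pairs over four offsets (0, 45, 90
and 135 degrees at the configured distance), is symmetrized and normalized
to sum 1.  Gray levels are quantized uniformly over [0, 255] into
``levels`` bins (0-based indices enter the metric formulas).

Metrics, for P(i, j) with marginal mean mu and variance sigma^2 (identical
for both indices of a symmetric matrix):

    mean            = sum i * P
    variance        = sum (i - mu)^2 * P
    contrast        = sum (i - j)^2 * P
    energy          = sum P^2
    entropy         = -sum P * ln P           (0 ln 0 := 0)
    homogeneity     = sum P / (1 + (i - j)^2)
    autocorrelation = sum i * j * P
    dissimilarity   = sum |i - j| * P
    correlation     = (autocorrelation - mu^2) / sigma^2, 0 when sigma = 0

The batched sliding-window path and the single-window entry point share one
metric implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .geo import PlotIndex, RasterGrid

TEXTURE_NAMES = ("mean", "variance", "contrast", "energy", "entropy",
                 "homogeneity", "autocorrelation", "dissimilarity",
                 "correlation")


@dataclass(frozen=True)
class GLCMParams:
    window: int = 7          # sliding-window side, pixels (odd, >= 3)
    step: int = 2            # window stride, pixels
    levels: int = 32         # gray quantization bins
    distance: int = 1        # co-occurrence offset length, pixels
    angles: tuple[int, ...] = (0, 45, 90, 135)   # degrees
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.window < self.distance + 1:
            raise ValueError("window must be >= distance + 1")
        bad = set(self.angles) - {0, 45, 90, 135}
        if bad or not self.angles:
            raise ValueError(f"unsupported angles: {sorted(bad)}")

    def offsets(self) -> list[tuple[int, int]]:
        """(drow, dcol) per angle, drow >= 0 (direction is irrelevant for a
        symmetric GLCM)."""
        d = self.distance
        table = {0: (0, d), 45: (d, -d), 90: (d, 0), 135: (d, d)}
        return [table[a] for a in self.angles]


def to_grayscale(rgb: RasterGrid) -> RasterGrid:
    """Luminance gray image 0.299 R + 0.587 G + 0.114 B on [0, 255]."""
    r = rgb.band("red").astype(float)
    g = rgb.band("green").astype(float)
    b = rgb.band("blue").astype(float)
    gray = 0.299 * r + 0.587 * g + 0.114 * b
    return RasterGrid(bands={"gray": gray}, transform=rgb.transform,
                      nodata=rgb.nodata, units={"gray": "DN"})


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniform binning of [0, 255] gray values into ``levels`` 0-based bins."""
    q = np.floor(np.asarray(gray, dtype=float) * levels / 256.0)
    return np.clip(q, 0, levels - 1).astype(np.int32)


def glcm_matrix(quantized: np.ndarray, params: GLCMParams) -> np.ndarray:
    """Symmetric normalized GLCM of one quantized window."""
    L = params.levels
    q = np.asarray(quantized)
    counts = np.zeros((L, L), dtype=float)
    for dr, dc in params.offsets():
        h, w = q.shape
        if dr >= h or abs(dc) >= w:
            continue
        r0, r1 = 0, h - dr
        c0, c1 = max(0, -dc), w - max(0, dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        np.add.at(counts, (a.ravel(), b.ravel()), 1.0)
    if params.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("window too small for the configured offsets")
    return counts / total


def metrics_from_glcm(P: np.ndarray) -> dict[str, np.ndarray]:
    """The nine texture metrics of (possibly batched) GLCMs (..., L, L)."""
    L = P.shape[-1]
    i = np.arange(L, dtype=float)
    I = i[:, None]
    J = i[None, :]
    s = lambda w: (P * w).sum(axis=(-2, -1))
    mean = s(I)
    variance = s((I - mean[..., None, None]) ** 2)
    contrast = s((I - J) ** 2)
    energy = (P ** 2).sum(axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_terms = np.where(P > 0, P * np.log(P), 0.0)
    entropy = -ent_terms.sum(axis=(-2, -1))
    homogeneity = s(1.0 / (1.0 + (I - J) ** 2))
    autocorrelation = s(I * J)
    dissimilarity = s(np.abs(I - J))
    correlation = np.where(variance > 0,
                           (autocorrelation - mean ** 2)
                           / np.where(variance > 0, variance, 1.0),
                           0.0)
    return {"mean": mean, "variance": variance, "contrast": contrast,
            "energy": energy, "entropy": entropy,
            "homogeneity": homogeneity,
            "autocorrelation": autocorrelation,
            "dissimilarity": dissimilarity, "correlation": correlation}


def glcm_window_metrics(window_pixels: np.ndarray,
                        params: GLCMParams = GLCMParams()
                        ) -> dict[str, float]:
    """Texture metrics of one raw gray window (values on [0, 255])."""
    q = quantize(window_pixels, params.levels)
    P = glcm_matrix(q, params)
    return {k: float(v) for k, v in metrics_from_glcm(P).items()}


def _batched_glcms(q: np.ndarray, top_rows: np.ndarray, top_cols: np.ndarray,
                   params: GLCMParams) -> np.ndarray:
    """Normalized symmetric GLCMs for windows at given top-left corners."""
    L = params.levels
    w = params.window
    n = top_rows.size
    counts = np.zeros((n, L * L), dtype=float)
    for dr, dc in params.offsets():
        h_, w_ = q.shape
        c0 = max(0, -dc)
        a = q[:h_ - dr, c0:w_ - max(0, dc)]
        b = q[dr:h_, c0 + dc:(w_ - max(0, dc)) + dc]
        code = a * L + b
        swv = sliding_window_view(code, (w - dr, w - abs(dc)))
        blocks = swv[top_rows, top_cols].reshape(n, -1)
        offs = (np.arange(n, dtype=np.int64) * (L * L))[:, None]
        flat = (blocks.astype(np.int64) + offs).ravel()
        counts += np.bincount(flat, minlength=n * L * L
                              ).reshape(n, L * L).astype(float)
    P = counts.reshape(n, L, L)
    if params.symmetric:
        P = P + P.transpose(0, 2, 1)
    totals = P.sum(axis=(1, 2), keepdims=True)
    return P / np.where(totals > 0, totals, 1.0)


def plot_texture_features(gray: RasterGrid, maize: np.ndarray,
                          plot: PlotIndex,
                          params: GLCMParams = GLCMParams(),
                          canopy_only: bool = True,
                          chunk: int = 2048) -> dict[str, float]:
    """Mean window-level texture metrics over one plot.

    Windows slide across the plot's bounding box with stride ``step``; a
    window is kept when its centre pixel lies inside the plot polygon, is
    classified maize (unless ``canopy_only`` is False) and the full window
    fits inside the raster.  Plots with zero valid windows return NaN for
    all nine metrics (missing values, imputed downstream).
    """
    if maize.shape != gray.shape:
        raise ValueError("maize mask shape differs from raster shape")
    win = plot.pixel_window(gray)
    hw = params.window // 2
    nrow, ncol = gray.shape
    h, wd = win.mask.shape
    cr = np.arange(win.row0, win.row0 + h, params.step)
    cc = np.arange(win.col0, win.col0 + wd, params.step)
    cr = cr[(cr >= hw) & (cr < nrow - hw)]
    cc = cc[(cc >= hw) & (cc < ncol - hw)]
    if cr.size == 0 or cc.size == 0:
        return {k: float("nan") for k in TEXTURE_NAMES}
    rr, ccg = np.meshgrid(cr, cc, indexing="ij")
    rr, ccg = rr.ravel(), ccg.ravel()
    inside = win.mask[rr - win.row0, ccg - win.col0]
    if canopy_only:
        inside &= maize[rr, ccg]
    rr, ccg = rr[inside], ccg[inside]
    if rr.size == 0:
        return {k: float("nan") for k in TEXTURE_NAMES}

    q = quantize(gray.band("gray"), params.levels)
    sums = {k: 0.0 for k in TEXTURE_NAMES}
    n_windows = rr.size
    for start in range(0, n_windows, chunk):
        tr = rr[start:start + chunk] - hw
        tc = ccg[start:start + chunk] - hw
        P = _batched_glcms(q, tr, tc, params)
        m = metrics_from_glcm(P)
        for k in TEXTURE_NAMES:
            sums[k] += float(m[k].sum())
    return {k: sums[k] / n_windows for k in TEXTURE_NAMES}
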