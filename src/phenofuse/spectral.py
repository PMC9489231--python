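"""Vegetation indices from RGB digital numbers and multispectral reflectance.

RGB indices operate on the raw 8-bit band means ``g, r, b`` (no chromatic
normalization); multispectral indices on reflectance band means ``g, r, re,
nir``.  Band means are computed over a plot's maize pixels first and each
index is then evaluated on the means (index-of-means; a per-pixel mode is
available through ``mode="per_pixel"``).

Any index whose denominator is zero for a given input yields NaN (a missing
value, imputed downstream from training-partition medians) rather than an
infinity.
"""

from __future__ import annotations

import numpy as np

from .geo import PlotIndex, RasterGrid, zonal_pixels

RGB_BAND_FEATURES = ("rgb_g", "rgb_r", "rgb_b")
MS_BAND_FEATURES = ("ms_g", "ms_r", "ms_re", "ms_nir")


def _div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.divide(num, den, out=np.full(np.broadcast_shapes(
        num.shape, den.shape), np.nan), where=den != 0)
    return out if out.shape else float(out)


# --------------------------------------------------------- RGB indices
def exr(g, r, b):
    return 1.4 * r - g


def exg(g, r, b):
    return 2.0 * g - r - b


def exgr(g, r, b):
    return 3.0 * g - 2.4 * r - b


def mgrvi(g, r, b):
    return _div(g ** 2 - r ** 2, g ** 2 + r ** 2)


def ngrdi(g, r, b):
    return _div(g - r, g + r)


def rgri(g, r, b):
    return _div(r, g)


def cive(g, r, b):
    return 0.441 * r - 0.881 * g + 0.385 * b + 18.78


def vari(g, r, b):
    return _div(g - r, g + r - b)


def wi(g, r, b):
    return _div(g - b, r - g)


def gla(g, r, b):
    return _div(2.0 * g - r - b, 2.0 * g + r + b)


def rgbvi(g, r, b):
    return _div(g ** 2 - b * r, g ** 2 + b * r)


def veg(g, r, b, k: float = 0.667):
    with np.errstate(invalid="ignore"):
        den = np.power(np.asarray(r, dtype=float), k) * \
            np.power(np.asarray(b, dtype=float), 1.0 - k)
    return _div(g, den)


def com(g, r, b):
    return (0.25 * exg(g, r, b) + 0.3 * exgr(g, r, b)
            + 0.33 * cive(g, r, b) + 0.12 * veg(g, r, b))


RGB_INDICES = {
    "EXR": exr, "EXG": exg, "EXGR": exgr, "MGRVI": mgrvi, "NGRDI": ngrdi,
    "RGRI": rgri, "CIVE": cive, "VARI": vari, "WI": wi, "GLA": gla,
    "RGBVI": rgbvi, "VEG": veg, "COM": com,
}


# ------------------------------------------------- multispectral indices
def ci(g, r, re, nir):
    return _div(nir, re) - 1.0


def dvi(g, r, re, nir):
    return nir - r


def gndvi(g, r, re, nir):
    return _div(nir - g, nir + g)


def grvi(g, r, re, nir):
    return _div(g - r, g + r)


def mcari(g, r, re, nir):
    return ((re - r) - 0.2 * (re - g)) * _div(re, r)


def mnvi(g, r, re, nir):
    return _div(1.5 * (nir ** 2 - r), nir ** 2 + r + 0.5)


def msr(g, r, re, nir):
    ratio = _div(nir, r)
    with np.errstate(invalid="ignore"):
        return _div(ratio - 1.0, np.sqrt(ratio) + 1.0)


def mtci(g, r, re, nir):
    return _div(nir - re, re - r)


def ndre(g, r, re, nir):
    return _div(nir - re, nir + re)


def ndvi(g, r, re, nir):
    return _div(nir - r, nir + r)


def nli(g, r, re, nir):
    return _div(nir ** 2 - r, nir ** 2 + r)


def osavi(g, r, re, nir):
    return 1.16 * _div(nir - r, nir + r + 0.16)


def rdvi(g, r, re, nir):
    with np.errstate(invalid="ignore"):
        return _div(nir - r, np.sqrt(nir + r))


def rvi1(g, r, re, nir):
    return _div(nir, r)


def rvi2(g, r, re, nir):
    return _div(nir, g)


def savi(g, r, re, nir):
    return _div(1.5 * (nir - r), nir + r + 0.5)


def to_index(g, r, re, nir):
    # printed form, including the OSAVI denominator and the asymmetric
    # parenthesization relative to MCARI
    num = 3.0 * ((re - r) - 0.2 * (re - g) * _div(re, r))
    return _div(num, osavi(g, r, re, nir))


def tvi(g, r, re, nir):
    return 60.0 * (nir - g) - 100.0 * (r - g)


MS_INDICES = {
    "CI": ci, "DVI": dvi, "GNDVI": gndvi, "GRVI": grvi, "MCARI": mcari,
    "MNVI": mnvi, "MSR": msr, "MTCI": mtci, "NDRE": ndre, "NDVI": ndvi,
    "NLI": nli, "OSAVI": osavi, "RDVI": rdvi, "RVI1": rvi1, "RVI2": rvi2,
    "SAVI": savi, "TO": to_index, "TVI": tvi,
}

RGB_SPECTRAL_FEATURES = RGB_BAND_FEATURES + tuple(RGB_INDICES)
MS_SPECTRAL_FEATURES = MS_BAND_FEATURES + tuple(MS_INDICES)


def _nanmean(values: np.ndarray) -> float:
    return float(np.mean(values)) if values.size else float("nan")


def rgb_spectral_features(rgb: RasterGrid, maize: np.ndarray,
                          plot: PlotIndex,
                          mode: str = "index_of_means") -> dict[str, float]:
    """The 16 RGB spectral variables (3 band means + 13 indices) of a plot.

    Band means are taken over the plot's maize pixels; with no maize pixel
    every variable is NaN.
    """
    px = zonal_pixels(rgb, plot, mask=maize)
    g, r, b = px["green"].astype(float), px["red"].astype(float), \
        px["blue"].astype(float)
    out = {"rgb_g": _nanmean(g), "rgb_r": _nanmean(r), "rgb_b": _nanmean(b)}
    if g.size == 0:
        out.update({k: float("nan") for k in RGB_INDICES})
        return out
    if mode == "index_of_means":
        for name, fn in RGB_INDICES.items():
            out[name] = float(fn(out["rgb_g"], out["rgb_r"], out["rgb_b"]))
    elif mode == "per_pixel":
        for name, fn in RGB_INDICES.items():
            with np.errstate(invalid="ignore", divide="ignore"):
                out[name] = float(np.nanmean(fn(g, r, b)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def ms_spectral_features(ms: RasterGrid, maize_ms: np.ndarray,
                         plot: PlotIndex,
                         mode: str = "index_of_means") -> dict[str, float]:
    """The 22 multispectral variables (4 band means + 18 indices) of a plot."""
    px = zonal_pixels(ms, plot, mask=maize_ms)
    bands = {k: px[k].astype(float) for k in
             ("green", "red", "red_edge", "nir")}
    out = {"ms_g": _nanmean(bands["green"]), "ms_r": _nanmean(bands["red"]),
           "ms_re": _nanmean(bands["red_edge"]),
           "ms_nir": _nanmean(bands["nir"])}
    if bands["green"].size == 0:
        out.update({k: float("nan") for k in MS_INDICES})
        return out
    if mode == "index_of_means":
        for name, fn in MS_INDICES.items():
            out[name] = float(fn(out["ms_g"], out["ms_r"], out["ms_re"],
                                 out["ms_nir"]))
    elif mode == "per_pixel":
        for name, fn in MS_INDICES.items():
            with np.errstate(invalid="ignore", divide="ignore"):
                out[name] = float(np.nanmean(fn(*(bands[k] for k in
                                                  ("green", "red",
                                                   "red_edge", "nir")))))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out
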