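"""Read/write the on-disk scene layout.

A scene directory contains, per stage ``S`` (days after sowing):

* ``stage_SSS_rgb.tif``    -- 3-band uint8 digital numbers (red, green, blue)
* ``stage_SSS_ms.tif``     -- 4-band float32 reflectance
* ``stage_SSS_dsm.tif`` / ``stage_SSS_dem.tif`` -- float32 metres
* ``stage_SSS_labels.tif`` -- optional uint8 class raster (synthetic truth)

plus ``plots.geojson`` (plot polygons with a ``plot_id`` property),
``ground_truth.csv`` (synthetic mode) and a ``scene.json`` manifest.

Rasters are plain TIFFs written with :mod:`tifffile`; the affine
geotransform, band names, units and nodata live as a JSON document in the
TIFF ImageDescription tag, so every file is self-describing.  All rasters of
a scene share one projected coordinate system in metres; no reprojection is
performed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .config import SceneConfig
from .geo import Affine, PlotIndex, RasterGrid
from .scene import MS_BANDS, FieldScene, StageScene


class SceneSchemaError(ValueError):
    """A scene file is missing a band or required metadata."""


# ---------------------------------------------------------------- rasters
def write_raster(path: str | Path, raster: RasterGrid) -> None:
    names = raster.band_names
    data = raster.stack(names)
    meta = {
        "transform": list(raster.transform),
        "bands": list(names),
        "units": [raster.units.get(n, "") for n in names],
        "nodata": raster.nodata,
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta),
                     photometric="minisblack")


def read_raster(path: str | Path,
                band_names: list[str] | None = None) -> RasterGrid:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        meta = {}
    if data.ndim == 2:
        data = data[None]
    names = band_names or meta.get("bands")
    if names is None or len(names) != data.shape[0]:
        raise SceneSchemaError(
            f"{path}: band names unknown or mismatched "
            f"({names} for {data.shape[0]} bands)")
    units = dict(zip(names, meta.get("units", [""] * len(names))))
    transform = Affine(*meta["transform"]) if "transform" in meta else \
        Affine.from_origin(0.0, data.shape[1], 1.0)
    return RasterGrid(bands={n: data[i] for i, n in enumerate(names)},
                      transform=transform, nodata=meta.get("nodata"),
                      units=units)


# ------------------------------------------------------------------ plots
def write_plots_geojson(path: str | Path, plots: list[PlotIndex]) -> None:
    features = [{
        "type": "Feature",
        "properties": {"plot_id": p.plot_id},
        "geometry": mapping(p.polygon),
    } for p in plots]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_plots_geojson(path: str | Path) -> list[PlotIndex]:
    with open(path) as fh:
        gj = json.load(fh)
    plots = []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "plot_id" not in props:
            raise SceneSchemaError(f"{path}: feature lacks 'plot_id'")
        plots.append(PlotIndex(str(props["plot_id"]),
                               shape(feat["geometry"])))
    return plots


# ------------------------------------------------------------------ scene
def write_scene(scene: FieldScene, directory: str | Path) -> Path:
    """Write a full scene; returns the directory path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "ms_band_order": list(MS_BANDS)}
    for das in scene.stage_list:
        st = scene.stages[das]
        entry = {"das": das}
        for kind in ("rgb", "ms", "dsm", "dem", "labels"):
            raster = getattr(st, kind)
            if raster is None:
                continue
            fname = f"stage_{das:03d}_{kind}.tif"
            write_raster(d / fname, raster)
            entry[kind] = fname
        manifest["stages"].append(entry)
    write_plots_geojson(d / "plots.geojson", scene.plots)
    if scene.ground_truth is not None:
        truth_csv(scene.ground_truth).to_csv(d / "ground_truth.csv",
                                             index=False)
    if scene.config is not None:
        scene.config.to_yaml(d / "config.yaml")
    with open(d / "scene.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return d


def truth_csv(truth: pd.DataFrame) -> pd.DataFrame:
    cols = ["plot_id", "stage_das", "LAI", "FW_g_m2", "DW_g_m2", "PH_m",
            "coverage"]
    return truth[[c for c in cols if c in truth.columns]]


def read_scene(directory: str | Path,
               ms_band_order: tuple[str, ...] | None = None) -> FieldScene:
    """Load a scene directory written by :func:`write_scene`.

    ``ms_band_order`` declares the band order stored in the multispectral
    files when it differs from the canonical ``(green, red, red_edge, nir)``
    (for files whose embedded band names are absent or untrusted); the
    returned scene always uses the canonical order.
    """
    d = Path(directory)
    with open(d / "scene.json") as fh:
        manifest = json.load(fh)
    scene = FieldScene(plots=read_plots_geojson(d / "plots.geojson"))
    if (d / "config.yaml").exists():
        scene.config = SceneConfig.from_yaml(d / "config.yaml")
    if (d / "ground_truth.csv").exists():
        scene.ground_truth = pd.read_csv(d / "ground_truth.csv")
    for entry in manifest["stages"]:
        das = int(entry["das"])
        rasters = {}
        for kind in ("rgb", "ms", "dsm", "dem", "labels"):
            if kind not in entry:
                rasters[kind] = None
                continue
            names = list(ms_band_order) if (kind == "ms" and ms_band_order) \
                else None
            raster = read_raster(d / entry[kind], band_names=names)
            if kind == "ms":
                raster = normalize_ms_bands(raster)
            rasters[kind] = raster
        scene.stages[das] = StageScene(
            das=das, rgb=rasters["rgb"], ms=rasters["ms"],
            dsm=rasters["dsm"], dem=rasters["dem"],
            labels=rasters["labels"])
    return scene


def normalize_ms_bands(raster: RasterGrid) -> RasterGrid:
    """Permute multispectral bands into the canonical order."""
    missing = set(MS_BANDS) - set(raster.band_names)
    if missing:
        raise SceneSchemaError(
            f"multispectral raster lacks bands: {sorted(missing)}")
    return RasterGrid(bands={n: raster.bands[n] for n in MS_BANDS},
                      transform=raster.transform, nodata=raster.nodata,
                      units={n: raster.units.get(n, "") for n in MS_BANDS})


def write_class_raster(path: str | Path, class_raster: RasterGrid) -> None:
    """Single-band class-code raster with the legend embedded."""
    legend = {"0": "soil", "1": "maize", "2": "shadow", "3": "other"}
    meta = {
        "transform": list(class_raster.transform),
        "bands": list(class_raster.band_names),
        "units": ["class"],
        "nodata": None,
        "legend": legend,
    }
    tifffile.imwrite(str(path), class_raster.stack(),
                     description=json.dumps(meta), photometric="minisblack")
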