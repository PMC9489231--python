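"""Minimal planar geo-referencing primitives shared by every raster module.

The pipeline works in a single projected coordinate system (metres).  A raster
is a stack of named 2-D bands plus an affine pixel->world mapping; plots are
shapely polygons in world coordinates.  Pixel/world conventions:

* pixel indices are 0-based ``(row, col)``;
* the affine maps the *edge-based* pixel coordinate ``(col, row)`` to world
  ``(x, y)`` (GDAL convention), so the centre of pixel ``(row, col)`` sits at
  ``transform * (col + 0.5, row + 0.5)``;
* a pixel belongs to a plot iff its centre falls strictly inside the plot
  polygon (one shared centre rule for coverage, spectral, texture and height
  extraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import shapely
from shapely.geometry import Polygon


class Affine(NamedTuple):
    """Affine transform ``x = a*col + b*row + c; y = d*col + e*row + f``."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, gsd: float) -> "Affine":
        """North-up transform with square pixels of size ``gsd`` metres."""
        return cls(gsd, 0.0, west, 0.0, -gsd, north)

    def xy(self, col, row):
        """World coordinates of edge-based pixel coordinates."""
        return (self.a * col + self.b * row + self.c,
                self.d * col + self.e * row + self.f)

    def pixel_center(self, row, col):
        return self.xy(np.asarray(col) + 0.5, np.asarray(row) + 0.5)

    def world_to_pixel(self, x, y):
        """Fractional (row, col) edge-based pixel coordinates of world points."""
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("singular geotransform")
        xs = np.asarray(x, dtype=float) - self.c
        ys = np.asarray(y, dtype=float) - self.f
        col = (self.e * xs - self.b * ys) / det
        row = (-self.d * xs + self.a * ys) / det
        return row, col


class AlignmentError(ValueError):
    """Rasters do not share shape/geotransform."""


class PlotExtentError(ValueError):
    """A plot polygon falls (partly) outside the raster extent."""


@dataclass
class RasterGrid:
    """Named 2-D bands of identical shape with one affine geotransform.

    ``units`` is a per-band tag: ``"DN"`` (raw 8-bit digital numbers),
    ``"reflectance"`` (unitless, [0, 1]), ``"m"`` (metres) or ``"class"``.
    """

    bands: dict[str, np.ndarray]
    transform: Affine
    nodata: float | None = None
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise AlignmentError(f"bands have differing shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.bands.values()))
        return first.shape

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def band(self, name: str) -> np.ndarray:
        return self.bands[name]

    def stack(self, names=None) -> np.ndarray:
        """(n_bands, H, W) array, in ``names`` order (default: stored order)."""
        names = self.band_names if names is None else names
        return np.stack([self.bands[n] for n in names])

    def same_grid(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def require_aligned(self, other: "RasterGrid") -> None:
        if not self.same_grid(other):
            raise AlignmentError("rasters are not on a common grid")

    def valid_mask(self, name: str) -> np.ndarray:
        arr = self.bands[name]
        ok = np.isfinite(arr)
        if self.nodata is not None:
            ok &= arr != self.nodata
        return ok


@dataclass(frozen=True)
class ZonalWindow:
    """A plot's footprint on one raster grid: bbox offset + in-polygon mask."""

    row0: int
    col0: int
    mask: np.ndarray  # bool, shape of the bbox window

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        r, c = np.nonzero(self.mask)
        return r + self.row0, c + self.col0

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        h, w = self.mask.shape
        out[self.row0:self.row0 + h, self.col0:self.col0 + w] = self.mask
        return out

    def extract(self, band: np.ndarray) -> np.ndarray:
        h, w = self.mask.shape
        win = band[self.row0:self.row0 + h, self.col0:self.col0 + w]
        return win[self.mask]


@dataclass(frozen=True)
class PlotIndex:
    """A plot polygon with an identifier, resolvable to pixel windows."""

    plot_id: str
    polygon: Polygon

    def pixel_window(self, raster: RasterGrid) -> ZonalWindow:
        """Pixels of ``raster`` whose centres lie strictly inside the polygon.

        Raises :class:`PlotExtentError` when the polygon is not fully inside
        the raster extent (an out-of-extent plot is a data error, never an
        empty selection).
        """
        nrow, ncol = raster.shape
        minx, miny, maxx, maxy = self.polygon.bounds
        rows, cols = raster.transform.world_to_pixel(
            np.array([minx, maxx]), np.array([miny, maxy]))
        r0, r1 = int(np.floor(rows.min())), int(np.ceil(rows.max()))
        c0, c1 = int(np.floor(cols.min())), int(np.ceil(cols.max()))
        if r0 < 0 or c0 < 0 or r1 > nrow or c1 > ncol:
            raise PlotExtentError(
                f"plot {self.plot_id!r} extends outside the raster extent")
        r0c, r1c = max(r0, 0), min(r1, nrow)
        c0c, c1c = max(c0, 0), min(c1, ncol)
        rr, cc = np.meshgrid(np.arange(r0c, r1c), np.arange(c0c, c1c),
                             indexing="ij")
        xs, ys = raster.transform.pixel_center(rr.ravel(), cc.ravel())
        inside = shapely.contains_xy(self.polygon, xs, ys)
        mask = inside.reshape(rr.shape)
        return ZonalWindow(r0c, c0c, mask)

    def pixel_mask(self, raster: RasterGrid) -> np.ndarray:
        return self.pixel_window(raster).full_mask(raster.shape)


def zonal_pixels(raster: RasterGrid, plot: PlotIndex,
                 mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Per-band 1-D pixel values of ``raster`` inside ``plot``.

    ``mask`` (optional, full-raster boolean) further restricts the selection,
    e.g. to classified maize pixels.  Nodata pixels are dropped per band.  An
    empty selection yields empty arrays; callers decide the policy.
    """
    win = plot.pixel_window(raster)
    sel = win.full_mask(raster.shape)
    if mask is not None:
        if mask.shape != raster.shape:
            raise AlignmentError("mask shape differs from raster shape")
        sel &= mask
    out: dict[str, np.ndarray] = {}
    for name in raster.band_names:
        vals = raster.bands[name][sel]
        good = np.isfinite(vals)
        if raster.nodata is not None:
            good &= vals != raster.nodata
        out[name] = vals[good]
    return out


def plot_rectangles(plots: list[PlotIndex]) -> Iterator[tuple[str, Polygon]]:
    for p in plots:
        yield p.plot_id, p.polygon
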