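"""In-memory containers for a multi-stage UAV field scene."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import SceneConfig
from .geo import PlotIndex, RasterGrid

#: canonical multispectral band order used throughout the package
MS_BANDS = ("green", "red", "red_edge", "nir")
RGB_BANDS = ("red", "green", "blue")

#: class codes of the pixel classifier and the synthetic label rasters
CLASS_CODES = {"soil": 0, "maize": 1, "shadow": 2, "other": 3}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class StageScene:
    """All rasters of one acquisition date, on two aligned grids.

    ``rgb``, ``dsm``, ``dem`` and ``labels`` share the fine (RGB) grid;
    ``ms`` sits on the coarser multispectral grid covering the same world
    extent.  ``labels`` is only present for synthetic scenes.
    """

    das: int
    rgb: RasterGrid
    ms: RasterGrid
    dsm: RasterGrid
    dem: RasterGrid
    labels: RasterGrid | None = None

    def __post_init__(self) -> None:
        self.rgb.require_aligned(self.dsm)
        self.rgb.require_aligned(self.dem)
        if self.labels is not None:
            self.rgb.require_aligned(self.labels)


@dataclass
class FieldScene:
    """A bundle of per-stage rasters plus the plot layout.

    ``ground_truth`` (synthetic mode only) is a table with one row per
    (plot_id, stage_das) carrying LAI, PH_m, coverage, FW_g_m2 and DW_g_m2.
    """

    stages: dict[int, StageScene] = field(default_factory=dict)
    plots: list[PlotIndex] = field(default_factory=list)
    config: SceneConfig | None = None
    ground_truth: pd.DataFrame | None = None

    @property
    def stage_list(self) -> tuple[int, ...]:
        return tuple(sorted(self.stages))

    def plot(self, plot_id: str) -> PlotIndex:
        for p in self.plots:
            if p.plot_id == plot_id:
                return p
        raise KeyError(plot_id)
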