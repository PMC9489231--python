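"""Synthetic field-trial generator: ground-truth traits and sensor rasters.

The generator is the package's stand-in for an undeposited field campaign.
It has two halves:

``generate_ground_truth``
    draws per-plot latent growth trajectories and converts them to the four
    traits (LAI, plant height, fresh weight, dry weight) plus the true canopy
    coverage, with pooled dispersion matching a maize breeding trial
    (coefficient of variation >= 50 % for every trait);

``render_scene``
    a forward sensor model that turns the ground truth into orthorectified
    RGB digital numbers, 4-band multispectral reflectance, DSM/DEM height
    rasters and a per-pixel class raster (maize / soil / shadow / other).

Canopies are unions of plant discs with hemispheric crown profiles; the disc
radius threshold is chosen per plot and stage so that the rendered pixel
canopy fraction matches the Beer-Lambert coverage ``1 - exp(-k_ext * LAI)``
to within one pixel in the plot.  Multispectral reflectance is an exact
linear soil/leaf mixture obtained by block-averaging the fine-grid scene,
which reproduces the saturating reflectance-vs-LAI response of real
canopies.  Everything is deterministic given ``SceneConfig.seed``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import box

from .config import SceneConfig
from .geo import Affine, PlotIndex, RasterGrid
from .scene import CLASS_CODES, FieldScene, StageScene

TRUTH_COLUMNS = ("plot_id", "plot_row", "plot_col", "stage_das", "growth",
                 "LAI", "PH_m", "coverage", "FW_g_m2", "DW_g_m2")

# soil background reflectance per multispectral band
_SOIL_REFL = {"green": 0.16, "red": 0.20, "red_edge": 0.23, "nir": 0.26}
# soil RGB digital numbers (dry loam)
_SOIL_DN = np.array([112.0, 92.0, 68.0])
_DEBRIS_DN = np.array([228.0, 222.0, 210.0])
_SHADOW_FACTOR = 0.35
_SHADOW_SHIFT_M = 0.10  # cast-shadow offset, metres (row and col)
_DEBRIS_FRACTION = 0.002


def _lognormal(rng: np.random.Generator, mean: float, cv: float,
               size: int) -> np.ndarray:
    """Lognormal draws parameterised by arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def leaf_reflectance(lai: float) -> dict[str, float]:
    """Leaf-level multispectral reflectance, mildly increasing with canopy
    density (multiple scattering brightens nir/red-edge, chlorophyll
    absorption darkens red)."""
    return {
        "green": min(0.12 + 0.004 * lai, 0.17),
        "red": float(np.clip(0.075 - 0.003 * lai, 0.03, 0.08)),
        "red_edge": min(0.28 + 0.012 * lai, 0.42),
        "nir": min(0.40 + 0.02 * lai, 0.60),
    }


def leaf_color_dn(growth: float) -> np.ndarray:
    """Leaf RGB digital numbers; senescence browns/darkens with growth."""
    g = float(np.clip(growth, 0.0, 1.0))
    return np.array([38.0 + 22.0 * g, 96.0 - 26.0 * g, 30.0 + 6.0 * g])


def generate_ground_truth(config: SceneConfig) -> pd.DataFrame:
    """Draw per-plot trait trajectories for every stage of ``config``.

    Returns a tidy table with one row per (plot, stage), columns
    ``TRUTH_COLUMNS``.  LAI and PH trajectories are non-decreasing within a
    plot (enforced after multiplicative measurement noise); dry weight never
    exceeds fresh weight.
    """
    tp = config.trait_params
    n = config.n_plots
    stages = np.asarray(config.stages, dtype=float)
    rng = np.random.default_rng([config.seed, 101])

    lmax = _lognormal(rng, tp.lai_max_mean, tp.lai_max_cv, n)
    hmax = _lognormal(rng, tp.ph_max_mean, tp.ph_max_cv, n)
    rate = np.clip(rng.normal(tp.growth_rate_mean, tp.growth_rate_sd, n),
                   0.03, None)
    mid = rng.normal(tp.growth_mid_mean, tp.growth_mid_sd, n)

    # latent growth state, plots x stages
    g = 1.0 / (1.0 + np.exp(-rate[:, None] * (stages[None, :] - mid[:, None])))

    def noisy(base: np.ndarray, sd: float) -> np.ndarray:
        eps = rng.normal(0.0, sd, base.shape) if sd > 0 else 0.0
        return np.clip(base * (1.0 + eps), 0.0, None)

    lai = np.maximum.accumulate(noisy(lmax[:, None] * g, tp.lai_noise_sd),
                                axis=1)
    ph = np.maximum.accumulate(noisy(hmax[:, None] * g, tp.ph_noise_sd),
                               axis=1)
    coverage = 1.0 - np.exp(-tp.k_ext * lai)
    fw = noisy(tp.fw_allometry_a * np.power(lai, tp.fw_allometry_b),
               tp.fw_noise_sd)
    dmf = np.asarray(tp.dry_matter_fractions)[None, :]
    dmf_eps = (rng.normal(0.0, tp.dmf_noise_sd, fw.shape)
               if tp.dmf_noise_sd > 0 else 0.0)
    dw = fw * np.clip(dmf * (1.0 + dmf_eps), 0.02, 0.95)

    rows = []
    for p in range(n):
        prow, pcol = divmod(p, config.n_plot_cols)
        pid = config.plot_id(prow, pcol)
        for s, das in enumerate(config.stages):
            rows.append((pid, prow, pcol, das, g[p, s], lai[p, s], ph[p, s],
                         coverage[p, s], fw[p, s], dw[p, s]))
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


def build_plot_indices(config: SceneConfig) -> list[PlotIndex]:
    """Analysis polygons: sown rectangles shrunk by ``plot_buffer``."""
    plots = []
    b = config.plot_buffer
    for row in range(config.n_plot_rows):
        for col in range(config.n_plot_cols):
            x0, y0, x1, y1 = config.plot_rect(row, col)
            poly = box(x0 + b, y0 + b, x1 - b, y1 - b)
            plots.append(PlotIndex(config.plot_id(row, col), poly))
    return plots


def _grid_dims(config: SceneConfig) -> tuple[int, int, int]:
    ratio = config.gsd_ms / config.gsd_rgb
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("gsd_ms must be an integer multiple of gsd_rgb")
    ratio = int(round(ratio))
    h = int(np.ceil(config.field_length / config.gsd_rgb))
    w = int(np.ceil(config.field_width / config.gsd_rgb))
    h += (-h) % ratio
    w += (-w) % ratio
    return h, w, ratio


def _plant_centers(config: SceneConfig, plot_row: int, plot_col: int,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """World-coordinate plant centres and per-plant size multipliers.

    Plants sit on a jittered sowing grid (rows of plants along the plot
    length), fixed across stages, snapped to fine-grid pixel centres so the
    crown apex height is rendered exactly.
    """
    rng = np.random.default_rng(
        [config.seed, 202, plot_row * config.n_plot_cols + plot_col])
    x0, y0, x1, y1 = config.plot_rect(plot_row, plot_col)
    m = config.plot_buffer + 0.05
    n_rows_plants = 3
    n_per_row = max(2, int(round((y1 - y0 - 2 * m) / 0.28)))
    xs = np.linspace(x0 + m, x1 - m, n_rows_plants)
    ys = np.linspace(y0 + m, y1 - m, n_per_row)
    cx, cy = np.meshgrid(xs, ys)
    cx = cx.ravel() + rng.uniform(-0.03, 0.03, cx.size)
    cy = cy.ravel() + rng.uniform(-0.03, 0.03, cy.size)
    # snap to pixel centres of the fine grid
    g = config.gsd_rgb
    cx = (np.floor(cx / g) + 0.5) * g
    cy = (np.floor(cy / g) + 0.5) * g
    mult = rng.uniform(0.85, 1.15, cx.size)
    return np.column_stack([cx, cy]), mult


def _smooth_dem(h: int, w: int, transform: Affine,
                config: SceneConfig) -> np.ndarray:
    """Near-flat low-order ground surface (gentle tilt + long undulation)."""
    cols = np.arange(w) + 0.5
    rows = np.arange(h) + 0.5
    x = transform.a * cols + transform.c
    y = transform.e * rows + transform.f
    xx = x[None, :]
    yy = y[:, None]
    lx = max(config.field_width, 1.0)
    ly = max(config.field_length, 1.0)
    dem = (50.0 + 0.002 * xx + 0.0015 * yy
           + 0.03 * np.sin(2 * np.pi * xx / lx) * np.cos(2 * np.pi * yy / ly))
    return np.broadcast_to(dem, (h, w)).astype(np.float64).copy()


def render_scene(truth: pd.DataFrame, config: SceneConfig) -> FieldScene:
    """Forward sensor model: traits -> per-stage rasters.

    ``truth`` must carry ``plot_id, plot_row, plot_col, stage_das, LAI, PH_m,
    coverage`` (``growth`` optional, defaults to the coverage value); it is
    normally the output of :func:`generate_ground_truth` under the same
    config.
    """
    required = {"plot_id", "plot_row", "plot_col", "stage_das", "LAI",
                "PH_m", "coverage"}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"truth table lacks columns: {sorted(missing)}")
    h, w, ratio = _grid_dims(config)
    north = h * config.gsd_rgb
    t_rgb = Affine.from_origin(0.0, north, config.gsd_rgb)
    t_ms = Affine.from_origin(0.0, north, config.gsd_ms)
    plots = build_plot_indices(config)
    plot_lookup = {p.plot_id: p for p in plots}
    noise = config.noise_params
    shift_px = max(1, int(round(_SHADOW_SHIFT_M / config.gsd_rgb)))

    scene = FieldScene(plots=plots, config=config, ground_truth=truth)
    for das, sub in truth.groupby("stage_das", sort=True):
        rng = np.random.default_rng([config.seed, 303, int(das)])
        dem = _smooth_dem(h, w, t_rgb, config)
        canopy_h = np.zeros((h, w))          # crown height above ground
        maize = np.zeros((h, w), dtype=bool)
        refl = {b: np.full((h, w), _SOIL_REFL[b]) for b in _SOIL_REFL}
        dn = np.empty((h, w, 3))
        dn[:] = _SOIL_DN

        for rec in sub.itertuples(index=False):
            pid = rec.plot_id
            if pid not in plot_lookup:
                raise ValueError(f"plot grid too large: unknown plot {pid!r}")
            lai = float(rec.LAI)
            target = float(rec.coverage)
            growth = float(getattr(rec, "growth", target))
            if lai <= 0 or target <= 0:
                continue
            _render_plot(config, rec, plot_lookup[pid], t_rgb, (h, w),
                         target, lai, growth, float(rec.PH_m),
                         canopy_h, maize, refl, dn)

        # shadow: canopy mask shifted towards south-east, over non-canopy
        shadow = np.zeros_like(maize)
        shadow[shift_px:, shift_px:] = maize[:-shift_px, :-shift_px]
        shadow &= ~maize
        # scattered bright debris ("other") on bare soil
        soil_mask = ~(maize | shadow)
        n_debris = int(soil_mask.sum() * _DEBRIS_FRACTION)
        labels = np.zeros((h, w), dtype=np.uint8)
        labels[maize] = CLASS_CODES["maize"]
        labels[shadow] = CLASS_CODES["shadow"]
        if n_debris > 0:
            flat = np.flatnonzero(soil_mask.ravel())
            pick = rng.choice(flat, size=n_debris, replace=False)
            dr, dc = np.unravel_index(pick, (h, w))
            labels[dr, dc] = CLASS_CODES["other"]
            dn[dr, dc] = _DEBRIS_DN
        dn[shadow] *= _SHADOW_FACTOR
        for b in refl:
            refl[b][shadow] *= 0.6

        if noise.dn_sd > 0:
            dn = dn + rng.normal(0.0, noise.dn_sd, dn.shape)
        rgb_arr = np.clip(np.rint(dn), 0, 255).astype(np.uint8)

        # multispectral: exact soil/leaf linear mixture by block averaging
        ms_bands = {}
        for b in ("green", "red", "red_edge", "nir"):
            coarse = refl[b].reshape(h // ratio, ratio,
                                     w // ratio, ratio).mean(axis=(1, 3))
            if noise.reflectance_sd > 0:
                coarse = coarse + rng.normal(0.0, noise.reflectance_sd,
                                             coarse.shape)
            ms_bands[b] = np.clip(coarse, 0.0, 1.0).astype(np.float32)

        dsm = dem + (rng.normal(0.0, noise.dsm_sd, (h, w))
                     if noise.dsm_sd > 0 else 0.0)
        # canopy pixels: ground + crown height (+ noise), never below ground
        ch = canopy_h[maize]
        if noise.dsm_sd > 0:
            ch = np.clip(ch + rng.normal(0.0, noise.dsm_sd, ch.shape), 0, None)
        dsm[maize] = dem[maize] + ch

        mk = lambda arr, names, unit, tr: RasterGrid(
            bands=dict(zip(names, arr)), transform=tr,
            units={n: unit for n in names})
        scene.stages[int(das)] = StageScene(
            das=int(das),
            rgb=mk(np.moveaxis(rgb_arr, -1, 0), ("red", "green", "blue"),
                   "DN", t_rgb),
            ms=RasterGrid(bands=ms_bands, transform=t_ms,
                          units={b: "reflectance" for b in ms_bands}),
            dsm=RasterGrid({"dsm": dsm.astype(np.float32)}, t_rgb,
                           units={"dsm": "m"}),
            dem=RasterGrid({"dem": dem.astype(np.float32)}, t_rgb,
                           units={"dem": "m"}),
            labels=RasterGrid({"class": labels}, t_rgb,
                              units={"class": "class"}),
        )
    return scene


def _render_plot(config, rec, plot, t_rgb, shape, target, lai, growth, ph,
                 canopy_h, maize, refl, dn) -> None:
    """Render one plot's canopy into the full-scene stage arrays in place."""
    h, w = shape
    centers, mult = _plant_centers(config, int(rec.plot_row),
                                   int(rec.plot_col))
    # window: full sown rectangle + margin for crown spill
    x0, y0, x1, y1 = config.plot_rect(int(rec.plot_row), int(rec.plot_col))
    margin = 0.15
    rows, cols = t_rgb.world_to_pixel(
        np.array([x0 - margin, x1 + margin]),
        np.array([y0 - margin, y1 + margin]))
    r0 = max(int(np.floor(rows.min())), 0)
    r1 = min(int(np.ceil(rows.max())), h)
    c0 = max(int(np.floor(cols.min())), 0)
    c1 = min(int(np.ceil(cols.max())), w)
    rr = np.arange(r0, r1)
    cc = np.arange(c0, c1)
    px, py = t_rgb.pixel_center(rr[:, None], cc[None, :])
    # scaled squared distance to the nearest plant (per-plant multipliers)
    d2 = ((px[..., None] - centers[None, None, :, 0]) ** 2
          + (py[..., None] - centers[None, None, :, 1]) ** 2)
    m = (d2 / (mult[None, None, :] ** 2)).min(axis=2)

    # threshold on m chosen so the canopy fraction over the analysis polygon
    # matches the Beer-Lambert coverage to within one pixel
    win = plot.pixel_window(RasterGrid({"_": np.empty(shape)}, t_rgb))
    poly_full = win.full_mask(shape)[r0:r1, c0:c1]
    mpoly = m[poly_full]
    n_poly = mpoly.size
    k = int(round(target * n_poly))
    if k <= 0:
        return
    if k >= n_poly:
        r2 = mpoly.max() + 1e-12
    else:
        r2 = np.partition(mpoly, k - 1)[k - 1]
    canopy = m <= r2
    profile = np.sqrt(np.clip(1.0 - m / r2, 0.0, 1.0))  # hemispheric crown

    leaf = leaf_reflectance(lai)
    leaf_dn = leaf_color_dn(growth)
    sl_h = (slice(r0, r1), slice(c0, c1))
    sub_maize = maize[sl_h]
    sub_maize |= canopy
    ch = canopy_h[sl_h]
    np.maximum(ch, np.where(canopy, ph * profile, 0.0), out=ch)
    for b, val in leaf.items():
        band = refl[b][sl_h]
        band[canopy] = val
    # within-canopy brightness follows the crown profile (texture source)
    shade = 0.70 + 0.55 * profile[canopy]
    dn[sl_h][canopy] = leaf_dn[None, :] * shade[:, None]
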