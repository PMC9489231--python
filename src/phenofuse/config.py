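"""Scene and trait-model configuration.

The defaults encode the study design the pipeline emulates: a breeding trial
of 55 sampled plots (5 x 11 grid), plot footprint 1.2 m x 2.5 m, observed at
four stages (27, 37, 56 and 87 days after sowing), imaged at 1 cm RGB and
3 cm multispectral ground sampling distance.  Trait dispersion targets a
pooled coefficient of variation above 50 % for every trait, with means close
to PH 1.27 m, LAI 3.1, fresh weight 3.7 kg/m2 and dry weight 0.74 kg/m2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class TraitParams:
    """Latent growth-model parameters for per-plot trait trajectories.

    Each plot p carries a logistic growth state
    ``g(p, s) = 1 / (1 + exp(-rate_p * (DAS_s - mid_p)))`` and plot-specific
    asymptotes, giving ``LAI = Lmax_p * g`` and ``PH = Hmax_p * g``.  Canopy
    coverage follows a Beer-Lambert gap-fraction link
    ``1 - exp(-k_ext * LAI)``; fresh weight is allometric in LAI,
    ``FW = a * LAI^b * (1 + eps)``; dry weight applies a stage-wise dry-matter
    fraction to FW.
    """

    lai_max_mean: float = 4.65      # lognormal mean of per-plot LAI asymptote
    lai_max_cv: float = 0.25        # lognormal CV of LAI asymptote
    ph_max_mean: float = 2.05       # m, lognormal mean of height asymptote
    ph_max_cv: float = 0.12
    growth_rate_mean: float = 0.13  # 1/day, logistic rate
    growth_rate_sd: float = 0.02
    growth_mid_mean: float = 40.0   # DAS at inflection
    growth_mid_sd: float = 4.0
    k_ext: float = 0.7              # canopy extinction coefficient
    fw_allometry_a: float = 460.0   # g/m2 at LAI = 1
    fw_allometry_b: float = 1.6     # allometric exponent
    dry_matter_fractions: tuple[float, ...] = (0.10, 0.13, 0.20, 0.28)
    lai_noise_sd: float = 0.04      # multiplicative measurement noise
    ph_noise_sd: float = 0.03
    fw_noise_sd: float = 0.08
    dmf_noise_sd: float = 0.05

    def validate(self) -> None:
        for name in ("lai_max_mean", "ph_max_mean", "growth_rate_mean",
                     "growth_mid_mean", "fw_allometry_a", "fw_allometry_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TraitParams.{name} must be > 0")
        for name in ("lai_max_cv", "ph_max_cv", "growth_rate_sd",
                     "growth_mid_sd", "k_ext", "lai_noise_sd", "ph_noise_sd",
                     "fw_noise_sd", "dmf_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"TraitParams.{name} must be >= 0")
        if not self.dry_matter_fractions:
            raise ValueError("dry_matter_fractions must be non-empty")
        if any(not 0 < f < 1 for f in self.dry_matter_fractions):
            raise ValueError("dry_matter_fractions must lie in (0, 1)")


@dataclass(frozen=True)
class NoiseParams:
    """Sensor noise standard deviations."""

    reflectance_sd: float = 0.01   # multispectral bands, reflectance units
    dn_sd: float = 6.0             # RGB digital numbers (0-255 scale)
    dsm_sd: float = 0.02           # DSM height, metres

    def validate(self) -> None:
        for name in ("reflectance_sd", "dn_sd", "dsm_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"NoiseParams.{name} must be >= 0")

    def zeroed(self) -> "NoiseParams":
        return NoiseParams(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic field trial.

    Plots are laid out on a regular grid, plot *width* along x (east) and
    *length* along y, separated by alleys on all sides.  ``plot_buffer`` is
    the margin excluded from each plot's analysis polygon to avoid mixed
    border pixels.
    """

    n_plot_rows: int = 5
    n_plot_cols: int = 11
    plot_width: float = 1.2       # m, east-west
    plot_length: float = 2.5      # m, north-south
    alley_width: float = 0.4      # m between plots and around the field
    plot_buffer: float = 0.1      # m excluded from plot edges
    gsd_rgb: float = 0.01         # m / pixel, RGB + DSM/DEM grid
    gsd_ms: float = 0.03          # m / pixel, multispectral grid
    stages: tuple[int, ...] = (27, 37, 56, 87)   # days after sowing
    trait_params: TraitParams = field(default_factory=TraitParams)
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plot_rows < 1 or self.n_plot_cols < 1:
            raise ValueError("plot grid dimensions must be >= 1")
        for name in ("plot_width", "plot_length", "alley_width",
                     "gsd_rgb", "gsd_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SceneConfig.{name} must be > 0")
        if self.gsd_rgb > self.gsd_ms:
            raise ValueError("gsd_rgb must be <= gsd_ms")
        if self.plot_buffer < 0 or 2 * self.plot_buffer >= min(
                self.plot_width, self.plot_length):
            raise ValueError("plot_buffer must be >= 0 and leave a non-empty "
                             "plot interior")
        stages = tuple(int(s) for s in self.stages)
        if any(b <= a for a, b in zip(stages, stages[1:])) or not stages:
            raise ValueError("stages must be a non-empty strictly increasing "
                             "sequence")
        object.__setattr__(self, "stages", stages)
        if len(self.trait_params.dry_matter_fractions) != len(stages):
            raise ValueError("dry_matter_fractions must match the number of "
                             "stages")
        self.trait_params.validate()
        self.noise_params.validate()

    # -- layout helpers -------------------------------------------------
    @property
    def n_plots(self) -> int:
        return self.n_plot_rows * self.n_plot_cols

    @property
    def field_width(self) -> float:
        return (self.n_plot_cols * (self.plot_width + self.alley_width)
                + self.alley_width)

    @property
    def field_length(self) -> float:
        return (self.n_plot_rows * (self.plot_length + self.alley_width)
                + self.alley_width)

    def plot_id(self, row: int, col: int) -> str:
        return f"P{row * self.n_plot_cols + col + 1:03d}"

    def plot_rect(self, row: int, col: int) -> tuple[float, float, float, float]:
        """Full sown rectangle (minx, miny, maxx, maxy), y increasing north."""
        x0 = self.alley_width + col * (self.plot_width + self.alley_width)
        y1 = self.field_length - (
            self.alley_width + row * (self.plot_length + self.alley_width))
        return x0, y1 - self.plot_length, x0 + self.plot_width, y1

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if isinstance(d.get("trait_params"), dict):
            tp = dict(d["trait_params"])
            if "dry_matter_fractions" in tp:
                tp["dry_matter_fractions"] = tuple(tp["dry_matter_fractions"])
            d["trait_params"] = TraitParams(**tp)
        if isinstance(d.get("noise_params"), dict):
            d["noise_params"] = NoiseParams(**d["noise_params"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["stages"] = list(d["stages"])
        d["trait_params"]["dry_matter_fractions"] = list(
            d["trait_params"]["dry_matter_fractions"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
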