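"""Configuration objects for the synthetic generators and the pipeline.

All stochastic stages take an explicit integer seed; identical configs with
identical seeds reproduce outputs bit for bit.  Configs can be loaded from a
single YAML file holding the spectra section, the orchard section, the Monte
Carlo settings and a global seed (see :func:`load_run_config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "SpectraConfig",
    "OrchardConfig",
    "RunConfig",
    "load_run_config",
    "save_run_config",
]

#: Fixed-effect coefficients (% SSC; the week slope is % SSC per WAFB) used as
#: generator defaults.  Baselines carry effect 0 by construction: year 2016,
#: bottom sector, standard crop load, ambient cell-division temperature,
#: calcium applied.
DEFAULT_FIXED_EFFECTS: dict[str, float] = {
    "intercept": 3.78,
    "week": 0.31,
    "year:2017": 1.47,
    "year:2018": 1.85,
    "sector:middle": 0.11,
    "sector:top": 0.39,
    "crop_load:light": -0.07,
    "crop_load:heavy": -0.03,
    "temperature_trt:cold": 0.15,
    "temperature_trt:warm": 0.21,
    "calcium:without": 0.17,
}

#: Time-interaction coefficients (% SSC per WAFB) for the non-baseline factor
#: levels.  Derived from the published early/late effect offsets of the
#: treatment levels (difference over 100 days, converted to weeks).
DEFAULT_INTERACTION_EFFECTS: dict[str, float] = {
    "sector:middle": 0.0154,
    "sector:top": 0.0252,
    "crop_load:light": 0.0161,
    "crop_load:heavy": -0.0070,
    "temperature_trt:cold": -0.0119,
    "temperature_trt:warm": -0.0091,
    "calcium:without": 0.0,
    "year:2017": 0.0,
    "year:2018": 0.0,
}

FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "sector": ("bottom", "middle", "top"),
    "crop_load": ("standard", "light", "heavy"),
    "temperature_trt": ("ambient", "cold", "warm"),
    "calcium": ("with", "without"),
}

#: First level of each tuple above is the baseline (dummy-coded to zero).
BASELINE_LEVELS: dict[str, str] = {k: v[0] for k, v in FACTOR_LEVELS.items()}


@dataclass
class SpectraConfig:
    """Forward model for point-spectrometer absorbance scans.

    The instrument grid runs from ``wavelength_start`` to ``wavelength_stop``
    in ``wavelength_step`` nm increments (defaults 310/1100/3 nm, the grid of
    a handheld Vis/NIR fruit spectrometer).  Each scan is a smooth baseline
    plus SSC-proportional Gaussian absorption bands plus white noise;
    temperature shifts the band centers to mimic hydrogen-bonding effects.
    """

    wavelength_start: float = 310.0
    wavelength_stop: float = 1100.0
    wavelength_step: float = 3.0
    n_samples: int = 2400
    years: tuple[int, ...] = (2016, 2017, 2018)
    ssc_range: tuple[float, float] = (5.0, 14.0)
    noise_sd_absorbance: float = 0.0055
    temperature_levels: tuple[float, ...] = (10.0, 20.0, 30.0)
    temperature_shift_per_degC: float = 0.15
    band_centers: tuple[float, ...] = (840.0, 960.0)
    band_widths: tuple[float, ...] = (25.0, 25.0)
    band_gains: tuple[float, ...] = (0.004, 0.003)
    duplicate_scans: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.wavelength_step <= 0 or self.wavelength_stop <= self.wavelength_start:
            raise ValueError("wavelength grid must be strictly increasing")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        lo, hi = self.ssc_range
        if not lo < hi:
            raise ValueError("ssc_range lower bound must be below upper bound")
        if self.noise_sd_absorbance < 0:
            raise ValueError("noise_sd_absorbance must be >= 0")
        if not (len(self.band_centers) == len(self.band_widths) == len(self.band_gains)):
            raise ValueError("band_centers/widths/gains must have equal length")
        for c in self.band_centers:
            if not (self.wavelength_start <= c <= self.wavelength_stop):
                raise ValueError(f"band center {c} nm outside the wavelength grid")


@dataclass
class OrchardConfig:
    """Generative model for the longitudinal orchard SSC table.

    ``design`` maps year -> (number of trees, total number of marked fruit in
    that year); fruit are spread as evenly as possible over the trees.  The
    default design spans three seasons with 237 trees and 1274 fruit, visited
    weekly for 14 weeks after June drop (WAFB 8..21).

    The response is the linear mixed-effect generative process: population
    intercept and weekly slope, dummy-coded treatment main effects and
    time-interaction effects, independent Gaussian random intercepts and
    slopes per tree and per fruit, and an observation-level residual.
    """

    design: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {2016: (33, 198), 2017: (96, 603), 2018: (108, 473)}
    )
    weeks: tuple[int, ...] = tuple(range(8, 22))
    fixed_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS)
    )
    interaction_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERACTION_EFFECTS)
    )
    sd_tree_intercept: float = 0.3
    sd_tree_slope: float = 0.02
    sd_fruit_intercept: float = 0.3
    sd_fruit_slope: float = 0.02
    sd_residual: float = 0.3
    dropout_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.design:
            raise ValueError("design must name at least one year")
        for year, (n_trees, n_fruit) in self.design.items():
            if n_trees <= 0 or n_fruit <= 0:
                raise ValueError(f"year {year}: trees and fruit counts must be positive")
            if n_fruit < n_trees:
                raise ValueError(f"year {year}: need at least one fruit per tree")
        if len(self.weeks) == 0:
            raise ValueError("sampling schedule is empty")
        for name in (
            "sd_tree_intercept",
            "sd_tree_slope",
            "sd_fruit_intercept",
            "sd_fruit_slope",
            "sd_residual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")


@dataclass
class RunConfig:
    """Top-level configuration for the end-to-end pipeline."""

    seed: int = 0
    output_dir: str = "runs/demo"
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    orchard: OrchardConfig = field(default_factory=OrchardConfig)
    mc_modes: tuple[str, ...] = ("sample_size", "lab_error")
    mc_reps: int = 50
    lme_models: tuple[int, ...] = (1, 2, 3)

    def validate(self) -> None:
        self.spectra.validate()
        self.orchard.validate()
        if self.mc_reps < 1:
            raise ValueError("mc_reps must be >= 1")
        for m in self.lme_models:
            if m not in (1, 2, 3):
                raise ValueError(f"unknown LME model id {m}")


def _coerce_spectra(d: Mapping) -> SpectraConfig:
    kw = dict(d)
    for key in ("years", "temperature_levels", "band_centers", "band_widths", "band_gains"):
        if key in kw:
            kw[key] = tuple(kw[key])
    if "ssc_range" in kw:
        kw["ssc_range"] = tuple(kw["ssc_range"])
    return SpectraConfig(**kw)


def _coerce_orchard(d: Mapping) -> OrchardConfig:
    kw = dict(d)
    if "design" in kw:
        kw["design"] = {int(y): tuple(v) for y, v in kw["design"].items()}
    if "weeks" in kw:
        kw["weeks"] = tuple(kw["weeks"])
    return OrchardConfig(**kw)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file; missing sections use defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    kw: dict = {}
    if "seed" in raw:
        kw["seed"] = int(raw["seed"])
    if "output_dir" in raw:
        kw["output_dir"] = str(raw["output_dir"])
    if "spectra" in raw:
        kw["spectra"] = _coerce_spectra(raw["spectra"])
    if "orchard" in raw:
        kw["orchard"] = _coerce_orchard(raw["orchard"])
    if "mc_modes" in raw:
        kw["mc_modes"] = tuple(raw["mc_modes"])
    if "mc_reps" in raw:
        kw["mc_reps"] = int(raw["mc_reps"])
    if "lme_models" in raw:
        kw["lme_models"] = tuple(int(m) for m in raw["lme_models"])
    cfg = RunConfig(**kw)
    # global seed cascades into sections that kept their default seed
    if "seed" in raw:
        if "spectra" not in raw or "seed" not in raw["spectra"]:
            cfg.spectra.seed = cfg.seed
        if "orchard" not in raw or "seed" not in raw["orchard"]:
            cfg.orchard.seed = cfg.seed
    cfg.validate()
    return cfg


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    d = asdict(cfg)
    # YAML-friendly: tuples to lists
    def _clean(obj):
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        return obj

    Path(path).write_text(yaml.safe_dump(_clean(d), sort_keys=False))
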