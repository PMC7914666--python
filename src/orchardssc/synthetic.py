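"""Synthetic data generators for the calibration and longitudinal stages.

Two generators stand in for field data that is not publicly deposited:

* :func:`generate_spectra` draws absorbance scans from a known forward model
  (smooth baseline + SSC-proportional Gaussian absorption bands + white
  noise), so the whole spectra -> second derivative -> PLSR chain can be
  tested against a known truth.
* :func:`generate_orchard` draws a longitudinal orchard table from the linear
  mixed-effect generative process (random intercepts and slopes per tree and
  per fruit, treatment main effects and time interactions), so the model
  fitting stage can be checked by parameter recovery.

Both return plain :class:`pandas.DataFrame` tables; see the column contracts
in each docstring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    BASELINE_LEVELS,
    FACTOR_LEVELS,
    OrchardConfig,
    SpectraConfig,
)

__all__ = [
    "wavelength_grid",
    "generate_spectra",
    "generate_orchard",
    "generate_harvest",
    "spectra_matrix",
]


def wavelength_grid(config: SpectraConfig) -> np.ndarray:
    """Uniform wavelength grid (nm) implied by the config.

    Channels sit on integer multiples of the sampling step inside
    [start, stop]; at the default 3 nm step this places channels exactly on
    the 729 and 975 nm bounds of the modelling window.
    """
    step = config.wavelength_step
    first = step * np.ceil(config.wavelength_start / step)
    last = step * np.floor(config.wavelength_stop / step)
    n = int(round((last - first) / step)) + 1
    return first + step * np.arange(n)


def _baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth instrument/fruit-matrix baseline, identical for every scan.

    A gentle downward linear trend plus one broad chlorophyll-like bump in the
    visible; carries no SSC information by construction.
    """
    lam = wavelengths
    return (
        0.8
        - 2.0e-4 * (lam - 310.0)
        + 0.15 * np.exp(-0.5 * ((lam - 680.0) / 60.0) ** 2)
    )


def generate_spectra(config: SpectraConfig) -> pd.DataFrame:
    """Draw absorbance scans from the Gaussian-band forward model.

    For a scan with soluble solids content ``ssc`` (% SSC) at temperature
    ``T`` the absorbance at wavelength ``lam`` is::

        A(lam) = baseline(lam)
                 + ssc * sum_b gain_b * exp(-((lam - c_b - s*(T-20))^2) / (2 w_b^2))
                 + eps(lam),   eps ~ N(0, noise_sd^2) iid

    where ``c_b``, ``w_b``, ``gain_b`` are the band centers/widths/gains and
    ``s`` the temperature shift per degree Celsius.

    Returns a wide table with one row per scan: ``sample_id``, ``year``,
    ``temperature_C``, ``ssc_ref`` and one column per wavelength named by the
    integer nanometre value.  Reference SSC values are drawn uniformly over
    ``config.ssc_range``; years and temperatures are balanced.  With
    ``duplicate_scans`` two scans of the same fruit (same SSC, independent
    noise) are emitted per sample, mimicking scans on two sides of a fruit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lam = wavelength_grid(config)
    n = config.n_samples
    years = np.array(config.years)[np.arange(n) % len(config.years)]
    temps = np.array(config.temperature_levels)[
        (np.arange(n) // len(config.years)) % len(config.temperature_levels)
    ]
    lo, hi = config.ssc_range
    ssc = rng.uniform(lo, hi, size=n)

    reps = 2 if config.duplicate_scans else 1
    rows = np.repeat(np.arange(n), reps)
    shift = config.temperature_shift_per_degC * (temps[rows] - 20.0)

    # n_scans x n_wavelengths response matrix
    signal = np.zeros((len(rows), lam.size))
    for c, w, g in zip(config.band_centers, config.band_widths, config.band_gains):
        centers = c + shift
        signal += g * np.exp(-0.5 * ((lam[None, :] - centers[:, None]) / w) ** 2)
    absorb = _baseline(lam)[None, :] + ssc[rows, None] * signal
    if config.noise_sd_absorbance > 0:
        absorb = absorb + rng.normal(0.0, config.noise_sd_absorbance, size=absorb.shape)

    scan_suffix = np.tile(np.arange(reps), n)
    sample_id = [f"S{r:05d}" + (f"_{s}" if reps > 1 else "") for r, s in zip(rows, scan_suffix)]
    out = pd.DataFrame(
        {
            "sample_id": sample_id,
            "year": years[rows],
            "temperature_C": temps[rows],
            "ssc_ref": ssc[rows],
        }
    )
    spec = pd.DataFrame(absorb, columns=[str(int(round(v))) for v in lam])
    return pd.concat([out, spec], axis=1)


def spectra_matrix(spectra: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a wide spectra table into (wavelengths nm, absorbance matrix)."""
    wl_cols = [c for c in spectra.columns if str(c).lstrip("-").isdigit()]
    wavelengths = np.array([float(c) for c in wl_cols])
    order = np.argsort(wavelengths)
    wl_cols = [wl_cols[i] for i in order]
    return wavelengths[order], spectra[wl_cols].to_numpy(dtype=float)


def _assign_treatments(n_trees: int, rng: np.random.Generator) -> list[dict[str, str]]:
    """Randomised full cross of crop load x temperature x calcium over trees."""
    combos = [
        {"crop_load": c, "temperature_trt": t, "calcium": ca}
        for c in FACTOR_LEVELS["crop_load"]
        for t in FACTOR_LEVELS["temperature_trt"]
        for ca in FACTOR_LEVELS["calcium"]
    ]
    reps = -(-n_trees // len(combos))
    pool = combos * reps
    idx = rng.permutation(len(pool))[:n_trees]
    return [pool[i] for i in idx]


def generate_orchard(config: OrchardConfig) -> pd.DataFrame:
    """Draw a longitudinal orchard SSC table from the mixed-effect process.

    Each observation of fruit *i* on tree *j* at week *t* is::

        ssc = b0 + u_j0 + u_i0 + (b1 + u_j1 + u_i1) * t
              + sum_X (bX + bY * t) * [level X active]  + e

    with independent Gaussian random effects (tree intercept/slope, fruit
    intercept/slope) and residual, all standard deviations from the config.
    Treatments are a randomised cross over trees; the three canopy sectors
    cycle over the fruit within each tree.  Columns: ``fruit_id``,
    ``tree_id``, ``year``, ``wafb``, ``dafb`` (= 7 * wafb), ``sector``,
    ``crop_load``, ``temperature_trt``, ``calcium``, ``ssc``, plus the
    generating truth per observation (``true_fixed`` and the random draws) to
    support variance-accounting checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fe = config.fixed_effects
    ie = config.interaction_effects
    weeks = np.asarray(config.weeks, dtype=float)

    recs: list[dict] = []
    for year in sorted(config.design):
        n_trees, n_fruit = config.design[year]
        trt = _assign_treatments(n_trees, rng)
        # spread fruit as evenly as possible over trees
        per_tree = np.full(n_trees, n_fruit // n_trees)
        per_tree[: n_fruit % n_trees] += 1
        fruit_counter = 0
        for j in range(n_trees):
            tree_id = f"T{year}_{j:03d}"
            u_j0 = rng.normal(0.0, config.sd_tree_intercept)
            u_j1 = rng.normal(0.0, config.sd_tree_slope)
            for i in range(per_tree[j]):
                fruit_id = f"F{year}_{fruit_counter:04d}"
                fruit_counter += 1
                sector = FACTOR_LEVELS["sector"][i % 3]
                u_i0 = rng.normal(0.0, config.sd_fruit_intercept)
                u_i1 = rng.normal(0.0, config.sd_fruit_slope)
                levels = {"sector": sector, **trt[j], "year": str(year)}
                beta_x = 0.0
                beta_y = 0.0
                for factor, level in levels.items():
                    key = f"{factor}:{level}"
                    beta_x += fe.get(key, 0.0)
                    beta_y += ie.get(key, 0.0)
                keep = np.ones(weeks.size, dtype=bool)
                if config.dropout_prob > 0:
                    # once a fruit drops it stays dropped (lost fruit)
                    alive = rng.random(weeks.size) >= config.dropout_prob
                    keep = np.cumprod(alive).astype(bool)
                e = rng.normal(0.0, config.sd_residual, size=weeks.size)
                fixed = fe["intercept"] + fe["week"] * weeks + beta_x + beta_y * weeks
                ssc = fixed + u_j0 + u_i0 + (u_j1 + u_i1) * weeks + e
                for k in np.nonzero(keep)[0]:
                    recs.append(
                        {
                            "fruit_id": fruit_id,
                            "tree_id": tree_id,
                            "year": year,
                            "wafb": weeks[k],
                            "dafb": 7.0 * weeks[k],
                            "sector": sector,
                            "crop_load": trt[j]["crop_load"],
                            "temperature_trt": trt[j]["temperature_trt"],
                            "calcium": trt[j]["calcium"],
                            "ssc": ssc[k],
                            "true_fixed": fixed[k],
                            "u_tree_int": u_j0,
                            "u_tree_slope": u_j1,
                            "u_fruit_int": u_i0,
                            "u_fruit_slope": u_i1,
                        }
                    )
    return pd.DataFrame.from_records(recs)


def generate_harvest(
    n_batches_per_level: int = 3,
    level_means: dict[str, float] | None = None,
    sd_destructive: float = 0.5,
    sd_nondestructive: float = 0.7,
    method_bias: float = 0.0,
    batch_size: int = 8,
    blender_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate the harvest comparison of destructive vs modelled SSC.

    Destructive rows pool a batch of ``batch_size`` fruit (the juice of the
    batch is blended before refractometry): the recorded value is the batch
    mean plus blender noise.  Non-destructive rows are individual fruit whose
    SSC comes from the spectral calibration, hence the larger spread.
    ``method_bias`` shifts the non-destructive method; 0 means both methods
    share the level mean.  Columns: method, treatment_level, ssc.
    """
    if level_means is None:
        level_means = {"bottom": 11.2, "middle": 11.7, "top": 12.1}
    rng = np.random.default_rng(seed)
    recs = []
    for level, mu in level_means.items():
        for b in range(n_batches_per_level):
            fruit = rng.normal(mu, sd_destructive, size=batch_size)
            pooled = fruit.mean() + rng.normal(0.0, blender_sd)
            recs.append({"method": "destructive", "treatment_level": level, "ssc": pooled})
        for _ in range(n_batches_per_level * batch_size):
            val = rng.normal(mu + method_bias, sd_nondestructive)
            recs.append({"method": "nondestructive", "treatment_level": level, "ssc": val})
    return pd.DataFrame.from_records(recs)
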