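"""Monte Carlo sensitivity analysis of the PLSR calibration design.

Repeatedly resamples calibration sets from a reference pool of
second-derivative spectra and maps the validation RMSEP against:

* calibration sample size per year (``sample_size`` mode),
* artificial laboratory (refractometer) error added to the calibration
  responses only (``lab_error`` mode),
* the SSC range of the validation samples (``ssc_range`` mode),
* train-year x validate-year transfer (``transfer`` mode),
* scan temperature of the validation samples (``temperature`` mode).

Every rep draws a fresh validation set and a disjoint, year- and SSC-
stratified calibration set, fits the PLSR calibration and records the RMSEP;
results are summarised as mean +/- sd over reps.  Per-rep seeds derive from
the master seed through a spawning scheme, so reps are independent and any
single rep can be reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsr import MAX_COMPONENTS, fit_plsr, predict
from .synthetic import spectra_matrix

__all__ = [
    "SAMPLE_SIZE_GRID",
    "NOISE_SD_GRID",
    "SSC_BIN_EDGES",
    "MCSetting",
    "MCResult",
    "stratified_sample",
    "add_lab_noise",
    "run_setting",
    "run_grid",
]

#: Calibration sizes per year explored in sample_size mode.
SAMPLE_SIZE_GRID = (20, 30, 40, 50, 75, 100, 125, 150, 175, 200, 300, 400, 500)
#: Added laboratory error standard deviations (% SSC) in lab_error mode.
NOISE_SD_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0, 2.0)
#: Interior breakpoints of the SSC validation bins (<9, 9-10, ..., >13 % SSC).
SSC_BIN_EDGES = (9.0, 10.0, 11.0, 12.0, 13.0)

_MODES = ("sample_size", "lab_error", "ssc_range", "transfer", "temperature")

#: Validation-set size per year by mode, mirroring the sizes used for the
#: corresponding published analyses.
_DEFAULT_N_VALIDATION = {
    "sample_size": 200,
    "lab_error": 100,
    "ssc_range": 100,
    "transfer": 100,
    "temperature": 200,
}


@dataclass
class MCSetting:
    """One Monte Carlo scenario.

    ``n_components=None`` selects the component count by LOO-CV inside every
    rep (the calibration procedure proper); an integer fixes it, trading
    fidelity for speed on large grids.
    """

    mode: str = "sample_size"
    n_cal_per_year: int = 500
    noise_sd: float = 0.0
    train_years: tuple[int, ...] = ()
    validate_years: tuple[int, ...] = ()
    ssc_bins: tuple[float, ...] = SSC_BIN_EDGES
    n_validation_per_year: int | None = None
    reps: int = 500
    seed: int = 0
    max_components: int = MAX_COMPONENTS
    n_components: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if list(self.ssc_bins) != sorted(self.ssc_bins):
            raise ValueError("ssc_bins must be ordered")
        if self.n_validation_per_year is None:
            self.n_validation_per_year = _DEFAULT_N_VALIDATION[self.mode]


@dataclass
class MCResult:
    """Mean +/- sd RMSEP over reps, plus the per-rep values and breakdowns."""

    setting: MCSetting
    rmsep_per_rep: np.ndarray
    breakdown: pd.DataFrame | None = None

    @property
    def mean_rmsep(self) -> float:
        return float(np.mean(self.rmsep_per_rep))

    @property
    def sd_rmsep(self) -> float:
        return float(np.std(self.rmsep_per_rep, ddof=1)) if self.rmsep_per_rep.size > 1 else 0.0


def _year_pool(meta: pd.DataFrame, year, exclude: np.ndarray) -> np.ndarray:
    pool = np.flatnonzero((meta["year"].to_numpy() == year) & ~exclude)
    return pool


def stratified_sample(
    reference: pd.DataFrame,
    n_per_year: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exclude: np.ndarray | None = None,
    years: tuple | None = None,
    ssc_balance: bool = True,
    n_bins: int = 4,
) -> np.ndarray:
    """Draw a calibration subset: ``n_per_year`` rows per year, SSC-balanced.

    Rows are drawn without replacement, never from ``exclude`` (boolean mask,
    e.g. the validation set).  Within each year the pool is cut into
    ``n_bins`` SSC quantile bins and the draw is spread evenly over the bins
    (remainders and short bins fall back to the remaining pool), so the
    calibration set covers the response range.  Returns positional indices
    into ``reference``.  Raises ``ValueError`` naming the first year whose
    pool is too small.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if exclude is None:
        exclude = np.zeros(len(reference), dtype=bool)
    if years is None:
        years = tuple(sorted(reference["year"].unique()))
    ssc = reference["ssc_ref"].to_numpy(dtype=float)
    chosen: list[np.ndarray] = []
    for year in years:
        pool = _year_pool(reference, year, exclude)
        if pool.size < n_per_year:
            raise ValueError(
                f"year {year}: only {pool.size} samples available, need {n_per_year}"
            )
        if not ssc_balance or np.unique(ssc[pool]).size < n_bins:
            chosen.append(rng.choice(pool, size=n_per_year, replace=False))
            continue
        qs = np.quantile(ssc[pool], np.linspace(0, 1, n_bins + 1)[1:-1])
        bin_of = np.searchsorted(qs, ssc[pool], side="right")
        take: list[np.ndarray] = []
        base, extra = divmod(n_per_year, n_bins)
        shortfall = 0
        leftover: list[np.ndarray] = []
        for b in range(n_bins):
            members = pool[bin_of == b]
            want = base + (1 if b < extra else 0)
            k = min(want, members.size)
            pick = rng.choice(members, size=k, replace=False) if k else np.empty(0, int)
            take.append(pick)
            shortfall += want - k
            leftover.append(np.setdiff1d(members, pick, assume_unique=False))
        if shortfall:
            rest = np.concatenate(leftover)
            take.append(rng.choice(rest, size=shortfall, replace=False))
        chosen.append(np.concatenate(take))
    return np.sort(np.concatenate(chosen))


def add_lab_noise(
    y: np.ndarray,
    s: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Add unbiased Gaussian laboratory error of sd ``s`` (% SSC) to ``y``.

    ``s = 0`` returns the input unchanged (the unperturbed calibration).
    """
    if s < 0:
        raise ValueError("noise sd must be >= 0")
    y = np.asarray(y, dtype=float)
    if s == 0:
        return y.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    return y + rng.normal(0.0, s, size=y.shape)


def _rmsep(y_hat: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def run_setting(setting: MCSetting, reference: pd.DataFrame) -> MCResult:
    """Run one Monte Carlo scenario against a reference pool.

    ``reference`` is a wide derivative-spectra table carrying ``year``,
    ``temperature_C`` and ``ssc_ref`` per row.  Laboratory noise (lab_error
    mode) perturbs calibration responses only — validation references are
    left untouched.
    """
    for col in ("year", "ssc_ref"):
        if col not in reference.columns:
            raise ValueError(f"reference set lacks required column {col!r}")
    reference = reference.reset_index(drop=True)
    wavelengths, X = spectra_matrix(reference)
    y = reference["ssc_ref"].to_numpy(dtype=float)
    years_all = tuple(sorted(reference["year"].unique()))
    train_years = setting.train_years or years_all
    validate_years = setting.validate_years or years_all

    seeds = np.random.SeedSequence(setting.seed).spawn(setting.reps)
    rmseps = np.empty(setting.reps)
    rows: list[dict] = []
    for rep in range(setting.reps):
        rng = np.random.default_rng(seeds[rep])
        try:
            val_idx = stratified_sample(
                reference,
                setting.n_validation_per_year,
                rng=rng,
                years=tuple(sorted(set(validate_years) | set(train_years)))
                if setting.mode == "transfer"
                else years_all,
            )
            val_mask = np.zeros(len(reference), dtype=bool)
            val_mask[val_idx] = True

            if setting.mode == "transfer":
                per_pair: dict[tuple, float] = {}
                overall: list[float] = []
                for ty in train_years:
                    cal_idx = stratified_sample(
                        reference,
                        setting.n_cal_per_year,
                        rng=rng,
                        exclude=val_mask,
                        years=(ty,),
                    )
                    model = fit_plsr(
                        X[cal_idx],
                        y[cal_idx],
                        max_components=setting.max_components,
                        n_components=setting.n_components,
                    )
                    for vy in validate_years:
                        sub = val_idx[reference["year"].to_numpy()[val_idx] == vy]
                        r = _rmsep(predict(model, X[sub]), y[sub])
                        per_pair[(ty, vy)] = r
                        rows.append(
                            {"rep": rep, "train_year": ty, "validate_year": vy, "rmsep": r}
                        )
                        overall.append(r)
                rmseps[rep] = float(np.mean(overall))
                continue

            cal_idx = stratified_sample(
                reference,
                setting.n_cal_per_year,
                rng=rng,
                exclude=val_mask,
                years=train_years,
            )
            y_cal = y[cal_idx]
            if setting.mode == "lab_error":
                y_cal = add_lab_noise(y_cal, setting.noise_sd, rng=rng)
            model = fit_plsr(
                X[cal_idx],
                y_cal,
                max_components=setting.max_components,
                n_components=setting.n_components,
            )
            y_hat = predict(model, X[val_idx])
            rmseps[rep] = _rmsep(y_hat, y[val_idx])

            if setting.mode == "ssc_range":
                edges = np.asarray(setting.ssc_bins, dtype=float)
                labels = np.searchsorted(edges, y[val_idx], side="right")
                names = (
                    [f"<{edges[0]:g}"]
                    + [f"{a:g}-{b:g}" for a, b in zip(edges[:-1], edges[1:])]
                    + [f">{edges[-1]:g}"]
                )
                for b in range(edges.size + 1):
                    m = labels == b
                    if m.any():
                        rows.append(
                            {
                                "rep": rep,
                                "bin": names[b],
                                "rmsep": _rmsep(y_hat[m], y[val_idx][m]),
                                "n": int(m.sum()),
                            }
                        )
            elif setting.mode == "temperature":
                temps = reference["temperature_C"].to_numpy(dtype=float)[val_idx]
                for t in np.unique(temps):
                    m = temps == t
                    rows.append(
                        {
                            "rep": rep,
                            "temperature_C": float(t),
                            "rmsep": _rmsep(y_hat[m], y[val_idx][m]),
                            "n": int(m.sum()),
                        }
                    )
        except ValueError as exc:
            raise ValueError(f"rep {rep} of mode {setting.mode!r} failed: {exc}") from exc

    breakdown = pd.DataFrame(rows) if rows else None
    return MCResult(setting=setting, rmsep_per_rep=rmseps, breakdown=breakdown)


def run_grid(
    mode: str,
    reference: pd.DataFrame,
    reps: int = 500,
    seed: int = 0,
    sample_sizes: tuple[int, ...] = SAMPLE_SIZE_GRID,
    noise_sds: tuple[float, ...] = NOISE_SD_GRID,
    n_cal_per_year: int = 500,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Sweep a mode's parameter grid; returns a tidy summary table.

    sample_size mode sweeps ``sample_sizes``; lab_error sweeps ``noise_sds``
    at ``n_cal_per_year``; the other modes are a single setting.  Each grid
    point gets its own derived seed.
    """
    out: list[dict] = []
    ss = np.random.SeedSequence(seed)
    if mode == "sample_size":
        children = ss.spawn(len(sample_sizes))
        for n, child in zip(sample_sizes, children):
            setting = MCSetting(
                mode=mode,
                n_cal_per_year=n,
                reps=reps,
                seed=child.generate_state(1)[0] % (2**31),
                n_components=n_components,
            )
            res = run_setting(setting, reference)
            out.append(
                {"mode": mode, "n_cal_per_year": n, "mean_rmsep": res.mean_rmsep, "sd_rmsep": res.sd_rmsep}
            )
    elif mode == "lab_error":
        children = ss.spawn(len(noise_sds))
        for s, child in zip(noise_sds, children):
            setting = MCSetting(
                mode=mode,
                n_cal_per_year=n_cal_per_year,
                noise_sd=s,
                reps=reps,
                seed=child.generate_state(1)[0] % (2**31),
                n_components=n_components,
            )
            res = run_setting(setting, reference)
            out.append(
                {"mode": mode, "noise_sd": s, "mean_rmsep": res.mean_rmsep, "sd_rmsep": res.sd_rmsep}
            )
    elif mode in ("transfer", "ssc_range", "temperature"):
        setting = MCSetting(
            mode=mode,
            n_cal_per_year=n_cal_per_year,
            reps=reps,
            seed=ss.generate_state(1)[0] % (2**31),
            n_components=n_components,
        )
        res = run_setting(setting, reference)
        if res.breakdown is not None and mode == "transfer":
            g = res.breakdown.groupby(["train_year", "validate_year"])["rmsep"]
            for (ty, vy), grp in g:
                out.append(
                    {
                        "mode": mode,
                        "train_year": ty,
                        "validate_year": vy,
                        "mean_rmsep": float(grp.mean()),
                        "sd_rmsep": float(grp.std(ddof=1)) if len(grp) > 1 else 0.0,
                    }
                )
        elif res.breakdown is not None:
            key = "bin" if mode == "ssc_range" else "temperature_C"
            for k, grp in res.breakdown.groupby(key)["rmsep"]:
                out.append(
                    {
                        "mode": mode,
                        key: k,
                        "mean_rmsep": float(grp.mean()),
                        "sd_rmsep": float(grp.std(ddof=1)) if len(grp) > 1 else 0.0,
                    }
                )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(out)
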