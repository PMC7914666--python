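"""End-to-end orchestration: generate -> preprocess -> calibrate ->
montecarlo -> lme -> compare-harvest, with a reproducibility manifest.

Stages communicate only through the CSV/JSON artifacts they write, so any
stage can be re-run or replaced independently.  The manifest records the
seeds, row counts and content checksums of every artifact; two runs of the
same config produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .harvest import method_difference
from .io import write_csv
from .lme import LMEModelSpec, evaluate_effects, fit_lme, model_compare
from .mc import run_grid
from .plsr import fit_plsr, predict, prediction_stats, save_model
from .preprocess import second_derivative
from .synthetic import generate_harvest, generate_orchard, generate_spectra, spectra_matrix

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return (and write) the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            "spectra": config.spectra.seed,
            "orchard": config.orchard.seed,
            "mc": config.seed,
            "harvest": config.seed,
            "sensitivity": config.seed,
        },
        "stages": {},
    }

    def record(stage: str, path: Path, n_rows: int) -> None:
        manifest["stages"].setdefault(stage, {})[path.name] = {
            "rows": n_rows,
            "sha256": _sha256(path),
        }

    # --- generate ---------------------------------------------------------
    spectra = generate_spectra(config.spectra)
    p = out / "spectra.csv"
    spectra.to_csv(p, index=False)
    record("generate", p, len(spectra))

    orchard = generate_orchard(config.orchard)
    p = out / "orchard.csv"
    write_csv(orchard, p, round2=("ssc",))
    record("generate", p, len(orchard))

    # --- preprocess -------------------------------------------------------
    deriv = second_derivative(spectra)
    p = out / "derivative.csv"
    deriv.to_csv(p, index=False)
    record("preprocess", p, len(deriv))

    # --- calibrate --------------------------------------------------------
    rng = np.random.default_rng(config.seed)
    n = len(deriv)
    val_mask = np.zeros(n, dtype=bool)
    val_mask[rng.choice(n, size=max(3, n // 5), replace=False)] = True
    wavelengths, X = spectra_matrix(deriv)
    y = deriv["ssc_ref"].to_numpy(dtype=float)
    model = fit_plsr(X[~val_mask], y[~val_mask], wavelengths=wavelengths)
    stats = prediction_stats(predict(model, X[val_mask]), y[val_mask], model.n_components)
    p = out / "plsr_model.json"
    save_model(model, p)
    record("calibrate", p, 1)
    stats_df = pd.DataFrame(
        [
            {
                "n_components": model.n_components,
                "rmsep": stats.rmsep,
                "adjusted_r2": stats.adjusted_r2,
                "bias_slope": stats.bias_slope,
                "bias_intercept": stats.bias_intercept,
                "n_validation": stats.n,
            }
        ]
    )
    p = out / "calibration_stats.csv"
    write_csv(stats_df, p, round2=("rmsep",))
    record("calibrate", p, 1)

    # --- montecarlo -------------------------------------------------------
    for mode in config.mc_modes:
        summary = run_grid(
            mode,
            deriv,
            reps=config.mc_reps,
            seed=config.seed,
            sample_sizes=(20, 100, 500),
            noise_sds=(0.0, 0.5, 2.0),
        )
        p = out / f"mc_{mode}_summary.csv"
        write_csv(summary, p, round2=("mean_rmsep", "sd_rmsep"))
        record("montecarlo", p, len(summary))

    # --- lme --------------------------------------------------------------
    fits = [fit_lme(LMEModelSpec(m), orchard) for m in config.lme_models]
    coef_rows = []
    for fit in fits:
        tab = fit.coefficient_table()
        tab.insert(0, "model_id", fit.model_id)
        coef_rows.append(tab)
    p = out / "lme_coefficients.csv"
    write_csv(pd.concat(coef_rows, ignore_index=True), p)
    record("lme", p, sum(len(t) for t in coef_rows))
    comparison = model_compare(fits)
    p = out / "lme_comparison.csv"
    write_csv(comparison, p)
    record("lme", p, len(comparison))
    fit1 = next((f for f in fits if f.model_id == 1), fits[0])
    effects = evaluate_effects(fit1)
    p = out / "effects.csv"
    write_csv(effects, p)
    record("lme", p, len(effects))

    # --- compare-harvest --------------------------------------------------
    harvest = generate_harvest(seed=config.seed)
    p = out / "harvest.csv"
    write_csv(harvest, p, round2=("ssc",))
    record("compare-harvest", p, len(harvest))
    comp = method_difference(harvest)
    summary_df = pd.DataFrame(
        [
            {
                "mean_destructive": comp.method_means["destructive"],
                "mean_nondestructive": comp.method_means["nondestructive"],
                "sd_destructive": comp.method_sds["destructive"],
                "sd_nondestructive": comp.method_sds["nondestructive"],
                "mean_abs_difference": comp.mean_abs_difference,
                "mean_signed_difference": comp.mean_signed_difference,
                "u_statistic": comp.u_statistic,
                "p_value": comp.p_value,
            }
        ]
    )
    p = out / "harvest_summary.csv"
    write_csv(summary_df, p)
    record("compare-harvest", p, 1)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
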