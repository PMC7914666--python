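"""Longitudinal linear mixed-effect models of SSC accumulation.

Three nested specifications of the weekly SSC trajectory are supported:

* **Model 1** — fixed intercept, weekly slope, treatment/year main effects
  and time x treatment interactions; independent Gaussian random intercepts
  and slopes for trees and for fruit nested in trees.
* **Model 2** — Model 1 without the time interactions.
* **Model 3** — Model 1's fixed effects with no random effects (ordinary
  least squares baseline).

Estimation is by REML (reported coefficients and variance components) with a
parallel ML fit supplying AIC/BIC, so information criteria of models with
different fixed effects are comparable.  The time unit inside the models is
weeks after full bloom (WAFB); day-based interfaces convert with
``dafb = 7 * wafb``.  Coefficients with |t| > 2 are flagged significant.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import BASELINE_LEVELS, FACTOR_LEVELS

__all__ = [
    "LMEModelSpec",
    "LMEFit",
    "fit_lme",
    "model_compare",
    "evaluate_effects",
    "effect_range",
    "coefficients_from_anchors",
    "sensitivity_models",
    "significance_flag",
]

_FACTORS = ("year", "sector", "crop_load", "temperature_trt", "calcium")
_BASELINES = {"year": "2016", **BASELINE_LEVELS}


@dataclass
class LMEModelSpec:
    """Which fixed and random terms enter the model (ids 1, 2 or 3)."""

    model_id: int = 1

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")

    @property
    def has_interactions(self) -> bool:
        return self.model_id in (1, 3)

    @property
    def has_random_effects(self) -> bool:
        return self.model_id in (1, 2)


@dataclass
class LMEFit:
    """Fitted coefficients, variance components and fit criteria."""

    model_id: int
    method: str  # "REML" or "ML"
    estimates: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    variance_components: dict[str, float]
    aic: float
    bic: float
    loglik: float
    rmse: float
    n_obs: int
    n_fruit: int
    n_trees: int
    singular: bool = False
    converged: bool = True
    data_hash: str = ""

    def significant(self) -> dict[str, bool]:
        return {k: significance_flag(v) for k, v in self.t_values.items()}

    def coefficient_table(self) -> pd.DataFrame:
        names = list(self.estimates)
        return pd.DataFrame(
            {
                "coefficient": names,
                "estimate": [self.estimates[k] for k in names],
                "std_error": [self.std_errors.get(k, np.nan) for k in names],
                "t_value": [self.t_values.get(k, np.nan) for k in names],
                # boundary fits can yield undefined SEs; report those as
                # not-significant rather than failing
                "significant": [
                    significance_flag(t) if np.isfinite(t) else False
                    for t in (self.t_values.get(k, 0.0) for k in names)
                ],
            }
        )


def significance_flag(t_value: float) -> bool:
    """True iff |t| is strictly greater than 2."""
    if not np.isfinite(t_value):
        raise ValueError("t-value must be finite")
    return abs(t_value) > 2.0


def _present_factors(data: pd.DataFrame) -> list[str]:
    return [f for f in _FACTORS if f in data.columns and data[f].nunique() > 1]


def _fixed_formula(data: pd.DataFrame, interactions: bool) -> str:
    terms = ["wafb"]
    for f in _present_factors(data):
        base = _BASELINES[f]
        terms.append(f"C({f}, Treatment('{base}'))")
        if interactions:
            terms.append(f"wafb:C({f}, Treatment('{base}'))")
    return "ssc ~ " + " + ".join(terms)


_TERM_RE = re.compile(r"C\((\w+), Treatment\('[^']*'\)\)\[T\.([^\]]+)\]")


def _friendly(name: str) -> str:
    """Map patsy coefficient names to 'factor:level' / 'week:factor:level'."""
    if name == "Intercept":
        return "intercept"
    if name == "wafb":
        return "week"
    parts = name.split(":")
    has_time = "wafb" in parts
    parts = [p for p in parts if p != "wafb"]
    out = []
    for p in parts:
        m = _TERM_RE.fullmatch(p)
        out.append(f"{m.group(1)}:{m.group(2)}" if m else p)
    label = ":".join(out)
    return f"week:{label}" if has_time else label


def _data_hash(data: pd.DataFrame) -> str:
    key = pd.util.hash_pandas_object(
        data[["fruit_id", "tree_id", "wafb", "ssc"]], index=False
    ).to_numpy()
    return hashlib.sha256(key.tobytes()).hexdigest()[:16]


def _validate_nesting(data: pd.DataFrame) -> None:
    trees_per_fruit = data.groupby("fruit_id")["tree_id"].nunique()
    if (trees_per_fruit > 1).any():
        bad = trees_per_fruit[trees_per_fruit > 1].index[0]
        raise ValueError(f"fruit {bad!r} appears under more than one tree")


def _conditional_rmse(result) -> float:
    """RMSE of conditional residuals (fixed part and BLUPs subtracted)."""
    resid = np.asarray(result.resid, dtype=float)
    return float(np.sqrt(np.mean(resid**2)))


def _fit_mixed(formula: str, data: pd.DataFrame, reml: bool):
    model = smf.mixedlm(
        formula,
        data=data,
        groups=data["tree_id"],
        re_formula="1",
        vc_formula={
            "tree_slope": "0 + wafb",
            "fruit_intercept": "0 + C(fruit_id)",
            "fruit_slope": "0 + C(fruit_id):wafb",
        },
    )
    # two-stage optimisation: a fast lbfgs pass, then a bfgs refinement from
    # its endpoint (lbfgs can report convergence at a non-optimal point on
    # this profiled deviance surface; bfgs from that start either confirms it
    # cheaply or escapes it), with from-scratch restarts as a last resort
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            best = model.fit(reml=reml, method="lbfgs", maxiter=500)
            refined = model.fit(
                reml=reml, method="bfgs", maxiter=500, start_params=best.params_object
            )
            if refined.llf >= best.llf:
                best = refined
        except Exception:
            pass
        if best is None or not best.converged:
            for meth in ("bfgs", "powell"):
                try:
                    result = model.fit(reml=reml, method=meth, maxiter=500)
                except Exception:
                    continue
                if best is None or result.llf > best.llf:
                    best = result
                if result.converged:
                    break
    if best is None:
        raise RuntimeError("mixed-model optimisation failed for every optimizer")
    return model, best


def fit_lme(
    spec: LMEModelSpec | int,
    data: pd.DataFrame,
    method: str = "REML",
    information_criteria: str = "ml",
) -> LMEFit:
    """Fit one of the three SSC accumulation models.

    Parameters
    ----------
    spec:
        Model id (1, 2 or 3) or an :class:`LMEModelSpec`.
    data:
        Longitudinal table with columns ``ssc``, ``wafb``, ``fruit_id``,
        ``tree_id`` and the treatment factors; factor levels are dummy-coded
        against the baselines (year 2016, bottom sector, standard crop load,
        ambient temperature, calcium applied).
    method:
        ``"REML"`` (default, reported estimates and variance components) or
        ``"ML"``.
    information_criteria:
        ``"ml"`` runs a parallel ML fit for AIC/BIC when ``method`` is REML
        (comparable across fixed-effect structures); ``"same"`` reuses the
        main fit's likelihood and is cheaper.

    Boundary (near-zero variance) estimates are flagged ``singular``, not
    rejected.  RMSE is computed over conditional residuals (random effects
    subtracted via their BLUPs).
    """
    if isinstance(spec, int):
        spec = LMEModelSpec(spec)
    method = method.upper()
    if method not in ("REML", "ML"):
        raise ValueError("method must be REML or ML")
    data = data.reset_index(drop=True).copy()
    data["year"] = data["year"].astype(str)
    _validate_nesting(data)
    formula = _fixed_formula(data, spec.has_interactions)
    dhash = _data_hash(data)
    n_obs = len(data)
    n_fruit = data["fruit_id"].nunique()
    n_trees = data["tree_id"].nunique()

    if not spec.has_random_effects:
        ols = smf.ols(formula, data=data).fit()
        names = [_friendly(n) for n in ols.params.index]
        sigma2 = float(np.mean(ols.resid**2))  # ML estimate
        return LMEFit(
            model_id=spec.model_id,
            method="ML",
            estimates=dict(zip(names, ols.params)),
            std_errors=dict(zip(names, ols.bse)),
            t_values=dict(zip(names, ols.tvalues)),
            variance_components={
                "tree_intercept": 0.0,
                "tree_slope": 0.0,
                "fruit_intercept": 0.0,
                "fruit_slope": 0.0,
                "residual": sigma2,
            },
            aic=float(ols.aic),
            bic=float(ols.bic),
            loglik=float(ols.llf),
            rmse=float(np.sqrt(np.mean(ols.resid**2))),
            n_obs=n_obs,
            n_fruit=n_fruit,
            n_trees=n_trees,
            data_hash=dhash,
        )

    counts = data.groupby("fruit_id")["wafb"].nunique()
    if (counts < 2).all():
        raise ValueError("random slopes need >= 2 time points for some fruit")

    model, result = _fit_mixed(formula, data, reml=(method == "REML"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits: sqrt of ~0 diag
        bse_fe = np.asarray(result.bse_fe, dtype=float)
    names = [_friendly(n) for n in result.fe_params.index]
    vc_names = list(model.exog_vc.names)
    vcomp = dict(zip(vc_names, np.asarray(result.vcomp, dtype=float)))
    variance_components = {
        "tree_intercept": float(result.cov_re.iloc[0, 0]),
        "tree_slope": float(vcomp.get("tree_slope", np.nan)),
        "fruit_intercept": float(vcomp.get("fruit_intercept", np.nan)),
        "fruit_slope": float(vcomp.get("fruit_slope", np.nan)),
        "residual": float(result.scale),
    }
    singular = any(
        v < 1e-8 * variance_components["residual"]
        for k, v in variance_components.items()
        if k != "residual"
    )

    if method == "REML" and information_criteria == "ml":
        _, ml_result = _fit_mixed(formula, data, reml=False)
        ll = float(ml_result.llf)
        k_param = len(ml_result.fe_params) + 1 + len(ml_result.vcomp) + 1  # + cov_re + scale
    else:
        ll = float(result.llf)
        k_param = len(result.fe_params) + 1 + len(result.vcomp) + 1
    aic = -2.0 * ll + 2.0 * k_param
    bic = -2.0 * ll + np.log(n_obs) * k_param

    return LMEFit(
        model_id=spec.model_id,
        method=method,
        estimates=dict(zip(names, np.asarray(result.fe_params, dtype=float))),
        std_errors=dict(zip(names, bse_fe)),
        t_values=dict(zip(names, np.asarray(result.fe_params, dtype=float) / bse_fe)),
        variance_components=variance_components,
        aic=float(aic),
        bic=float(bic),
        loglik=ll,
        rmse=_conditional_rmse(result),
        n_obs=n_obs,
        n_fruit=n_fruit,
        n_trees=n_trees,
        singular=singular,
        converged=bool(result.converged),
        data_hash=dhash,
    )


def model_compare(fits: list[LMEFit]) -> pd.DataFrame:
    """AIC/BIC/RMSE comparison table; flags the minimum-AIC model.

    All fits must be on identical data (checked via a content hash).
    """
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were computed on differing data sets")
    tab = pd.DataFrame(
        {
            "model_id": [f.model_id for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
            "rmse": [f.rmse for f in fits],
            "loglik": [f.loglik for f in fits],
            "n_obs": [f.n_obs for f in fits],
        }
    )
    tab["best_aic"] = tab["aic"] == tab["aic"].min()
    return tab


def coefficients_from_anchors(
    base: tuple[float, float],
    offsets: dict[str, tuple[float, float]],
    dafb_anchors: tuple[float, float] = (40.0, 140.0),
) -> LMEFit:
    """Build a coefficient set from effect values printed at two DAFB points.

    Under the model every expected-effect column is affine in time, so the
    trajectory is fully determined by its values at two DAFB anchors: the
    weekly slope is the difference over the anchor span (converted from days
    to weeks) and the intercept is the extrapolation to bloom.  ``base`` is
    (value at first anchor, value at second anchor) for the baseline
    configuration; ``offsets`` maps "factor:level" to its two anchor values.
    Returns an :class:`LMEFit` holding only the implied fixed effects, usable
    with :func:`evaluate_effects`.
    """
    d1, d2 = dafb_anchors
    if d1 == d2:
        raise ValueError("anchors must be distinct")
    est: dict[str, float] = {}
    per_day = (base[1] - base[0]) / (d2 - d1)
    est["week"] = per_day * 7.0
    est["intercept"] = base[0] - per_day * d1
    for key, (v1, v2) in offsets.items():
        per_day = (v2 - v1) / (d2 - d1)
        est[f"week:{key}"] = per_day * 7.0
        est[key] = v1 - per_day * d1
    return LMEFit(
        model_id=1,
        method="ANCHORS",
        estimates=est,
        std_errors={},
        t_values={},
        variance_components={},
        aic=np.nan,
        bic=np.nan,
        loglik=np.nan,
        rmse=np.nan,
        n_obs=0,
        n_fruit=0,
        n_trees=0,
    )


def evaluate_effects(
    fit: LMEFit,
    dafb_list: tuple[float, ...] = (40, 60, 80, 100, 120, 140),
    factors: tuple[str, ...] = ("sector", "crop_load", "temperature_trt"),
    year: str | None = None,
) -> pd.DataFrame:
    """Expected fixed-effect SSC trajectory table by DAFB.

    The ``base`` column is the expected SSC of the baseline configuration,
    ``intercept + week * t`` with ``t = dafb / 7`` (plus the year main effect
    and year:time interaction when ``year`` is given); each factor-level
    column is the time-dependent offset ``beta_X + beta_Y * t`` to add to the
    base.  Baseline levels are identically 0 and omitted.  Values are
    reported to 0.01 % SSC.
    """
    est = fit.estimates
    dafb = np.asarray(dafb_list, dtype=float)
    weeks = dafb / 7.0
    base = est["intercept"] + est["week"] * weeks
    if year is not None and year != _BASELINES["year"]:
        key = f"year:{year}"
        if key not in est:
            raise ValueError(f"fit has no coefficient for {key}")
        base = base + est[key] + est.get(f"week:{key}", 0.0) * weeks
    out = pd.DataFrame({"dafb": dafb, "base": base})
    for f in factors:
        for level in FACTOR_LEVELS.get(f, ()):
            if level == _BASELINES[f]:
                continue
            key = f"{f}:{level}"
            if key not in est:
                raise ValueError(f"fit has no coefficient for level {key!r}")
            out[key] = est[key] + est.get(f"week:{key}", 0.0) * weeks
    num = out.columns.drop("dafb")
    out[num] = out[num].round(2)
    return out


def effect_range(table: pd.DataFrame, factor: str, dafb: float) -> float:
    """Max minus min effect over a factor's levels (baseline at 0) at a DAFB."""
    if factor not in FACTOR_LEVELS:
        raise ValueError(f"unknown factor {factor!r}")
    row = table[table["dafb"] == dafb]
    if row.empty:
        raise ValueError(f"DAFB {dafb} not in table")
    offsets = [0.0]  # baseline level
    for level in FACTOR_LEVELS[factor]:
        key = f"{factor}:{level}"
        if key in table.columns:
            offsets.append(float(row[key].iloc[0]))
    return float(max(offsets) - min(offsets))


def sensitivity_models(
    data: pd.DataFrame,
    master_seed: int = 0,
    n_trees: int = 100,
    n_fruit: int = 500,
    added_noise_sd: float = 1.0,
    method: str = "REML",
    information_criteria: str = "same",
) -> dict[str, LMEFit]:
    """Experimental-design sensitivity refits of the fully specified model.

    * ``multi_year`` — Model 1 on the full table;
    * ``A`` — random subsample of ``n_trees`` trees with all their fruit;
    * ``B`` — random subsample of ``n_fruit`` fruit across all trees;
    * ``C`` — full table with unbiased Gaussian error of sd
      ``added_noise_sd`` (% SSC) added to the response.

    Subsampling and noise seeds derive from ``master_seed`` and are
    reproducible.
    """
    trees = np.sort(data["tree_id"].unique())
    fruit = np.sort(data["fruit_id"].unique())
    if trees.size < n_trees:
        raise ValueError(f"need >= {n_trees} trees, have {trees.size}")
    if fruit.size < n_fruit:
        raise ValueError(f"need >= {n_fruit} fruit, have {fruit.size}")
    seeds = np.random.SeedSequence(master_seed).spawn(3)
    rng_a, rng_b, rng_c = (np.random.default_rng(s) for s in seeds)

    keep_trees = rng_a.choice(trees, size=n_trees, replace=False)
    data_a = data[data["tree_id"].isin(keep_trees)]
    keep_fruit = rng_b.choice(fruit, size=n_fruit, replace=False)
    data_b = data[data["fruit_id"].isin(keep_fruit)]
    data_c = data.copy()
    data_c["ssc"] = data_c["ssc"] + rng_c.normal(0.0, added_noise_sd, size=len(data_c))

    fits = {}
    for name, d in (
        ("multi_year", data),
        ("A", data_a),
        ("B", data_b),
        ("C", data_c),
    ):
        fits[name] = fit_lme(
            LMEModelSpec(1), d, method=method, information_criteria=information_criteria
        )
    return fits
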