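"""Mixed-model fitting, model comparison, effect tables and sensitivity runs."""

import numpy as np
import pandas as pd
import pytest

from orchardssc.config import OrchardConfig
from orchardssc.lme import (
    LMEModelSpec,
    coefficients_from_anchors,
    effect_range,
    evaluate_effects,
    fit_lme,
    model_compare,
    sensitivity_models,
    significance_flag,
)
from orchardssc.synthetic import generate_orchard


@pytest.fixture(scope="module")
def fits_123(small_orchard):
    return [
        fit_lme(LMEModelSpec(m), small_orchard, method="ML", information_criteria="same")
        for m in (1, 2, 3)
    ]


class TestFitLme:
    def test_zero_variance_data_matches_ols(self):
        # when the generating process has no random effects, Model 1's fixed
        # effects collapse onto the least squares estimates
        cfg = OrchardConfig(
            design={2016: (8, 24), 2017: (8, 24)},
            weeks=tuple(range(8, 16)),
            sd_tree_intercept=0,
            sd_tree_slope=0,
            sd_fruit_intercept=0,
            sd_fruit_slope=0,
            sd_residual=0.2,
            seed=42,
        )
        d = generate_orchard(cfg)
        f1 = fit_lme(LMEModelSpec(1), d, information_criteria="same")
        f3 = fit_lme(LMEModelSpec(3), d)
        for k, v in f3.estimates.items():
            assert f1.estimates[k] == pytest.approx(v, abs=1e-4)

    def test_model3_is_plain_linear_regression(self, small_orchard):
        import statsmodels.formula.api as smf

        from orchardssc.lme import _fixed_formula

        f3 = fit_lme(LMEModelSpec(3), small_orchard)
        d = small_orchard.copy()
        d["year"] = d["year"].astype(str)
        ols = smf.ols(_fixed_formula(d, interactions=True), data=d).fit()
        assert f3.aic == pytest.approx(ols.aic)
        assert f3.rmse == pytest.approx(float(np.sqrt(np.mean(ols.resid**2))))
        assert sorted(f3.estimates.values()) == pytest.approx(sorted(ols.params.values))

    def test_variance_components_recovered(self, small_orchard):
        fit = fit_lme(LMEModelSpec(2), small_orchard, information_criteria="same")
        vc = fit.variance_components
        # generating values: 0.09 intercepts, 0.0004 slopes, 0.09 residual
        assert vc["residual"] == pytest.approx(0.09, rel=0.25)
        assert vc["fruit_intercept"] == pytest.approx(0.09, rel=0.6)
        assert all(v >= 0 for v in vc.values())

    def test_t_equals_estimate_over_se(self, fits_123):
        fit = fits_123[0]
        for k in fit.estimates:
            assert fit.t_values[k] == pytest.approx(
                fit.estimates[k] / fit.std_errors[k], rel=1e-10
            )

    def test_non_nested_fruit_rejected(self, small_orchard):
        d = small_orchard.copy()
        d.loc[d.index[-1], "tree_id"] = "T2016_000"  # move one obs to another tree
        if d[d["fruit_id"] == d.iloc[-1]["fruit_id"]]["tree_id"].nunique() > 1:
            with pytest.raises(ValueError, match="more than one tree"):
                fit_lme(LMEModelSpec(1), d)

    def test_reml_vs_ml_methods(self, small_orchard):
        reml = fit_lme(LMEModelSpec(2), small_orchard, method="REML", information_criteria="same")
        ml = fit_lme(LMEModelSpec(2), small_orchard, method="ML")
        assert reml.method == "REML" and ml.method == "ML"
        # same data, nearly identical point estimates at this size
        assert reml.estimates["week"] == pytest.approx(ml.estimates["week"], abs=0.02)


class TestModelCompare:
    def test_nesting_deviance_order(self, fits_123):
        # richer models cannot have lower ML likelihood
        f1, f2, f3 = fits_123
        assert f1.loglik >= f2.loglik - 1e-6
        assert f2.loglik >= f3.loglik - 1e-6

    def test_table_flags_minimum_aic(self, fits_123):
        tab = model_compare(fits_123)
        assert tab.loc[tab["best_aic"], "aic"].iloc[0] == tab["aic"].min()

    def test_identical_fits_identical_rows(self, fits_123):
        tab = model_compare([fits_123[0], fits_123[0]])
        assert tab.iloc[0][["aic", "bic", "rmse"]].equals(tab.iloc[1][["aic", "bic", "rmse"]])

    def test_differing_data_rejected(self, fits_123, small_orchard):
        other = generate_orchard(
            OrchardConfig(design={2016: (4, 12)}, weeks=(8, 9, 10), seed=77)
        )
        f_other = fit_lme(LMEModelSpec(3), other)
        with pytest.raises(ValueError):
            model_compare([fits_123[0], f_other])

    def test_no_random_effects_bic_prefers_parsimony(self):
        # under a no-random-effect, no-interaction truth the OLS baseline must
        # beat the fully specified model, and its BIC gap to the best model is
        # bounded by the parameter-count difference (Model 3 carries 3 net
        # parameters more than Model 2: 7 interaction terms vs 4 variance
        # components) times ln(n), plus sampling slack -- nothing like the
        # thousands-of-units gaps seen under a random-effects truth
        cfg = OrchardConfig(
            design={2016: (10, 40), 2017: (10, 40)},
            weeks=tuple(range(8, 16)),
            interaction_effects={},
            sd_tree_intercept=0,
            sd_tree_slope=0,
            sd_fruit_intercept=0,
            sd_fruit_slope=0,
            sd_residual=0.3,
            seed=55,
        )
        d = generate_orchard(cfg)
        fits = [fit_lme(LMEModelSpec(m), d, method="ML") for m in (1, 2, 3)]
        tab = model_compare(fits).set_index("model_id")
        assert tab.loc[3, "bic"] < tab.loc[1, "bic"]
        assert tab.loc[3, "bic"] <= tab["bic"].min() + 4 * np.log(len(d))


class TestEffectTables:
    def test_zero_effects_give_zero_offsets(self):
        fit = coefficients_from_anchors(
            base=(5.0, 9.0),
            offsets={
                f"{f}:{lv}": (0.0, 0.0)
                for f, lvs in (
                    ("sector", ("middle", "top")),
                    ("crop_load", ("light", "heavy")),
                    ("temperature_trt", ("cold", "warm")),
                )
                for lv in lvs
            },
        )
        tab = evaluate_effects(fit)
        for col in tab.columns.drop(["dafb", "base"]):
            assert (tab[col] == 0.0).all()

    def test_columns_are_affine_in_dafb(self, small_orchard):
        fit = fit_lme(LMEModelSpec(1), small_orchard, information_criteria="same")
        tab = evaluate_effects(fit, dafb_list=(40, 60, 80, 100, 120, 140))
        # exact collinearity: second differences vanish (to rounding)
        for col in tab.columns.drop("dafb"):
            second_diff = np.diff(tab[col].to_numpy(), 2)
            assert np.max(np.abs(second_diff)) <= 0.021  # 2 decimals rounding

    def test_missing_level_rejected(self):
        fit = coefficients_from_anchors(base=(5.0, 9.0), offsets={})
        with pytest.raises(ValueError):
            evaluate_effects(fit)

    def test_effect_range_examples(self):
        tab = pd.DataFrame(
            {
                "dafb": [140.0],
                "sector:middle": [0.43],
                "sector:top": [0.89],
                "crop_load:light": [0.25],
                "crop_load:heavy": [-0.17],
            }
        )
        assert effect_range(tab, "sector", 140) == pytest.approx(0.89)
        assert effect_range(tab, "crop_load", 140) == pytest.approx(0.42)
        zero = pd.DataFrame({"dafb": [140.0], "sector:middle": [0.0], "sector:top": [0.0]})
        assert effect_range(zero, "sector", 140) == 0.0
        with pytest.raises(ValueError):
            effect_range(tab, "bogus", 140)
        with pytest.raises(ValueError):
            effect_range(tab, "sector", 60)


class TestSignificanceFlag:
    @pytest.mark.parametrize(
        "t,expected",
        [(2.1, True), (-2.0, False), (2.0, False), (0.0, False), (-5.3, True)],
    )
    def test_strict_threshold(self, t, expected):
        assert significance_flag(t) is expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            significance_flag(float("nan"))


@pytest.fixture(scope="module")
def sens():
    cfg = OrchardConfig(
        design={2016: (20, 80), 2017: (20, 80), 2018: (20, 80)},
        weeks=tuple(range(8, 17)),
        seed=91,
    )
    data = generate_orchard(cfg)
    fits = sensitivity_models(data, master_seed=5, n_trees=30, n_fruit=120)
    return data, fits


class TestSensitivityModels:
    def test_reduced_designs_inflate_standard_errors(self, sens):
        _, fits = sens
        full = fits["multi_year"]
        for name in ("A", "B"):
            worse = sum(
                fits[name].std_errors[k] > full.std_errors[k] for k in full.std_errors
            )
            assert worse >= 0.9 * len(full.std_errors)

    def test_added_noise_inflates_residual_variance(self, sens):
        _, fits = sens
        extra = (
            fits["C"].variance_components["residual"]
            - fits["multi_year"].variance_components["residual"]
        )
        assert extra == pytest.approx(1.0, abs=0.15)

    def test_subsampling_reproducible(self, sens):
        data, fits = sens
        again = sensitivity_models(data, master_seed=5, n_trees=30, n_fruit=120)
        assert again["A"].estimates == pytest.approx(fits["A"].estimates)
        assert again["B"].n_fruit == fits["B"].n_fruit == 120
        assert again["A"].n_trees == fits["A"].n_trees == 30

    def test_insufficient_data_rejected(self, small_orchard):
        with pytest.raises(ValueError):
            sensitivity_models(small_orchard, n_trees=100, n_fruit=500)
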