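"""Tests of the spectra and orchard generators against their generative laws."""

import numpy as np
import pandas as pd
import pytest

from orchardssc.config import OrchardConfig, SpectraConfig
from orchardssc.plsr import fit_plsr, predict
from orchardssc.preprocess import second_derivative
from orchardssc.synthetic import (
    generate_harvest,
    generate_orchard,
    generate_spectra,
    spectra_matrix,
    wavelength_grid,
)


class TestGenerateSpectra:
    def test_seed_determinism(self):
        cfg = SpectraConfig(n_samples=30, seed=11)
        pd.testing.assert_frame_equal(generate_spectra(cfg), generate_spectra(cfg))

    def test_different_seeds_differ(self):
        a = generate_spectra(SpectraConfig(n_samples=30, seed=1))
        b = generate_spectra(SpectraConfig(n_samples=30, seed=2))
        assert not a.equals(b)

    def test_linear_forward_model_single_band(self):
        # noise-free, one band: absorbance difference at the band center is
        # gain times the SSC difference
        cfg = SpectraConfig(
            n_samples=2,
            noise_sd_absorbance=0.0,
            band_centers=(840.0,),
            band_widths=(25.0,),
            band_gains=(0.004,),
            temperature_levels=(20.0,),
            seed=0,
        )
        sp = generate_spectra(cfg)
        wl, X = spectra_matrix(sp)
        ssc = sp["ssc_ref"].to_numpy()
        i840 = int(np.argmin(np.abs(wl - 840.0)))
        dA = X[1, i840] - X[0, i840]
        assert dA == pytest.approx(0.004 * (ssc[1] - ssc[0]), abs=1e-12)

    def test_grid_channels_on_step_multiples(self):
        wl = wavelength_grid(SpectraConfig())
        assert wl[0] == 312.0 and wl[-1] == 1098.0
        assert np.all(np.diff(wl) == 3.0)
        assert 729.0 in wl and 975.0 in wl

    def test_duplicate_scans_share_reference(self):
        cfg = SpectraConfig(n_samples=5, duplicate_scans=True, seed=3)
        sp = generate_spectra(cfg)
        assert len(sp) == 10
        ssc = sp["ssc_ref"].to_numpy()
        assert np.allclose(ssc[0::2], ssc[1::2])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            generate_spectra(SpectraConfig(n_samples=0))
        with pytest.raises(ValueError):
            generate_spectra(SpectraConfig(band_centers=(2000.0,), band_widths=(25.0,), band_gains=(0.004,)))
        with pytest.raises(ValueError):
            generate_spectra(SpectraConfig(ssc_range=(14.0, 5.0)))
        with pytest.raises(ValueError):
            generate_spectra(SpectraConfig(noise_sd_absorbance=-0.1))

    def test_end_to_end_recovery_low_noise(self):
        # the whole chain (generate -> derivative -> PLSR) recovers SSC well
        # below the 0.2 % SSC mark when spectral noise is small
        cfg = SpectraConfig(n_samples=1000, noise_sd_absorbance=0.0005, seed=21)
        deriv = second_derivative(generate_spectra(cfg))
        _, X = spectra_matrix(deriv)
        y = deriv["ssc_ref"].to_numpy()
        model = fit_plsr(X[:700], y[:700])
        rmsep = float(np.sqrt(np.mean((predict(model, X[700:]) - y[700:]) ** 2)))
        assert rmsep < 0.2


class TestGenerateOrchard:
    def test_seed_determinism(self):
        cfg = OrchardConfig(design={2016: (4, 12)}, weeks=(8, 9, 10), seed=5)
        pd.testing.assert_frame_equal(generate_orchard(cfg), generate_orchard(cfg))

    def test_degenerate_model_pure_line(self):
        # all sds and treatment effects zero: every trajectory is b0 + b1 t
        fe = {"intercept": 4.0, "week": 0.5}
        cfg = OrchardConfig(
            design={2016: (3, 9)},
            weeks=(8, 9, 10, 11),
            fixed_effects=fe,
            interaction_effects={},
            sd_tree_intercept=0,
            sd_tree_slope=0,
            sd_fruit_intercept=0,
            sd_fruit_slope=0,
            sd_residual=0,
            seed=1,
        )
        d = generate_orchard(cfg)
        assert np.allclose(d["ssc"], 4.0 + 0.5 * d["wafb"])

    def test_fruit_intercept_variance_decomposition(self):
        # no residual noise: within-fruit trajectories are exact lines and the
        # between-fruit intercept variance matches sd_fruit_intercept^2
        cfg = OrchardConfig(
            design={2016: (40, 400)},
            weeks=tuple(range(8, 14)),
            fixed_effects={"intercept": 4.0, "week": 0.3},
            interaction_effects={},
            sd_tree_intercept=0,
            sd_tree_slope=0,
            sd_fruit_intercept=0.5,
            sd_fruit_slope=0,
            sd_residual=0,
            seed=9,
        )
        d = generate_orchard(cfg)
        intercepts = []
        for _, grp in d.groupby("fruit_id"):
            coef = np.polyfit(grp["wafb"], grp["ssc"], 1)
            resid = grp["ssc"] - np.polyval(coef, grp["wafb"])
            assert np.max(np.abs(resid)) < 1e-10  # perfect line
            intercepts.append(coef[1])
        assert np.var(intercepts, ddof=1) == pytest.approx(0.25, abs=0.05)

    def test_per_fruit_ols_slope_recovery(self):
        # full variance structure at the default design scale: the mean of
        # per-fruit OLS slopes recovers the generating weekly slope 0.31
        cfg = OrchardConfig(interaction_effects={}, seed=17)
        d = generate_orchard(cfg)
        assert d["tree_id"].nunique() == 237
        assert d["fruit_id"].nunique() == 1274
        slopes = [
            np.polyfit(grp["wafb"], grp["ssc"], 1)[0] for _, grp in d.groupby("fruit_id")
        ]
        assert np.mean(slopes) == pytest.approx(0.31, abs=0.02)

    def test_residual_variance_conservation(self):
        # subtracting the known fixed part and the known random draws leaves
        # residuals whose variance matches sd_residual^2
        cfg = OrchardConfig(design={2016: (20, 100)}, weeks=tuple(range(8, 18)), seed=31)
        d = generate_orchard(cfg)
        resid = (
            d["ssc"]
            - d["true_fixed"]
            - d["u_tree_int"]
            - d["u_fruit_int"]
            - (d["u_tree_slope"] + d["u_fruit_slope"]) * d["wafb"]
        )
        assert np.var(resid, ddof=1) == pytest.approx(0.09, rel=0.1)

    def test_nesting_and_dafb(self):
        d = generate_orchard(OrchardConfig(design={2016: (5, 20)}, weeks=(8, 9), seed=2))
        assert (d["dafb"] == 7 * d["wafb"]).all()
        assert (d.groupby("fruit_id")["tree_id"].nunique() == 1).all()

    def test_dropout_is_monotone_prefix(self):
        cfg = OrchardConfig(
            design={2016: (10, 30)}, weeks=tuple(range(8, 20)), dropout_prob=0.2, seed=8
        )
        d = generate_orchard(cfg)
        assert len(d) < 30 * 12  # some loss occurred
        for _, grp in d.groupby("fruit_id"):
            w = np.sort(grp["wafb"].to_numpy())
            assert np.array_equal(w, np.arange(8, 8 + w.size))  # no gaps: lost fruit stay lost

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            generate_orchard(OrchardConfig(design={}))
        with pytest.raises(ValueError):
            generate_orchard(OrchardConfig(design={2016: (0, 10)}))
        with pytest.raises(ValueError):
            generate_orchard(OrchardConfig(weeks=()))
        with pytest.raises(ValueError):
            generate_orchard(OrchardConfig(sd_residual=-1.0))


class TestGenerateHarvest:
    def test_destructive_batches_pool_fruit(self):
        d = generate_harvest(seed=4)
        dest = d[d["method"] == "destructive"]
        nond = d[d["method"] == "nondestructive"]
        # batch pooling shrinks the destructive spread well below the
        # fruit-level nondestructive spread
        assert dest["ssc"].std() < nond["ssc"].std()

    def test_method_bias_shifts_nondestructive(self):
        d0 = generate_harvest(method_bias=0.0, seed=6, n_batches_per_level=20)
        d1 = generate_harvest(method_bias=1.0, seed=6, n_batches_per_level=20)
        shift = (
            d1[d1["method"] == "nondestructive"]["ssc"].mean()
            - d0[d0["method"] == "nondestructive"]["ssc"].mean()
        )
        assert shift == pytest.approx(1.0, abs=0.05)
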