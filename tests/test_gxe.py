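"""Genotype x year models, heritability, correlations, height model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import stemtherm as st
from stemtherm.gxe import (
    VarianceComponents,
    anova_variance_components,
    bonferroni_neglog_threshold,
    cross_year_r2,
    fit_gxe,
    fit_height_model,
    heritability,
    heritability_single_rep,
    percent_variance,
    trait_correlations,
)

from conftest import simulate_gxe


class TestHeritability:
    # variance components on the scale of a three-year, two-replicate wheat
    # trial; expected values are the published two-decimal heritabilities
    @pytest.mark.parametrize(
        "s2g,s2gy,s2e,expected",
        [
            (7.348e-8, 4.516e-8, 1.495e-8, 0.81),   # temperature-response slope
            (7.024e-7, 5.224e-7, 2.084e-7, 0.77),   # vigour intercept
            (1.226e-2, 5.890e-4, 4.417e-4, 0.98),   # final height
            (1.226e3, 6.241e2, 3.144e2, 0.82),      # start of SE (GDD_15)
            (1.190e3, 4.953e2, 4.081e2, 0.84),      # end of SE (GDD_95)
            (5.665e2, 1.067e3, 7.134e2, 0.54),      # SE duration, thermal time
            (5.844e0, 9.481e0, 5.668e0, 0.59),      # SE duration, calendar days
        ],
    )
    def test_three_year_two_rep_worked_examples(self, s2g, s2gy, s2e, expected):
        vc = VarianceComponents(s2g, s2gy, s2e, n_years=3, n_reps=2)
        assert round(heritability(vc), 2) == expected

    def test_limits(self):
        assert heritability(VarianceComponents(1.0, 0.0, 0.0, 3, 2)) == 1.0
        assert heritability(VarianceComponents(0.0, 1.0, 1.0, 3, 2)) == 0.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents(0.0, 0.0, 0.0, 3, 2))

    def test_monotone_in_components(self):
        base = heritability(VarianceComponents(1.0, 0.5, 0.25, 3, 2))
        assert heritability(VarianceComponents(1.2, 0.5, 0.25, 3, 2)) > base
        assert heritability(VarianceComponents(1.0, 0.7, 0.25, 3, 2)) < base
        assert heritability(VarianceComponents(1.0, 0.5, 0.45, 3, 2)) < base

    def test_single_rep_variant(self):
        # heading scored once per year: omit GY, divide residual by 3
        assert round(heritability_single_rep(1.742e3, 4.290e2, 3), 2) == 0.92
        assert heritability_single_rep(1.0, 0.0, 3) == 1.0
        assert heritability_single_rep(1.0, 1.0, 1) == 0.5


class TestPercentVariance:
    def test_published_share(self):
        vc = VarianceComponents(7.348e-8, 4.516e-8, 1.495e-8, 3, 2)
        assert round(percent_variance(vc)["genotype"], 2) == 55.00

    def test_equal_thirds(self):
        shares = percent_variance(VarianceComponents(1.0, 1.0, 1.0, 3, 2))
        assert np.allclose(shares, 100.0 / 3.0)

    @given(
        g=hst.floats(min_value=1e-6, max_value=1e6),
        gy=hst.floats(min_value=1e-6, max_value=1e6),
        e=hst.floats(min_value=1e-6, max_value=1e6),
    )
    @settings(max_examples=50, deadline=None)
    def test_shares_sum_to_100(self, g, gy, e):
        shares = percent_variance(VarianceComponents(g, gy, e, 3, 2))
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)


class TestFitGxe:
    def test_noiseless_additive_data_recovered_exactly(self):
        g = np.arange(10) * 0.1
        y = np.array([0.0, 1.0, -0.5])
        rows = [
            (f"g{i}", 2015 + j, 5.0 + g[i] + y[j])
            for i in range(10) for j in range(3) for _ in range(2)
        ]
        df = pd.DataFrame(rows, columns=["genotype", "year", "value"])
        fit = fit_gxe(df, "fixed")
        assert fit.vc.sigma2_gy == 0.0
        assert fit.vc.sigma2_e == 0.0
        means = df.groupby("genotype")["value"].mean().sort_index()
        assert np.allclose(fit.genotype_values.sort_index(), means, atol=1e-8)

    def test_balanced_reml_equals_anova_oracle(self):
        df, _ = simulate_gxe(I=120, seed=4)
        s2g0, s2gy0, s2e0 = anova_variance_components(df)
        fit = fit_gxe(df, "random")
        assert fit.vc.sigma2_g == pytest.approx(s2g0, rel=1e-6)
        assert fit.vc.sigma2_gy == pytest.approx(s2gy0, rel=1e-6)
        assert fit.vc.sigma2_e == pytest.approx(s2e0, rel=1e-6)

    def test_blup_shrinkage(self):
        for seed in range(4):
            df, _ = simulate_gxe(I=80, seed=seed)
            blue = fit_gxe(df, "fixed").genotype_values
            blup = fit_gxe(df, "random").genotype_values
            assert blup.var() <= blue.var() + 1e-12

    def test_blues_recover_true_genotype_effects(self):
        df, g = simulate_gxe(I=250, seed=9)
        fit = fit_gxe(df, "fixed")
        assert np.corrcoef(fit.genotype_values.to_numpy(), g)[0, 1] > 0.88

    def test_single_year_raises(self):
        df, _ = simulate_gxe(I=10, J=1, seed=1)
        with pytest.raises(ValueError, match="at least 2 years"):
            fit_gxe(df, "fixed")

    def test_incomplete_genotypes_dropped_and_reported(self):
        df, _ = simulate_gxe(I=12, seed=2)
        df = df[~((df["genotype"] == "g0003") & (df["year"] == 2016))]
        fit = fit_gxe(df, "fixed")
        assert fit.dropped_genotypes == ["g0003"]
        assert "g0003" not in fit.genotype_values.index

    def test_unbalanced_data_still_fits(self):
        df, g = simulate_gxe(I=60, seed=3)
        df = df.drop(df.index[::7])  # remove scattered plots
        fit = fit_gxe(df, "random")
        assert fit.vc.sigma2_g > 0
        assert np.corrcoef(fit.genotype_values.to_numpy(), g)[0, 1] > 0.8


class TestTraitCorrelations:
    def test_self_and_anticorrelation(self, rng):
        x = rng.normal(0, 1, 50)
        blues = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(0, 1, 50)})
        r, p = trait_correlations(blues)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert p.loc["a", "b"] < 1e-10

    def test_constant_trait_flagged_nan(self, rng):
        blues = pd.DataFrame({"a": rng.normal(0, 1, 20), "b": np.ones(20)})
        r, _ = trait_correlations(blues)
        assert np.isnan(r.loc["a", "b"])

    def test_configured_dependence_detected(self, rng):
        # joint normal with correlation 0.6 between two traits
        n = 400
        z = rng.standard_normal((n, 2))
        x = z[:, 0]
        y = 0.6 * z[:, 0] + np.sqrt(1 - 0.36) * z[:, 1]
        r, _ = trait_correlations(pd.DataFrame({"slope": x, "fh": y}))
        assert r.loc["slope", "fh"] == pytest.approx(0.6, abs=0.1)


class TestHeightModel:
    def _toy_factorial(self):
        # balanced 2x2 factorial, 2 replicates: hand-computed type II sums
        # of squares (equal to type I on this orthogonal design):
        #   SS_A = 12.5, SS_B = 24.5, SS_AB = 0.5, SS_resid = 0.08
        rows = [
            (0, 0, 1.0), (0, 0, 1.2),
            (0, 1, 4.0), (0, 1, 4.2),
            (1, 0, 3.0), (1, 0, 3.2),
            (1, 1, 7.0), (1, 1, 7.2),
        ]
        return pd.DataFrame(rows, columns=["a", "b", "y"])

    def test_type_ii_equals_hand_computation(self):
        df = self._toy_factorial()
        fit = fit_height_model(df, response="y", predictors=("a", "b"))
        an = fit.anova
        assert an.loc["a", "sum_sq"] == pytest.approx(12.5)
        assert an.loc["b", "sum_sq"] == pytest.approx(24.5)
        assert an.loc["a:b", "sum_sq"] == pytest.approx(0.5)
        assert an.loc["Residual", "sum_sq"] == pytest.approx(0.08)

    def test_single_active_predictor_dominates(self, rng):
        n = 60
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": 2.0 + 3.0 * x1})
        fit = fit_height_model(df, response="y", predictors=("x1", "x2"))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.anova.loc["x1", "sum_sq"] > 1e3 * fit.anova.loc["x2", "sum_sq"]

    def test_singular_interaction_dropped_by_name(self, rng):
        n = 80
        a = (rng.random(n) < 0.3).astype(float)
        b = (rng.random(n) < 0.3).astype(float)
        b[a == 1] = 0.0  # no individual carries both: a*b is identically zero
        df = pd.DataFrame({"a": a, "b": b, "y": rng.normal(1 + a + 2 * b, 0.1)})
        fit = fit_height_model(df, response="y", predictors=("a", "b"))
        assert fit.dropped_terms == ["a:b"]
        assert "a" in fit.anova.index and "b" in fit.anova.index

    def test_full_trait_model_pattern(self, paper_scale):
        # growth traits dominate the height model while allele terms carry
        # sums of squares orders of magnitude smaller — the published
        # ordering. The dwarfing alleles still shift height strongly before
        # adjustment; most of that effect travels through the measured
        # growth traits.
        an = paper_scale.height_model.anova
        for term in ("slope", "vigour", "gdd_se"):
            assert an.loc[term, "PR(>F)"] < 1e-10
        growth_ss = an.loc[["slope", "vigour", "gdd_se"], "sum_sq"].min()
        for term in ("rht_b1", "rht_d1", "ppd_d1"):
            assert an.loc[term, "sum_sq"] < 0.1 * growth_ss
        assert paper_scale.height_model.r_squared > 0.9

        # unadjusted allele contrast: semi-dwarfs are clearly shorter
        truth = paper_scale.trial.genotypes.set_index("genotype")
        tab = paper_scale.blues.join(truth[["rht_d1"]])
        gap = (
            tab.loc[tab["rht_d1"] == "Rht-D1a", "fh"].mean()
            - tab.loc[tab["rht_d1"] == "Rht-D1b", "fh"].mean()
        )
        assert gap > 0.05  # meters

    def test_too_few_observations_raise(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=3), "b": rng.normal(size=3), "y": rng.normal(size=3)})
        with pytest.raises(ValueError, match="fewer observations"):
            fit_height_model(df, response="y", predictors=("a", "b"))


class TestCrossYearR2:
    def _blues(self, rng, n=60, noise=0.02):
        idx = [f"g{i}" for i in range(n)]
        slope = rng.normal(1.2, 0.3, n)
        vig = rng.normal(10, 1, n)
        se = rng.normal(700, 30, n)
        fh = 0.3 * slope + 0.05 * vig + 0.0005 * se + rng.normal(0, noise, n)
        return pd.DataFrame({"slope": slope, "vigour": vig, "gdd_se": se, "fh": fh}, index=idx)

    def test_identical_years_exact_model_r2_one(self, rng):
        # height exactly linear in the predictors: self-prediction is perfect
        b = self._blues(rng, noise=0.0)
        assert cross_year_r2(b, b) == pytest.approx(1.0, abs=1e-9)

    def test_uncorrelated_prediction_near_zero(self, rng):
        train = self._blues(rng, n=2000)
        test = train.copy()
        test["fh"] = rng.normal(0, 1, len(test))  # truth unrelated to model
        assert cross_year_r2(train, test) < 0.01

    def test_disjoint_genotypes_raise(self, rng):
        a = self._blues(rng)
        b = self._blues(rng)
        b.index = [f"h{i}" for i in range(len(b))]
        with pytest.raises(ValueError, match="share no genotypes"):
            cross_year_r2(a, b)

    def test_synthetic_three_year_band_reported(self, paper_scale):
        r2s = [v for v in paper_scale.report["cross_year_r2"].values() if v is not None]
        assert len(r2s) == 6
        assert all(0.0 <= v <= 1.0 for v in r2s)
        assert np.mean(r2s) > 0.5  # high band under high-heritability truth


class TestBonferroni:
    def test_published_threshold(self):
        assert round(bonferroni_neglog_threshold(0.05, 13_450), 2) == 5.43

    def test_single_test(self):
        assert bonferroni_neglog_threshold(0.05, 1) == pytest.approx(1.30103, abs=1e-5)

    def test_stricter_alpha(self):
        assert round(bonferroni_neglog_threshold(0.001, 13_450), 2) == 7.13

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_neglog_threshold(1.5, 10)
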