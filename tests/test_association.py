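"""Logistic association models against closed-form and equivalence oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from voxfrail.association import (FrailtyAssociationModel, ModelSpec,
                                  fit_binomial, fit_multinomial,
                                  odds_to_probability)
from voxfrail.exceptions import (ConfigurationError, SeparationError,
                                 ZeroVarianceError)


def _two_by_two(a, b, c, d):
    """Exposed cases a, exposed controls b, unexposed cases c, controls d."""
    rows = ([{"A1": 1.0, "case": 1}] * a + [{"A1": 1.0, "case": 0}] * b
            + [{"A1": 0.0, "case": 1}] * c + [{"A1": 0.0, "case": 0}] * d)
    df = pd.DataFrame(rows)
    df["subject_id"] = range(len(df))
    return df


def _continuous_cohort(n=400, seed=0, beta=0.8, categories=("nonfrail", "SBF-only")):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    p = 1 / (1 + np.exp(-(-0.5 + beta * x)))
    case = rng.random(n) < p
    df = pd.DataFrame({"A2": x, "case": case.astype(int)})
    df["four_category"] = np.where(case, categories[1], categories[0])
    return df


class TestBinomial:
    def test_binary_exposure_or_equals_cross_product_ratio(self):
        a, b, c, d = 20, 80, 10, 90
        eff = fit_binomial(ModelSpec(outcome="case", exposure="A1"),
                           _two_by_two(a, b, c, d))
        assert eff.effect_type == "OR"
        assert eff.estimate == pytest.approx((a * d) / (b * c), abs=1e-6)
        assert eff.estimate == pytest.approx(2.25, abs=1e-6)
        assert eff.n_used == a + b + c + d
        assert eff.ci_low < eff.estimate < eff.ci_high

    def test_wald_ci_matches_closed_form_se(self):
        # for the saturated 2x2 model: Var(log OR) = 1/a + 1/b + 1/c + 1/d
        a, b, c, d = 20, 80, 10, 90
        eff = fit_binomial(ModelSpec(outcome="case", exposure="A1"),
                           _two_by_two(a, b, c, d))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert eff.se_log == pytest.approx(se, rel=1e-4)
        assert eff.ci_low == pytest.approx(eff.estimate * math.exp(-1.96 * se),
                                           rel=1e-4)

    def test_zero_variance_exposure_rejected(self):
        df = _two_by_two(20, 80, 10, 90)
        df["A1"] = 1.0
        with pytest.raises(ZeroVarianceError):
            fit_binomial(ModelSpec(outcome="case", exposure="A1"), df)

    def test_perfect_separation_raises(self):
        df = pd.DataFrame({"A2": np.r_[np.zeros(20), np.ones(20)],
                           "case": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        with pytest.raises(SeparationError):
            fit_binomial(ModelSpec(outcome="case", exposure="A2"), df)

    def test_exposure_rescaling_transforms_coefficient_exactly(self):
        df = _continuous_cohort(seed=3)
        per_unit = FrailtyAssociationModel.from_dataframe(
            df, "case", "A2").fit().effects[0]
        per_sd = FrailtyAssociationModel.from_dataframe(
            df, "case", "A2", standardize_exposure=True).fit().effects[0]
        sd = df["A2"].std(ddof=0)
        assert math.log(per_sd.estimate) == pytest.approx(
            sd * math.log(per_unit.estimate), rel=1e-8)

    def test_indeterminate_outcomes_are_excluded(self):
        df = _continuous_cohort(n=100, seed=5)
        pheno = np.where(df["case"] == 1, "frail", "robust").astype(object)
        pheno[:10] = "indeterminate"
        df["ebf_status"] = pheno
        df.loc[0, "A2"] = np.nan  # already indeterminate; no double count
        eff = fit_binomial(ModelSpec(outcome="EBF-frail", exposure="A2"), df)
        assert eff.n_used == 90

    def test_log_likelihood_at_optimum_beats_null(self):
        df = _continuous_cohort(seed=7)
        res = FrailtyAssociationModel.from_dataframe(df, "case", "A2").fit()
        p0 = df["case"].mean()
        ll_null = len(df) * (p0 * math.log(p0) + (1 - p0) * math.log(1 - p0))
        assert res.llf >= ll_null


class TestMultinomial:
    def test_two_category_rrr_equals_binomial_or(self):
        df = _continuous_cohort(seed=1)
        or_eff = fit_binomial(ModelSpec(outcome="case", exposure="A2"), df)
        rrr_effs = fit_multinomial(ModelSpec(outcome="four_category",
                                             exposure="A2"), df)
        assert len(rrr_effs) == 1
        assert rrr_effs[0].effect_type == "RRR"
        assert rrr_effs[0].baseline_category == "nonfrail"
        assert math.log(rrr_effs[0].estimate) == pytest.approx(
            math.log(or_eff.estimate), abs=1e-6)

    def test_predicted_category_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        n = 600
        x = rng.normal(0, 1, n)
        cats = rng.choice(["nonfrail", "EBF-only", "SBF-only", "both"], n,
                          p=[0.6, 0.15, 0.15, 0.1])
        df = pd.DataFrame({"A3": x, "four_category": cats})
        res = FrailtyAssociationModel.from_dataframe(
            df, "four_category", "A3").fit()
        probs = res.predict_probability()
        assert probs.shape == (n, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)

    def test_empty_category_dropped_with_warning(self):
        df = _continuous_cohort(seed=4)  # only two of four categories present
        with pytest.warns(UserWarning, match="zero members"):
            effs = fit_multinomial(ModelSpec(outcome="four_category",
                                             exposure="A2"), df)
        assert {e.category for e in effs} == {"SBF-only"}

    def test_missing_baseline_rejected(self):
        df = _continuous_cohort(seed=4, categories=("EBF-only", "SBF-only"))
        with pytest.raises(ConfigurationError):
            with pytest.warns(UserWarning):
                fit_multinomial(ModelSpec(outcome="four_category",
                                          exposure="A2"), df)


class TestOddsToProbability:
    @pytest.mark.parametrize("odds, prob", [(1.0, 0.5), (0.0, 0.0), (3.0, 0.75)])
    def test_quoted_formula(self, odds, prob):
        assert odds_to_probability(odds) == prob

    def test_negative_odds_rejected(self):
        with pytest.raises(ValueError):
            odds_to_probability(-0.1)

    @given(st.floats(0.0, 1e6), st.floats(0.0, 1e6))
    def test_strictly_increasing(self, o1, o2):
        p1, p2 = odds_to_probability(o1), odds_to_probability(o2)
        if o1 < o2:
            assert p1 < p2
        elif o1 == o2:
            assert p1 == p2

    @given(st.floats(0.0, 0.999))
    def test_inverse_of_p_over_one_minus_p(self, p):
        assert odds_to_probability(p / (1 - p)) == pytest.approx(p, abs=1e-12)


class TestReporting:
    def test_summary_carries_model_facts(self):
        df = _continuous_cohort(seed=6)
        res = FrailtyAssociationModel.from_dataframe(df, "case", "A2").fit()
        text = res.summary()
        assert "binomial logit" in text
        assert "A2" in text and "95% CI" in text
        assert f"N used:    {len(df)}" in text

    def test_results_frame_has_one_row_per_effect(self):
        df = _continuous_cohort(seed=6)
        res = FrailtyAssociationModel.from_dataframe(df, "case", "A2").fit()
        frame = res.to_frame()
        assert list(frame["outcome"]) == ["case"]
        assert frame.loc[0, "estimate"] > 0

    def test_forest_plot_returns_axis(self):
        df = _continuous_cohort(seed=6)
        res = FrailtyAssociationModel.from_dataframe(df, "case", "A2").fit()
        ax = res.plot_effects()
        assert ax.get_xlabel().startswith("OR")
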