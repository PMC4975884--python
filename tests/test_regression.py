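"""Regression engine: logistic ML + AME with delta-method SE, OLS, LR test.

Independent oracles used here: a Nelder-Mead grouped-binomial ML fit (frozen
value), statsmodels' own margins machinery, a finite-difference Jacobian, and
a parametric bootstrap of the parameter covariance.
"""

import numpy as np
import pytest
import statsmodels.api as sm

from spinedecline import (
    AgeGroup,
    IndividualRecord,
    PrevalenceAggregate,
    SeparationError,
    average_marginal_effect,
    expand_prevalence,
    fit_gaussian,
    fit_logistic,
    fit_logistic_grouped,
    lr_linearity_test,
    representative_ages,
)
from spinedecline.aggregates import PrevalenceGroup
from spinedecline.reconstruct import records_to_arrays

# Frozen from an independent grouped-binomial ML fit (scipy Nelder-Mead on the
# binomial log-likelihood of counts 101/273, 314/604, 282/415, 249/311 at ages
# 25/35/45/55): slope 0.0646372 log-odds/year.
ORACLE_DISK_DEGEN_SLOPE = 0.0646372


@pytest.fixture(scope="module")
def disk_degen(aged_fixtures):
    records = expand_prevalence(aged_fixtures["disk degeneration"])
    fit = fit_logistic(records, "linear-age", endpoint="disk degeneration")
    return records, fit


class TestLogistic:
    def test_slope_matches_independent_ml_oracle(self, disk_degen):
        _, fit = disk_degen
        assert fit.slope == pytest.approx(ORACLE_DISK_DEGEN_SLOPE, abs=1e-5)
        assert fit.n == 1603

    def test_flat_prevalence_gives_zero_slope(self):
        records = [IndividualRecord(a, o) for a in (25.0, 55.0) for o in (1.0, 1.0, 0.0, 0.0)]
        fit = fit_logistic(records)
        assert fit.slope == pytest.approx(0.0, abs=1e-10)

    def test_all_one_class_is_separation(self):
        records = [IndividualRecord(a, 1.0) for a in (25.0, 35.0, 45.0)]
        with pytest.raises(SeparationError, match="all outcomes"):
            fit_logistic(records)

    def test_perfectly_separated_ages(self):
        records = [IndividualRecord(25.0, 0.0)] * 5 + [IndividualRecord(55.0, 1.0)] * 5
        with pytest.raises(SeparationError):
            fit_logistic(records, endpoint="sep")

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            fit_logistic([IndividualRecord(25.0, 0.5), IndividualRecord(55.0, 1.0)])

    @pytest.mark.parametrize("endpoint", ["disk degeneration", "facet degeneration", "spondylolisthesis"])
    def test_grouped_equals_expanded(self, aged_fixtures, endpoint):
        agg = aged_fixtures[endpoint]
        expanded = fit_logistic(expand_prevalence(agg), endpoint=endpoint)
        grouped = fit_logistic_grouped(agg)
        assert grouped.slope == pytest.approx(expanded.slope, abs=1e-8)
        assert grouped.se_slope == pytest.approx(expanded.se_slope, abs=1e-8)
        assert grouped.loglik == pytest.approx(expanded.loglik, abs=1e-8)
        assert grouped.n == expanded.n

    def test_translation_invariance(self, aged_fixtures):
        agg = aged_fixtures["disk degeneration"]
        shifted = representative_ages(agg, [a + 10 for a in agg.ages])
        f0 = fit_logistic(expand_prevalence(agg))
        f1 = fit_logistic(expand_prevalence(shifted))
        m0 = average_marginal_effect(f0, expand_prevalence(agg))
        m1 = average_marginal_effect(f1, expand_prevalence(shifted))
        assert abs(f1.slope - f0.slope) < 1e-10
        assert abs(f1.se_slope - f0.se_slope) < 1e-10
        assert abs(m1.estimate - m0.estimate) < 1e-10
        assert f1.intercept != pytest.approx(f0.intercept, abs=0.1)


class TestAverageMarginalEffect:
    def test_matches_statsmodels_margins(self, disk_degen):
        records, fit = disk_degen
        ame = average_marginal_effect(fit, records)
        ages, y = records_to_arrays(records)
        X = np.column_stack([np.ones_like(ages), ages])
        marg = sm.Logit(y, X).fit(disp=0).get_margeff(at="overall", method="dydx")
        assert ame.estimate == pytest.approx(100 * marg.margeff[0], abs=1e-6)
        assert ame.se == pytest.approx(100 * marg.margeff_se[0], abs=1e-6)

    def test_delta_se_matches_numerical_jacobian(self, disk_degen):
        records, fit = disk_degen
        ame = average_marginal_effect(fit, records)
        ages, _ = records_to_arrays(records)

        def ame_of(params):
            a, b = params
            p = 1 / (1 + np.exp(-(a + b * ages)))
            return 100 * np.mean(b * p * (1 - p))

        eps = 1e-6
        grad = np.empty(2)
        for i in range(2):
            up, dn = np.array(fit.params), np.array(fit.params)
            up[i] += eps
            dn[i] -= eps
            grad[i] = (ame_of(up) - ame_of(dn)) / (2 * eps)
        se_num = float(np.sqrt(grad @ fit.cov_params @ grad))
        assert ame.se == pytest.approx(se_num, abs=1e-6)

    def test_delta_se_matches_parametric_bootstrap(self, disk_degen):
        records, fit = disk_degen
        ame = average_marginal_effect(fit, records)
        ages, _ = records_to_arrays(records)
        rng = np.random.default_rng(12345)
        draws = rng.multivariate_normal(fit.params, fit.cov_params, size=100_000)
        p = 1 / (1 + np.exp(-(draws[:, :1] + draws[:, 1:] * ages[None, :])))
        ame_draws = 100 * np.mean(draws[:, 1:] * p * (1 - p), axis=1)
        assert ame.se == pytest.approx(float(ame_draws.std(ddof=1)), rel=0.02)

    def test_ci_uses_normal_multiplier(self, disk_degen):
        records, fit = disk_degen
        ame = average_marginal_effect(fit, records)
        assert ame.ci_low == pytest.approx(ame.estimate - 1.96 * ame.se, abs=1e-12)
        assert ame.ci_high == pytest.approx(ame.estimate + 1.96 * ame.se, abs=1e-12)
        assert ame.ci_low <= ame.estimate <= ame.ci_high

    def test_requires_linear_logistic_fit(self, disk_degen):
        records, _ = disk_degen
        gfit = fit_gaussian([IndividualRecord(a, float(i)) for i, a in enumerate((25.0, 35.0, 45.0))])
        with pytest.raises(ValueError, match="logistic"):
            average_marginal_effect(gfit, records)


class TestGaussian:
    def test_two_group_balanced_closed_form(self):
        records = [IndividualRecord(21.5, v) for v in (35.0, 36.4)] + [
            IndividualRecord(52.5, v) for v in (37.0, 37.2)
        ]
        fit = fit_gaussian(records)
        assert fit.slope == pytest.approx((37.1 - 35.7) / 31.0, abs=1e-12)

    def test_valentin_means_with_zero_noise(self):
        records = [IndividualRecord(21.5, 35.7)] * 12 + [IndividualRecord(52.5, 37.1)] * 12
        fit = fit_gaussian(records)
        assert fit.slope == pytest.approx(0.0451612903, abs=1e-9)
        assert fit.se_slope == 0.0

    def test_constant_outcome(self):
        records = [IndividualRecord(a, 5.0) for a in (25.0, 35.0, 45.0, 55.0)]
        fit = fit_gaussian(records)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.se_slope == 0.0

    def test_too_few_records_or_ages(self):
        with pytest.raises(ValueError, match=">= 3 records"):
            fit_gaussian([IndividualRecord(25.0, 1.0), IndividualRecord(35.0, 2.0)])
        with pytest.raises(ValueError, match="distinct ages"):
            fit_gaussian([IndividualRecord(25.0, v) for v in (1.0, 2.0, 3.0)])


class TestLinearityTest:
    def test_two_group_design_is_saturated(self, aged_fixtures):
        # with two groups the linear model spans the saturated one exactly
        from spinedecline import RngSpec, draw_continuous

        records = draw_continuous(aged_fixtures["psoas (V)"], RngSpec(5))
        sat = fit_gaussian(records, "age-group-factor")
        lin = fit_gaussian(records, "linear-age")
        res = lr_linearity_test(records, sat, lin)
        assert res.df == 0
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.pvalue == 1.0

    def test_logistic_linearity_not_violated_for_published_tables(self, aged_fixtures):
        for name, agg in aged_fixtures.items():
            if not isinstance(agg, PrevalenceAggregate):
                continue
            records = expand_prevalence(agg)
            sat = fit_logistic(records, "age-group-factor", endpoint=name)
            lin = fit_logistic(records, "linear-age", endpoint=name)
            res = lr_linearity_test(records, sat, lin)
            assert res.statistic >= 0.0
            assert res.df == 2
            assert res.pvalue > 0.05, name

    def test_gaussian_statistic_nonnegative(self, aged_fixtures):
        from spinedecline import RngSpec, draw_continuous

        for name in ("MF (C)", "psoas (V)"):
            records = draw_continuous(aged_fixtures[name], RngSpec(11, name))
            sat = fit_gaussian(records, "age-group-factor")
            lin = fit_gaussian(records, "linear-age")
            res = lr_linearity_test(records, sat, lin)
            assert res.statistic >= 0.0
            assert res.df == len(aged_fixtures[name].groups) - 2

    def test_non_nested_rejected(self):
        records = [IndividualRecord(a, float(o)) for a in (25.0, 35.0, 45.0) for o in (0, 1)]
        sat = fit_logistic(records, "age-group-factor")
        lin = fit_logistic(records, "linear-age")
        gauss = fit_gaussian(records, "linear-age")
        with pytest.raises(ValueError, match="saturated"):
            lr_linearity_test(records, lin, lin)
        with pytest.raises(ValueError, match="model kinds"):
            lr_linearity_test(records, sat, gauss)


def test_grouped_fit_from_raw_counts_example():
    # two-group aggregate built inline: 10/100 then 30/100 positives
    agg = PrevalenceAggregate(
        "toy", "s",
        (
            PrevalenceGroup(AgeGroup("20-29", 20, 29), 100, 10.0),
            PrevalenceGroup(AgeGroup("50-59", 50, 59), 100, 30.0),
        ),
    )
    agg = representative_ages(agg, "decade-equal-spacing")
    fit = fit_logistic_grouped(agg)
    # closed form: logit(0.30) - logit(0.10) over 30 years
    expected = (np.log(0.3 / 0.7) - np.log(0.1 / 0.9)) / 30.0
    assert fit.slope == pytest.approx(expected, abs=1e-8)
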