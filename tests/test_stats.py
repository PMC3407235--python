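"""Phenotype classification and cohort statistics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import ultrarhythm as ur
from ultrarhythm.errors import SingularDesignError, ValidationError
from ultrarhythm.stats import CONTRAST_CODES, PHOTOPERIOD_ORDER


def _meta(L, etv, fur=1, mass=30.0):
    return ur.AnimalMetadata(photoperiod_L=float(L), etv_week12=float(etv),
                             fur_score=fur, body_mass=mass)


@pytest.mark.parametrize(
    "L, etv, fur, label",
    [
        (11, 350, 1, "SD-NR"),
        (10, 50, 3, "SD-R"),
        (12, 350, 3, "SD-R"),   # large testes but moulted fur: responder
        (12, 299, 1, "SD-R"),
        (13, 400, 1, "13L+"),
        (13, 100, 2, "13L-"),
        (14, 300, 1, "14L-developed"),  # ETV cut is inclusive
        (14, 299, 1, "14L-undeveloped"),
        (15, 500, 1, "LD"),
    ],
)
def test_classify_phenotype(L, etv, fur, label):
    assert ur.classify_phenotype(_meta(L, etv, fur)) == label


class TestPrevalenceChi2:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((8, 8, 0, 9), 6.62),   # 13 L (50% of 16) vs 15 L (0 of 9)
            ((3, 11, 0, 9), 2.22),  # 14 L (21% of 14) vs 15 L
            ((8, 8, 3, 11), 2.62),  # 13 L vs 14 L
        ],
    )
    def test_printed_values(self, table, expected):
        res = ur.prevalence_chi2(*table)
        assert res.chi2 == pytest.approx(expected, abs=0.005)
        assert res.df == 1

    def test_equal_proportions_zero(self):
        assert ur.prevalence_chi2(5, 5, 5, 5).chi2 == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            ur.prevalence_chi2(0, 0, 3, 4)
        with pytest.raises(ValidationError):
            ur.prevalence_chi2(0, 3, 0, 4)

    @given(st.tuples(st.integers(1, 60), st.integers(1, 60),
                     st.integers(1, 60), st.integers(1, 60)))
    @settings(max_examples=100, deadline=None)
    def test_matches_expected_count_formulation(self, table):
        """N(ad-bc)^2/(margins) == sum (O-E)^2/E, and scipy agrees."""
        a, b, c, d = table
        res = ur.prevalence_chi2(a, b, c, d)
        obs = np.array([[a, b], [c, d]], float)
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        brute = ((obs - exp) ** 2 / exp).sum()
        assert res.chi2 == pytest.approx(brute, abs=1e-10)
        scipy_chi2 = sps.chi2_contingency(obs, correction=False)[0]
        assert res.chi2 == pytest.approx(scipy_chi2, abs=1e-10)


class TestContrasts:
    def test_codes_zero_sum_and_orthogonal(self):
        codes = list(CONTRAST_CODES.values())
        for c in codes:
            assert c.sum() == 0
        for i in range(3):
            for j in range(i + 1, 3):
                assert float(codes[i] @ codes[j]) == 0.0

    def test_pure_linear_profile(self):
        """Means proportional to the linear code leave no higher-order signal."""
        L = np.repeat(PHOTOPERIOD_ORDER, 4)
        lin = dict(zip(PHOTOPERIOD_ORDER, CONTRAST_CODES["linear"]))
        y = np.array([2.0 * lin[g] + 7.0 for g in L])
        res = ur.polynomial_contrasts(y, L)
        assert res.t_quadratic <= 1e-10
        assert res.t_cubic <= 1e-10
        assert res.t_linear == np.inf

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        L = np.repeat(PHOTOPERIOD_ORDER, 5)
        y = rng.normal(0, 1, L.size) + 0.3 * L
        r1 = ur.polynomial_contrasts(y, L)
        r2 = ur.polynomial_contrasts(5.0 * y - 11.0, L)
        for k in ("t_linear", "t_quadratic", "t_cubic"):
            assert getattr(r1, k) == pytest.approx(getattr(r2, k), rel=1e-9)

    def test_group_mean_mode_and_missing_group(self):
        L = np.repeat(PHOTOPERIOD_ORDER, 3)
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, L.size)
        res = ur.polynomial_contrasts(y, L, per_animal=False)
        assert np.isfinite(res.t_linear)
        with pytest.raises(ValidationError):
            ur.polynomial_contrasts(y[L != 12], L[L != 12])

    def test_matches_statsmodels_ols(self):
        """Joint contrast regression agrees with an independent OLS solver."""
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        L = np.repeat(PHOTOPERIOD_ORDER, 6)
        y = rng.normal(0, 1, L.size) - 0.4 * L + 0.05 * (L - 12.0) ** 2
        res = ur.polynomial_contrasts(y, L)
        idx = np.searchsorted(np.array(PHOTOPERIOD_ORDER, float), L)
        X = sm.add_constant(np.column_stack(
            [CONTRAST_CODES[k][idx] for k in ("linear", "quadratic", "cubic")]))
        smres = sm.OLS(y, X).fit()
        assert res.t_linear == pytest.approx(abs(smres.tvalues[1]), rel=1e-8)
        assert res.t_quadratic == pytest.approx(abs(smres.tvalues[2]), rel=1e-8)
        assert res.p_cubic == pytest.approx(smres.pvalues[3], rel=1e-6)


class TestRegress:
    def test_perfect_fit(self):
        x = np.arange(20.0)
        res = ur.regress(x * 2.0 + 1.0, x)
        assert res.R[0] == pytest.approx(1.0)
        assert res.R2 == pytest.approx(1.0)
        assert res.see == pytest.approx(0.0, abs=1e-10)

    def test_collinear_design_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(SingularDesignError):
            ur.regress(np.random.default_rng(0).normal(size=20),
                       np.column_stack([x, 2 * x]))

    def test_simulation_oracle_and_standardization(self):
        rng = np.random.default_rng(3)
        n = 200
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 2, n)
        y = 2 * x1 - x2 + rng.normal(0, 1, n)
        res = ur.regress(y, np.column_stack([x1, x2]))
        assert abs(res.b[0] - 2) < 3 * res.SE[0]
        assert abs(res.b[1] + 1) < 3 * res.SE[1]
        # standardized beta invariant to predictor rescaling
        res_scaled = ur.regress(y, np.column_stack([10 * x1, 0.5 * x2]))
        assert res.beta == pytest.approx(res_scaled.beta, rel=1e-9)

    def test_nesting_property(self):
        """Dropping a predictor never increases R^2."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 3))
        y = X @ [1.0, 0.5, 0.0] + rng.normal(0, 1, 80)
        full = ur.regress(y, X)
        for j in range(3):
            sub = ur.regress(y, np.delete(X, j, axis=1))
            assert sub.R2 <= full.R2 + 1e-12

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 2))
        y = X @ [1.5, -0.7] + rng.normal(0, 1, 60)
        res = ur.regress(y, X)
        smres = sm.OLS(y, sm.add_constant(X)).fit()
        assert res.b == pytest.approx(smres.params[1:], rel=1e-9)
        assert res.SE == pytest.approx(smres.bse[1:], rel=1e-9)
        assert res.R2 == pytest.approx(smres.rsquared, rel=1e-9)
        assert res.F == pytest.approx(smres.fvalue, rel=1e-9)


class TestAnova:
    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = ur.anova_plsd({"a": a, "b": b})
        t_p = sps.ttest_ind(a, b).pvalue
        assert res.pairwise_p[("a", "b")] == pytest.approx(t_p, rel=1e-9)
        assert res.p == pytest.approx(t_p, rel=1e-9)  # F(1,df) == t^2

    def test_null_type_I_rate(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 400
        for _ in range(reps):
            g = {k: rng.normal(0, 1, 10) for k in "abc"}
            if ur.anova_plsd(g).p <= 0.05:
                rejections += 1
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate < 0.05 + 3 * se
        assert rate > 0.05 - 3 * se

    def test_separated_groups_always_detected(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            g = {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20),
                 "c": rng.normal(5, 1, 20)}
            assert ur.anova_plsd(g).p < 0.001

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            ur.anova_plsd({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        with pytest.raises(ValidationError):
            ur.anova_plsd({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            ur.anova_plsd({"a": [1.0, 2.0]})
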