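import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb
from scipy.stats import rankdata

from vhitkit import stats, synthetic as syn
from vhitkit.errors import ConfigError, InputError, UndefinedStatisticError


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def spearman_oracle(x, y):
    """Pearson correlation of explicit midranks."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def u_oracle(a, b):
    """Brute-force pair counting: #(a > b) + 0.5 * #(a == b)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def fisher_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
        for x in range(lo, hi + 1)
    }
    total = sum(probs.values())
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)) / total


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert stats.spearman(x, x).statistic == pytest.approx(1.0)
        assert stats.spearman(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # ranks of y are (2,1,4,3,5): sum d^2 = 4, r = 1 - 24/120 = 0.8
        res = stats.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.statistic == pytest.approx(0.8)
        assert res.statistic == pytest.approx(
            spearman_oracle(np.array([1, 2, 3, 4, 5]), np.array([2, 1, 4, 3, 5]))
        )

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            stats.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        st.lists(st.integers(min_value=-5, max_value=5), min_size=4, max_size=12),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_midrank_oracle(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.array(xs, dtype=float)
        y = rng.integers(-5, 6, size=len(xs)).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert stats.spearman(x, y).statistic == pytest.approx(
            spearman_oracle(x, y), abs=1e-12
        )


class TestMannWhitney:
    def test_complete_separation(self):
        res = stats.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/C(6,3)=2/20

    def test_identical_samples_p_one(self):
        res = stats.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_interleaved_example_matches_pair_counting(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0]
        res = stats.mann_whitney(a, b)
        assert res.extra["u1"] == u_oracle(a, b) == 3.0
        assert res.statistic == min(u_oracle(a, b), u_oracle(b, a))

    def test_empty_raises(self):
        with pytest.raises(InputError):
            stats.mann_whitney([], [1.0])

    @given(
        st.lists(st.integers(min_value=0, max_value=9), min_size=2, max_size=6),
        st.lists(st.integers(min_value=0, max_value=9), min_size=2, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_u_matches_brute_force(self, a, b):
        a = [float(v) for v in a]
        b = [float(v) for v in b]
        res = stats.mann_whitney(a, b)
        assert res.extra["u1"] == pytest.approx(u_oracle(a, b))
        assert res.extra["u2"] == pytest.approx(u_oracle(b, a))

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1.0, 1, 30)
        res = stats.mann_whitney(a, b)
        assert res.extra["detail"] == "normal_tie_corrected"
        assert res.p_value < 0.01


class TestContingency:
    def test_independent_table_chi_square(self):
        res = stats.contingency_test([[5, 5], [5, 5]])
        assert res.method == "chi_square"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table_fisher(self):
        res = stats.contingency_test([[10, 0], [0, 10]])
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(2 / comb(20, 10, exact=True), rel=1e-9)
        assert res.p_value == pytest.approx(1.08e-5, rel=0.01)

    def test_doubling_preserves_fisher_odds_ratio(self):
        t1 = [[3, 1], [1, 3]]
        t2 = [[6, 2], [2, 6]]
        r1 = stats.contingency_test(t1)
        r2 = stats.contingency_test(t2)
        assert r1.method == r2.method == "fisher_exact"
        assert r1.statistic == pytest.approx(r2.statistic)  # conditional OR estimate

    def test_all_zero_raises(self):
        with pytest.raises(InputError):
            stats.contingency_test([[0, 0], [0, 0]])

    def test_negative_raises(self):
        with pytest.raises(InputError):
            stats.contingency_test([[1, -1], [2, 3]])

    @given(
        st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
    )
    @settings(max_examples=80, deadline=None)
    def test_fisher_matches_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        table = [[a, b], [c, d]]
        total = a + b + c + d
        expected = np.outer([a + b, c + d], [a + c, b + d]) / total
        if np.all(expected >= 5):
            return
        res = stats.contingency_test(table)
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(fisher_oracle(table), rel=1e-7, abs=1e-12)


class TestLogisticFit:
    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        y = (rng.random(1000) < 0.4).astype(float)
        fit = stats.logistic_fit(y, x[:, None])
        assert abs(fit.params[1]) < 3 * fit.se[1]

    def test_single_binary_covariate_equals_table_log_or(self):
        # oracle: closed-form log odds ratio of the 2x2 table
        y = np.array([1] * 30 + [0] * 70 + [1] * 10 + [0] * 90, dtype=float)
        x = np.array([1.0] * 100 + [0.0] * 100)
        fit = stats.logistic_fit(y, x[:, None])
        table_or = (30 / 70) / (10 / 90)
        assert fit.params[1] == pytest.approx(math.log(table_or), abs=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 3))
        logit = 0.3 + X @ np.array([0.8, -0.5, 0.0])
        y = (rng.random(400) < 1 / (1 + np.exp(-logit))).astype(float)
        fit = stats.logistic_fit(y, X)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.params, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, atol=1e-5)

    def test_score_identity_fitted_sum(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 2))
        y = (rng.random(300) < 0.3).astype(float)
        fit = stats.logistic_fit(y, X)
        assert fit.fitted.sum() == pytest.approx(y.sum(), abs=1e-6)

    def test_recovery_of_generating_slope(self):
        params = syn.CohortParams(
            n_patients=5000, seed=9, copy_intercept=4.0, copy_slope_hc_gain=-6.0
        )
        recs = syn.simulate_cohort(params)
        hc = np.array([0.5 * (r.gain_rhc + r.gain_lhc) for r in recs])
        y = np.array([float(r.rcft_copy_z < -2.0) for r in recs])
        fit = stats.logistic_fit(y, hc[:, None])
        assert fit.params[1] == pytest.approx(-6.0, abs=0.5)

    def test_separation_warns_and_firth_is_finite(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        x = np.concatenate([np.linspace(-2, -0.1, 20), np.linspace(0.1, 2, 20)])
        with pytest.warns(stats.SeparationWarning):
            stats.logistic_fit(y, x[:, None])
        firth = stats.logistic_fit(y, x[:, None], model="firth")
        assert firth.converged
        assert abs(firth.params[1]) < 50

    def test_one_class_raises(self):
        with pytest.raises(InputError):
            stats.logistic_fit(np.zeros(10), np.ones((10, 1)))


class TestBackwardSelect:
    @staticmethod
    def _data(n=2000, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {f"noise{i}": rng.normal(size=n) for i in range(5)}
            | {"signal": rng.normal(size=n)}
        )
        logit = -1.0 + 1.2 * X["signal"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        return y.to_numpy(), X

    def test_true_covariate_retained(self):
        y, X = self._data()
        res = stats.backward_select(y, X)
        assert "signal" in res.retained

    def test_alpha_one_is_identity(self):
        y, X = self._data()
        res = stats.backward_select(y, X, alpha_remove=1.0)
        assert set(res.retained) == set(X.columns)
        assert res.elimination_trace == []

    def test_all_noise_allows_intercept_only(self):
        rng = np.random.default_rng(3)
        n = 500
        X = pd.DataFrame({f"noise{i}": rng.normal(size=n) for i in range(4)})
        y = (rng.random(n) < 0.3).astype(float)
        res = stats.backward_select(y, X, alpha_remove=0.01)
        assert all(t.p_value <= 0.01 for t in res.terms)

    def test_or_consistency(self):
        y, X = self._data()
        res = stats.backward_select(y, X)
        for t in res.terms:
            assert t.odds_ratio == pytest.approx(math.exp(t.coefficient))
            assert t.ci_low <= t.odds_ratio <= t.ci_high


class TestRunPrimaryAnalysis:
    @staticmethod
    def _cohort(seed=0, n=2000, slope=-6.0, recall_gain_free=True):
        params = syn.CohortParams(
            n_patients=n, seed=seed, copy_intercept=4.0, copy_slope_hc_gain=slope
        )
        return syn.simulate_cohort(params)

    def test_copy_model_recovers_hc_gain(self):
        recs = self._cohort()
        res = stats.run_primary_analysis(recs)
        t = res.copy_model.term("hc_gain")
        assert t is not None
        assert t.odds_ratio < 1.0

    def test_recall_model_prefers_generating_covariates(self):
        recs = self._cohort(seed=4, n=3000)
        res = stats.run_primary_analysis(
            recs, stats.AnalysisConfig(run_sensitivity=False)
        )
        assert {"mmse", "age"} <= set(res.recall_model.retained)

    def test_correlation_table_shape(self):
        recs = self._cohort(n=300)
        res = stats.run_primary_analysis(
            recs, stats.AnalysisConfig(run_sensitivity=False)
        )
        assert len(res.correlations) == 9
        assert set(res.correlations["canal"]) == {"HC", "AC", "PC"}

    def test_sensitivity_variants_present(self):
        recs = self._cohort(n=800)
        res = stats.run_primary_analysis(recs)
        assert set(res.sensitivity) == {"copy_z_lt_minus1", "decreased_gain_nominal"}
        nominal = res.sensitivity["decreased_gain_nominal"]
        assert not any(t.name.endswith("_gain") for t in nominal.terms)

    def test_missing_columns_listed(self):
        recs = self._cohort(n=300)
        df = stats.cohort_frame(recs).drop(columns=["mmse", "cadence"])
        with pytest.raises(ConfigError, match="mmse"):
            stats.run_primary_analysis(df)

    def test_patient_order_invariance(self):
        recs = self._cohort(n=500)
        res1 = stats.run_primary_analysis(
            recs, stats.AnalysisConfig(run_sensitivity=False)
        )
        res2 = stats.run_primary_analysis(
            list(reversed(recs)), stats.AnalysisConfig(run_sensitivity=False)
        )
        assert res1.copy_model.retained == res2.copy_model.retained
        for t1, t2 in zip(res1.copy_model.terms, res2.copy_model.terms):
            assert t1.coefficient == pytest.approx(t2.coefficient, rel=1e-9)

    def test_association_report_renders(self):
        recs = self._cohort(n=500)
        res = stats.run_primary_analysis(
            recs, stats.AnalysisConfig(run_sensitivity=False)
        )
        text = stats.association_report(res.copy_model)
        assert "OR" in text and "no multiple-testing correction" in text
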