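"""Statistical layer against textbook decompositions and scipy oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from engulf3d import bca_ci, one_way_anova, sidak_adjust, two_way_anova, welch_t
from engulf3d.stats import SignificancePolicy, _bca_quantile_levels


def balanced_two_way_oracle(y, a, b):
    """Textbook cell-means decomposition for a balanced two-way design."""
    y = np.asarray(y, float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = y.mean()
    ss_a = sum(
        (a == la).sum() * (y[a == la].mean() - grand) ** 2 for la in np.unique(a)
    )
    ss_b = sum(
        (b == lb).sum() * (y[b == lb].mean() - grand) ** 2 for lb in np.unique(b)
    )
    ss_ab, ss_res = 0.0, 0.0
    for la in np.unique(a):
        for lb in np.unique(b):
            sel = (a == la) & (b == lb)
            cm = y[sel].mean()
            ss_ab += sel.sum() * (
                cm - y[a == la].mean() - y[b == lb].mean() + grand
            ) ** 2
            ss_res += ((y[sel] - cm) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_res


class TestTwoWayAnova:
    def _design(self, rng, n=5):
        a = np.repeat(["x", "y"], 2 * n)
        b = np.tile(np.repeat(["u", "v"], n), 2)
        y = rng.normal(size=4 * n)
        return y, a, b

    def test_residual_df_matches_design(self, rng):
        # 2x2 factorial over 38 animals leaves 34 residual df
        a = np.array(["x"] * 19 + ["y"] * 19)
        b = np.array((["u"] * 10 + ["v"] * 9) + (["u"] * 9 + ["v"] * 10))
        tab = two_way_anova(rng.normal(size=38), a, b)
        assert tab.residual["df"] == 34
        assert all(row["df"] == 1 for row in tab.effects.values())

    def test_all_equal_observations_give_zero_f(self):
        y = np.ones(12)
        a = np.repeat(["x", "y"], 6)
        b = np.tile(["u", "v"], 6)
        tab = two_way_anova(y, a, b)
        for row in tab.effects.values():
            assert row["F"] == 0.0
            assert row["p"] == 1.0

    def test_matches_balanced_oracle(self, rng):
        y, a, b = self._design(rng)
        tab = two_way_anova(y, a, b, names=("a", "b"))
        ss_a, ss_b, ss_ab, ss_res = balanced_two_way_oracle(y, a, b)
        assert tab.effects["a"]["ss"] == pytest.approx(ss_a, rel=1e-10)
        assert tab.effects["b"]["ss"] == pytest.approx(ss_b, rel=1e-10)
        assert tab.effects["a:b"]["ss"] == pytest.approx(ss_ab, rel=1e-10)
        assert tab.residual["ss"] == pytest.approx(ss_res, rel=1e-10)
        ms_res = ss_res / tab.residual["df"]
        assert tab.effects["a"]["F"] == pytest.approx(ss_a / ms_res, rel=1e-10)

    def test_balanced_ss_conservation(self, rng):
        y, a, b = self._design(rng, n=4)
        tab = two_way_anova(y, a, b)
        total = ((y - y.mean()) ** 2).sum()
        parts = sum(r["ss"] for r in tab.effects.values()) + tab.residual["ss"]
        assert parts == pytest.approx(total, rel=1e-9)

    def test_invariant_to_observation_order(self, rng):
        y, a, b = self._design(rng)
        perm = rng.permutation(len(y))
        t1 = two_way_anova(y, a, b)
        t2 = two_way_anova(y[perm], a[perm], b[perm])
        for k in t1.effects:
            assert t1.effects[k]["F"] == pytest.approx(t2.effects[k]["F"], rel=1e-9)

    def test_empty_cell_errors(self, rng):
        a = np.array(["x", "x", "y", "y", "x", "x"])
        b = np.array(["u", "u", "u", "u", "v", "v"])  # (y, v) cell empty
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(rng.normal(size=6), a, b)

    def test_too_few_residual_df_errors(self, rng):
        a = ["x", "x", "y", "y"]
        b = ["u", "v", "u", "v"]
        with pytest.raises(ValueError, match="residual df"):
            two_way_anova(rng.normal(size=4), a, b)


class TestOneWayAnova:
    def test_df_three_groups_of_ten(self, rng):
        tab = one_way_anova([rng.normal(size=10) for _ in range(3)])
        assert tab.effects["group"]["df"] == 2
        assert tab.residual["df"] == 27

    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        tab = one_way_anova([g, g, g])
        assert tab.effects["group"]["F"] == 0.0
        assert tab.effects["group"]["p"] == 1.0

    def test_two_groups_f_is_t_squared(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=8)
        tab = one_way_anova([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=True)[:2]
        assert tab.effects["group"]["F"] == pytest.approx(t**2, rel=1e-10)
        assert tab.effects["group"]["p"] == pytest.approx(p, rel=1e-10)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(size=n) for n in (5, 7, 9, 6)]
        tab = one_way_anova(groups)
        f, p = sps.f_oneway(*groups)
        assert tab.effects["group"]["F"] == pytest.approx(f, rel=1e-12)
        assert tab.effects["group"]["p"] == pytest.approx(p, rel=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0], []])


class TestWelch:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0]
        t, df, p = welch_t(a, a)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_equal_variance_equal_n_df(self):
        # Satterthwaite reduces exactly to n_a + n_b - 2
        a = np.array([0.0, 1.0, 2.0, 3.0])
        b = a + 10.0  # identical variance
        _, df, _ = welch_t(a, b)
        assert df == pytest.approx(len(a) + len(b) - 2)

    def test_formula_oracle(self, rng):
        a, b = rng.normal(size=9), rng.normal(0.5, 2.0, size=14)
        t, df, p = welch_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_o = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_o = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p_o = 2 * sps.t.sf(abs(t_o), df_o)
        assert t == pytest.approx(t_o, rel=1e-12)
        assert df == pytest.approx(df_o, rel=1e-12)
        assert p == pytest.approx(p_o, rel=1e-12)

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestSidak:
    def test_endpoints(self):
        assert sidak_adjust([0.0], m=3)[0] == 0.0
        assert sidak_adjust([1.0], m=3)[0] == 1.0

    def test_closed_form(self):
        assert sidak_adjust([0.01], m=2)[0] == pytest.approx(1 - 0.99**2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust([1.5], m=2)
        with pytest.raises(ValueError):
            sidak_adjust([0.01, 0.02], m=1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.floats(0, 1),
        q=st.floats(0, 1),
        m=st.integers(2, 20),
    )
    def test_monotone_in_p_and_m(self, p, q, m):
        lo, hi = sorted([p, q])
        a_lo, a_hi = sidak_adjust([lo, hi], m=m)
        assert a_lo <= a_hi  # monotone in p
        assert a_lo >= lo - 1e-15  # never decreases a p-value
        assert sidak_adjust([lo], m=m)[0] <= sidak_adjust([lo], m=m + 1)[0]


class TestBcaCi:
    def test_degenerate_constant_groups(self):
        est = bca_ci([2.0, 2.0, 2.0], [5.0, 5.0, 5.0], n_boot=100, seed=0)
        assert est.degenerate
        assert est.mean_difference == 3.0
        assert est.ci_low == est.ci_high == 3.0

    def test_reduces_to_percentile_when_unbiased_symmetric(self):
        boot = np.concatenate([-np.arange(1, 500.5), np.arange(1, 500.5)])
        a_lo, a_hi, z0 = _bca_quantile_levels(boot, 0.0, accel=0.0, level=0.95)
        assert z0 == pytest.approx(0.0, abs=1e-9)
        assert a_lo == pytest.approx(0.025, abs=1e-9)
        assert a_hi == pytest.approx(0.975, abs=1e-9)

    def test_deterministic_given_seed(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        e1 = bca_ci(a, b, n_boot=500, seed=7)
        e2 = bca_ci(a, b, n_boot=500, seed=7)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)

    def test_interval_brackets_point_estimate(self, rng):
        for s in range(5):
            r = np.random.default_rng(s)
            a, b = r.normal(size=12), r.normal(0.8, 1.5, size=9)
            est = bca_ci(a, b, n_boot=2000, seed=s)
            assert est.ci_low <= est.mean_difference <= est.ci_high

    def test_matches_scipy_bca(self, rng):
        # independent oracle: scipy's BCa on the same two-sample statistic
        a, b = rng.normal(size=15), rng.normal(1.0, 1.0, size=15)
        est = bca_ci(a, b, n_boot=20000, seed=1)
        res = sps.bootstrap(
            (b, a),
            lambda y, x, axis: y.mean(axis=axis) - x.mean(axis=axis),
            n_resamples=20000,
            method="BCa",
            confidence_level=0.95,
            random_state=np.random.default_rng(2),
        )
        scale = b.std() / math.sqrt(len(b))
        assert est.ci_low == pytest.approx(res.confidence_interval.low, abs=0.15 * scale)
        assert est.ci_high == pytest.approx(res.confidence_interval.high, abs=0.15 * scale)

    def test_close_to_t_interval_for_normal_data(self):
        # asymptotic agreement with the Welch t interval at n=50
        rel = []
        for s in range(10):
            r = np.random.default_rng(100 + s)
            a, b = r.normal(size=50), r.normal(size=50)
            est = bca_ci(a, b, n_boot=2000, seed=s)
            se = math.sqrt(a.var(ddof=1) / 50 + b.var(ddof=1) / 50)
            _, df, _ = welch_t(a, b)
            half = sps.t.ppf(0.975, df) * se
            lo, hi = est.mean_difference - half, est.mean_difference + half
            rel.append(abs(est.ci_low - lo) / half)
            rel.append(abs(est.ci_high - hi) / half)
        assert np.median(rel) < 0.10

    def test_validation(self):
        with pytest.raises(ValueError):
            bca_ci([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            bca_ci([1.0, 2.0], [1.0, 2.0], n_boot=0)


def test_significance_policy_validation():
    assert SignificancePolicy().alpha == 0.05
    with pytest.raises(ValueError):
        SignificancePolicy(alpha=1.5)
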