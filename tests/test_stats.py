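import numpy as np
import pandas as pd
import pytest

from mycsig import (
    ConvergenceError,
    StatError,
    SurvivalTable,
    adjust_bh,
    adjust_family,
    correlate,
    cox_binary,
    km_estimate,
    logrank_test,
    median_survival,
)
from oracles import (
    bh_oracle,
    cox_breslow_loglik,
    cox_breslow_score,
    cox_grid_argmax,
    km_oracle,
    logrank_oracle,
    spearman_oracle,
)


def surv(times, events, groups=None):
    df = pd.DataFrame({"time": times, "event": events},
                      index=[f"p{i}" for i in range(len(times))])
    if groups is not None:
        df["group"] = groups
    return SurvivalTable(df)


class TestCorrelate:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        r = correlate(x, x)
        assert r.coefficient == pytest.approx(1.0)

    def test_negative_affine_is_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = correlate(x, -2 * x + 5)
        assert r.coefficient == pytest.approx(-1.0)

    def test_spearman_five_point_example(self):
        # ranks differ by d = (-1, 1, -1, 1, 0): rho = 1 - 6*4/(5*24) = 0.8
        r = correlate(
            np.array([1.0, 2, 3, 4, 5]), np.array([2.0, 1, 4, 3, 5]),
            method="spearman",
        )
        assert r.coefficient == pytest.approx(0.8, abs=1e-12)

    def test_spearman_matches_rank_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(4, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r = correlate(x, y, method="spearman")
            assert r.coefficient == pytest.approx(
                spearman_oracle(x.tolist(), y.tolist()), abs=1e-9
            )

    def test_pairwise_complete_deletion(self):
        x = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0], index=list("abcde"))
        y = pd.Series([1.0, 2.0, 3.0, 4.0, np.nan], index=list("abcde"))
        r = correlate(x, y)
        assert r.n == 3
        assert r.coefficient == pytest.approx(1.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="3"):
            correlate(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_zero_variance_rejected(self):
        with pytest.raises(StatError, match="zero variance"):
            correlate(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_two_sided_p_from_t_transform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = correlate(x, y)
        t = r.coefficient * np.sqrt((r.n - 2) / (1 - r.coefficient**2))
        p = 2 * sps.t.sf(abs(t), df=r.n - 2)
        assert r.p_value == pytest.approx(p, rel=1e-9)


class TestAdjustBH:
    def test_stepup_collapses_equal_spaced_example(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_unchanged(self):
        assert np.allclose(adjust_bh([0.2, 0.2, 0.2]), 0.2)

    def test_matches_direct_stepup_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            p = rng.uniform(size=int(rng.integers(1, 12)))
            assert np.allclose(adjust_bh(p), bh_oracle(p.tolist()), atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=10)
        perm = rng.permutation(10)
        assert np.allclose(adjust_bh(p)[perm], adjust_bh(p[perm]), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.uniform(size=8))
        q = adjust_bh(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_domain_error(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            adjust_bh([0.5, 1.5])

    def test_adjust_family_q_at_least_p(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        results = [
            correlate(x, rng.normal(size=30) + 0.2 * x) for _ in range(6)
        ]
        adjust_family(results)
        for r in results:
            assert r.q_value >= r.p_value - 1e-12


class TestKaplanMeier:
    def test_hand_toy(self):
        # events at 1 and 3, censored at 2: S = 2/3 after t=1, 0 after t=3
        curve = km_estimate(surv([1.0, 2.0, 3.0], [1, 0, 1]))
        by_time = dict(zip(curve.times, curve.survival))
        assert by_time[0.0] == pytest.approx(1.0)
        assert by_time[1.0] == pytest.approx(2 / 3)
        assert by_time[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        curve = km_estimate(surv([1.0, 2.0, 3.0], [0, 0, 0]))
        assert np.allclose(curve.survival, 1.0)

    def test_single_event_drops_to_zero(self):
        curve = km_estimate(surv([5.0], [1]))
        assert curve.survival[-1] == pytest.approx(0.0)

    def test_monotone_nonincreasing_starting_at_one(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(1, 9))
            t = np.round(rng.exponential(5, size=n), 1) + 0.1
            e = rng.integers(0, 2, size=n)
            curve = km_estimate(surv(t, e))
            assert curve.survival[0] == pytest.approx(1.0)
            assert (np.diff(curve.survival) <= 1e-12).all()

    def test_matches_product_limit_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            t = np.round(rng.exponential(5, size=n), 1)
            e = rng.integers(0, 2, size=n)
            curve = km_estimate(surv(t, e))
            o_times, o_surv = km_oracle(t.tolist(), e.tolist())
            by_time = dict(zip(curve.times, curve.survival))
            for ot, os in zip(o_times, o_surv):
                assert by_time[ot] == pytest.approx(os, abs=1e-9)

    def test_group_restriction(self):
        table = surv([1.0, 2.0, 9.0], [1, 1, 0], ["A", "B", "A"])
        curve = km_estimate(table, group="A")
        assert dict(zip(curve.times, curve.survival))[1.0] == pytest.approx(0.5)


class TestMedianSurvival:
    def test_exact_half_boundary_counts(self):
        curve = km_estimate(surv([10.0, 20.0], [1, 1]))
        # S(10) = 0.5 exactly: the <= 0.5 rule picks t = 10
        assert median_survival(curve) == pytest.approx(10.0)

    def test_curve_never_reaching_half_is_undefined(self):
        curve = km_estimate(surv([1.0] + [2.0] * 9, [1] + [0] * 9))
        assert median_survival(curve) is None

    def test_hand_read_step_curve(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        curve = km_estimate(surv(t, [1, 1, 1, 0, 0]))
        # S: 0.8, 0.6, 0.4 -> first time with S <= 0.5 is t = 3
        assert median_survival(curve) == pytest.approx(3.0)


class TestLogrank:
    def test_hand_accumulated_toy(self):
        # A events at (1, 2); B events at (3, 4): chi2 = (7/6)^2 / (17/36)
        table = surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], ["A", "A", "B", "B"])
        result = logrank_test(table)
        assert result.chi2 == pytest.approx(49 / 17, abs=1e-9)
        assert result.observed["A"] == pytest.approx(2.0)
        assert result.expected["A"] == pytest.approx(5 / 6, abs=1e-12)

    def test_identical_groups_give_zero(self):
        table = surv([1.0, 2.0, 1.0, 2.0], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert logrank_test(table).chi2 == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(5, size=8)
        e = rng.integers(0, 2, size=8)
        e[0] = 1
        g = ["A"] * 4 + ["B"] * 4
        swapped = ["B" if x == "A" else "A" for x in g]
        r1 = logrank_test(surv(t, e, g))
        r2 = logrank_test(surv(t, e, swapped))
        assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 9))
            t = np.round(rng.exponential(5, size=n), 1)
            e = rng.integers(0, 2, size=n)
            g = rng.choice(["A", "B"], size=n)
            if len(set(g)) < 2 or e.sum() == 0:
                continue
            chi2, *_ , v = logrank_oracle(t.tolist(), e.tolist(),
                                          (g == "A").tolist())
            if not np.isfinite(chi2) or v <= 0:
                continue
            result = logrank_test(surv(t, e, g))
            assert result.chi2 == pytest.approx(chi2, abs=1e-9)
            checked += 1

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(31)
        t = rng.exponential(5, size=30)
        e = rng.integers(0, 2, size=30)
        e[:3] = 1
        g = np.array(["A"] * 15 + ["B"] * 15)
        mine = logrank_test(surv(t, e, g))
        ref = ll_logrank(t[g == "A"], t[g == "B"], e[g == "A"], e[g == "B"])
        assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_observed_totals_match_expected_totals(self):
        rng = np.random.default_rng(37)
        t = rng.exponential(5, size=12)
        e = np.ones(12, dtype=int)
        g = np.array(["A"] * 6 + ["B"] * 6)
        result = logrank_test(surv(t, e, g))
        assert sum(result.observed.values()) == pytest.approx(
            sum(result.expected.values()), abs=1e-9
        )

    def test_zero_events_rejected(self):
        with pytest.raises(StatError, match="no events"):
            logrank_test(surv([1.0, 2.0], [0, 0], ["A", "B"]))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(surv([1.0, 2.0], [1, 1], ["A", "A"]))


class TestCoxBinary:
    def test_symmetric_groups_give_null_hazard_ratio(self):
        table = surv(
            [1.0, 3.0, 1.0, 3.0, 5.0, 5.0],
            [1, 1, 1, 1, 0, 0],
            ["A", "A", "B", "B", "A", "B"],
        )
        result = cox_binary(table)
        assert result.log_hr == pytest.approx(0.0, abs=1e-6)
        assert result.hr == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_raises(self):
        table = surv([1.0, 2.0], [1, 1], ["High", "Low"])
        with pytest.raises(ConvergenceError):
            cox_binary(table)

    def test_score_vanishes_at_estimate_and_likelihood_improves(self):
        rng = np.random.default_rng(41)
        n = 60
        g = np.array(["High"] * 30 + ["Low"] * 30)
        lam = np.where(g == "High", 2.0, 1.0)
        t = rng.exponential(1 / lam)
        e = np.ones(n, dtype=int)
        table = surv(t, e, g)
        result = cox_binary(table, tie_method="breslow")
        x = (g == "High").astype(float).tolist()
        score = cox_breslow_score(result.log_hr, t.tolist(), e.tolist(), x)
        assert abs(score) < 1e-4
        ll_hat = cox_breslow_loglik(result.log_hr, t.tolist(), e.tolist(), x)
        ll_null = cox_breslow_loglik(0.0, t.tolist(), e.tolist(), x)
        assert ll_hat >= ll_null

    def test_matches_partial_likelihood_grid_search(self):
        rng = np.random.default_rng(43)
        n = 40
        g = np.array(["High"] * 20 + ["Low"] * 20)
        lam = np.where(g == "High", 1.8, 1.0)
        t = rng.exponential(1 / lam)
        e = rng.uniform(size=n) < 0.85
        table = surv(t, e.astype(int), g)
        result = cox_binary(table, tie_method="breslow")
        grid = cox_grid_argmax(t.tolist(), e.astype(int).tolist(),
                               (g == "High").astype(float).tolist())
        assert result.log_hr == pytest.approx(grid, abs=2e-3)

    def test_efron_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(47)
        n = 50
        g = np.array(["High"] * 25 + ["Low"] * 25)
        lam = np.where(g == "High", 2.0, 1.0)
        t = np.round(rng.exponential(1 / lam), 1) + 0.1
        e = np.ones(n, dtype=int)
        table = surv(t, e, g)
        result = cox_binary(table, tie_method="efron")
        df = pd.DataFrame({"t": t, "e": e, "x": (g == "High").astype(float)})
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert result.log_hr == pytest.approx(ref.params_["x"], abs=1e-5)

    def test_wald_ci_contains_hr(self):
        rng = np.random.default_rng(53)
        n = 80
        g = np.array(["High"] * 40 + ["Low"] * 40)
        t = rng.exponential(np.where(g == "High", 0.5, 1.0))
        table = surv(t, np.ones(n, dtype=int), g)
        result = cox_binary(table)
        assert result.ci95[0] < result.hr < result.ci95[1]
        assert result.exposed_group == "High"

    def test_zero_events_rejected(self):
        with pytest.raises(StatError, match="no events"):
            cox_binary(surv([1.0, 2.0], [0, 0], ["High", "Low"]))
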