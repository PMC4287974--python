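"""Survival estimators against hand computations, brute-force oracles and
the independent lifelines implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sigrank.survival import (
    CoxPH,
    cox_univariate,
    gehan_wilcoxon,
    km_estimate,
    logrank,
    two_sample_test,
)


# ------------------------------------------------------------------ oracles


def naive_partial_loglik(beta, time, event, x, ties="efron"):
    """Straight-from-the-definition partial log-likelihood (slow loops)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        deaths = np.where((time == t) & (event == 1))[0]
        risk = np.where(time >= t)[0]
        d = len(deaths)
        s0_risk = sum(np.exp(beta * x[j]) for j in risk)
        s0_dead = sum(np.exp(beta * x[j]) for j in deaths)
        ll += beta * sum(x[j] for j in deaths)
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            ll -= np.log(s0_risk - frac * s0_dead)
    return ll


def grid_max_beta(time, event, x, ties="efron", lo=-5, hi=5):
    # coarse grid, then a fine pass around the coarse maximizer
    grid = np.linspace(lo, hi, 1001)
    lls = [naive_partial_loglik(b, time, event, x, ties) for b in grid]
    b0 = grid[int(np.argmax(lls))]
    fine = np.linspace(b0 - 0.02, b0 + 0.02, 801)
    lls = [naive_partial_loglik(b, time, event, x, ties) for b in fine]
    return fine[int(np.argmax(lls))]


def naive_gehan(time_a, event_a, time_b, event_b):
    """Independent per-event-time tabulation of d, E, V with weight n_i."""
    t = np.concatenate([time_a, time_b]).astype(float)
    e = np.concatenate([event_a, event_b]).astype(int)
    g = np.concatenate([np.zeros(len(time_a)), np.ones(len(time_b))])
    num = den = 0.0
    for tt in sorted(set(t[e == 1])):
        n_i = (t >= tt).sum()
        n_ai = ((t >= tt) & (g == 0)).sum()
        d_i = ((t == tt) & (e == 1)).sum()
        d_ai = ((t == tt) & (e == 1) & (g == 0)).sum()
        e_ai = d_i * n_ai / n_i
        v_i = d_i * (n_ai / n_i) * (1 - n_ai / n_i) * (n_i - d_i) / (n_i - 1) if n_i > 1 else 0
        num += n_i * (d_ai - e_ai)
        den += n_i**2 * v_i
    return num**2 / den


# ------------------------------------------------------------------ KM


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        km = km_estimate([5, 8, 12], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(100) == 1.0

    def test_hand_product_limit(self):
        # times {1,2,3}, events {1,0,1}: S(1) = 2/3; at t=3 risk set is 1,
        # one death -> S(3) = 2/3 * 0 = 0
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_censored_at_event_time_stays_at_risk(self):
        # censoring at t=2 counted in the risk set of the death at t=2
        km = km_estimate([1, 2, 2, 3], [1, 1, 0, 1])
        assert km.survival_at(2) == pytest.approx((3 / 4) * (2 / 3))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.1, 100), min_size=1, max_size=40))
    def test_no_censoring_equals_empirical_survival(self, times):
        times = np.asarray(times)
        km = km_estimate(times, np.ones(times.size, dtype=int))
        for t in times:
            assert km.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 80).round(1)
        e = rng.integers(0, 2, 80)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tt, s in kmf.survival_function_.itertuples():
            assert km.survival_at(tt) == pytest.approx(s, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])


# ------------------------------------------------------------------ two-sample tests


class TestTwoSampleTests:
    def test_identical_groups_give_zero_statistic(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 0, 1]
        res = gehan_wilcoxon(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_three_vs_three_matches_hand_tabulation(self):
        ta, ea = [2, 5, 9], [1, 1, 0]
        tb, eb = [1, 3, 7], [1, 0, 1]
        res = gehan_wilcoxon(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(naive_gehan(ta, ea, tb, eb), rel=1e-12)
        assert res.p == pytest.approx(stats.chi2.sf(res.statistic, 1), rel=1e-12)

    def test_matches_lifelines_wilcoxon_and_logrank(self, rng):
        from lifelines.statistics import logrank_test

        ta = rng.exponential(10, 50).round(1)
        tb = rng.exponential(20, 60).round(1)
        ea = rng.integers(0, 2, 50)
        eb = rng.integers(0, 2, 60)
        ours = gehan_wilcoxon(ta, ea, tb, eb)
        ll = logrank_test(ta, tb, ea, eb, weightings="wilcoxon")
        assert ours.statistic == pytest.approx(ll.test_statistic, rel=1e-10)
        ours_lr = logrank(ta, ea, tb, eb)
        ll_lr = logrank_test(ta, tb, ea, eb)
        assert ours_lr.statistic == pytest.approx(ll_lr.test_statistic, rel=1e-10)

    def test_time_scaling_invariance(self, rng):
        ta, tb = rng.exponential(5, 30), rng.exponential(9, 30)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        a = two_sample_test(ta, ea, tb, eb, "logrank")
        b = two_sample_test(ta * 7.3, ea, tb * 7.3, eb, "logrank")
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_no_events_warns_p_one(self):
        res = gehan_wilcoxon([1, 2], [0, 0], [3, 4], [0, 0])
        assert res.p == 1.0

    def test_null_p_values_approximately_uniform(self, rng):
        ps = []
        for _ in range(300):
            t = rng.exponential(10, 60)
            c = rng.exponential(25, 60)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            half = rng.permutation(60) < 30
            ps.append(gehan_wilcoxon(time[half], event[half], time[~half], event[~half]).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


# ------------------------------------------------------------------ Cox


class TestCoxUnivariate:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate([1, 2, 3], [1, 1, 0], [2, 2, 2])

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_small_untied_matches_grid_oracle(self, ties):
        time = [1.0, 2.5, 3.0, 4.5, 6.0, 7.5]
        event = [1, 1, 0, 1, 1, 0]
        x = [0.5, -1.0, 0.2, 1.5, -0.3, 0.8]
        res = cox_univariate(time, event, x, ties=ties)
        assert res.converged
        assert res.beta == pytest.approx(grid_max_beta(time, event, x, ties), abs=1e-3)
        ours = naive_partial_loglik(res.beta, time, event, x, ties)
        assert res.loglik == pytest.approx(ours, rel=1e-10)

    def test_exhaustive_small_instances_match_oracle(self):
        # all event patterns (>=1 event) on a fixed untied 5-subject design
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        for pattern in itertools.product([0, 1], repeat=5):
            if sum(pattern) == 0:
                continue
            res = cox_univariate(time, pattern, x)
            if not res.converged:  # separation is legitimately flagged
                continue
            b_grid = grid_max_beta(time, pattern, x, lo=-5, hi=5)
            # the likelihood can be flat (tiny risk sets), so assert our
            # beta attains the grid maximum rather than equality of betas
            ll_ours = naive_partial_loglik(res.beta, time, pattern, x)
            ll_grid = naive_partial_loglik(b_grid, time, pattern, x)
            assert ll_ours >= ll_grid - 1e-8

    def test_tied_data_matches_lifelines_efron(self, rng):
        from lifelines import CoxPHFitter

        n = 150
        x = rng.integers(0, 2, n)
        t = np.round(rng.exponential(1 / (0.05 * 2.0**x)), 0) + 1
        c = rng.exponential(40, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        res = cox_univariate(time, event, x)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e")
        assert res.beta == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert res.se == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-6)
        assert res.wald_p == pytest.approx(cph.summary["p"].iloc[0], rel=1e-4)

    def test_separation_flagged_not_silent(self):
        # every high-covariate subject fails before any low-covariate one
        time = [1, 2, 3, 10, 11, 12]
        event = [1, 1, 1, 1, 1, 1]
        x = [1, 1, 1, 0, 0, 0]
        res = cox_univariate(time, event, x)
        assert res.separation and not res.converged
        assert abs(res.beta) == pytest.approx(CoxPH.MAX_ABS_BETA)

    def test_hr_and_ci_shape(self, cohort_fixture):
        matrix, cohort, truth = cohort_fixture
        res = cox_univariate(cohort.time, cohort.event, truth["latent_class"].to_numpy())
        lo, hi = res.conf_int()
        assert lo < res.hr < hi
        assert res.hr > 1.5  # planted 2.24 with n=400
        assert "HR" in res.summary()
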