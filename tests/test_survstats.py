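"""Statistical battery tests: hand arithmetic, brute force, and library oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import binary_roc, empirical_survival, permutation_logrank_p, spearman_nodiff_ties
from pet_hetero.survstats import (
    RocUndefinedError,
    km_fit,
    logrank_test,
    midranks,
    spearman_rho,
    stratify_and_report,
    td_roc,
)


class TestSpearman:
    def test_perfect_antimonotone(self):
        rho, p = spearman_rho([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert rho == -1.0 and p == 0.0

    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).normal(size=20)
        rho, _ = spearman_rho(x, x)
        assert rho == pytest.approx(1.0)

    def test_tie_free_matches_rank_difference_formula(self):
        x = (1, 2, 3, 4, 5)
        y = (2, 1, 4, 3, 5)
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(spearman_nodiff_ties(x, y))  # = 0.8 here
        assert rho == pytest.approx(0.8)

    def test_ties_match_scipy_midrank_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 5, size=15).astype(float)  # plenty of ties
            y = rng.integers(0, 5, size=15).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, p = spearman_rho(x, y)
            ref = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_midranks_average_ties(self):
        assert midranks([10.0, 20.0, 20.0, 30.0]).tolist() == [1.0, 2.5, 2.5, 4.0]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_antisymmetric_under_reversal(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho1, _ = spearman_rho(x, y)
        rho2, _ = spearman_rho(x, -y)
        assert rho1 == pytest.approx(-rho2)


class TestKaplanMeier:
    def test_hand_product_limit_with_censor(self):
        # times (2, 4+, 6): S = 2/3 after t=2, still 2/3 at t=5, 0 after t=6
        km = km_fit([2.0, 4.0, 6.0], [1, 0, 1])
        assert km.survival_at(5.0) == pytest.approx(2 / 3)
        assert km.survival_at(1.9) == 1.0
        assert km.survival_at(6.0) == pytest.approx(0.0)
        assert km.median_months == pytest.approx(6.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10.0, size=50)
        km = km_fit(times, np.ones(50, dtype=int))
        grid = np.linspace(0.1, 40.0, 57)
        got = np.array([km.survival_at(t) for t in grid])
        assert got == pytest.approx(empirical_survival(times, grid), abs=1e-12)

    def test_all_censored_never_reaches_median(self):
        km = km_fit([3.0, 6.0, 9.0], [0, 0, 0])
        assert km.survival_at(100.0) == 1.0
        assert km.median_months is None

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        t = rng.exponential(12.0, size=80)
        e = (rng.random(80) < 0.7).astype(int)
        km = km_fit(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        for q in (2.0, 8.0, 20.0):
            assert km.survival_at(q) == pytest.approx(
                float(kmf.survival_function_at_times(q).iloc[0]), abs=1e-10
            )
        ll_median = kmf.median_survival_time_
        assert km.median_months == pytest.approx(ll_median)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [2.0, 5.0, 8.0, 11.0]
        e = [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_hand_tally(self):
        """Group A fails at 1..5, group B at 11..15: O/E/V accumulates only
        over A's event times (B contributes at-risk counts)."""
        ta, tb = [1.0, 2.0, 3.0, 4.0, 5.0], [11.0, 12.0, 13.0, 14.0, 15.0]
        ea = eb = [1, 1, 1, 1, 1]
        chi2, _ = logrank_test(ta, ea, tb, eb)
        # hand tally: at A's times n_a=5..1, n=10..6, each d=1
        o_minus_e = sum(1 - na / (na + 5) for na in [5, 4, 3, 2, 1])
        var = sum((na / (na + 5)) * (5 / (na + 5)) for na in [5, 4, 3, 2, 1])
        assert chi2 == pytest.approx(o_minus_e**2 / var)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(5, 12), rng.exponential(9, 15)
        ea, eb = np.ones(12, int), (rng.random(15) < 0.8).astype(int)
        chi2_ab, p_ab = logrank_test(ta, ea, tb, eb)
        chi2_ba, p_ba = logrank_test(tb, eb, ta, ea)
        assert chi2_ab == pytest.approx(chi2_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [0, 0], [3.0], [0])

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(5)
        ta, tb = rng.exponential(5, 30), rng.exponential(10, 25)
        ea = (rng.random(30) < 0.8).astype(int)
        eb = (rng.random(25) < 0.8).astype(int)
        chi2, p = logrank_test(ta, ea, tb, eb)
        ref = lifelines_stats.logrank_test(ta, tb, event_observed_A=ea,
                                           event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


class TestTdRoc:
    def test_perfect_separation_auc_one(self):
        # no censoring before horizon; marker separates events from survivors
        marker = [1.1, 1.2, 1.3, 1.8, 1.9, 2.0]
        time = [20.0, 25.0, 30.0, 3.0, 5.0, 8.0]
        event = [0, 0, 0, 1, 1, 1]
        roc = td_roc(marker, time, event, 12.0)
        assert roc.auc == pytest.approx(1.0)
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0
        assert roc.optimal_cutoff == pytest.approx(1.3)

    def test_censoring_free_equals_binary_roc(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = 40
            marker = rng.normal(1.5, 0.3, n)
            time = rng.exponential(14.0, n)
            event = np.ones(n, dtype=int)  # no censoring at all
            if not ((time <= 12).any() and (time > 12).any()):
                continue
            roc = td_roc(marker, time, event, 12.0)
            ref_pts, ref_auc = binary_roc(marker, time <= 12.0)
            got = {c: (se, sp) for c, se, sp in roc.curve}
            for c, se, sp in ref_pts:
                assert got[c][0] == pytest.approx(se, abs=1e-12)
                assert got[c][1] == pytest.approx(sp, abs=1e-12)
            assert roc.auc == pytest.approx(ref_auc, abs=1e-12)

    def test_hand_km_weighted_example(self):
        """Eight subjects, one censored before the horizon; Se/Sp at cutoff 1.4
        computed by hand from the stratified product-limit estimates."""
        marker = [1.0, 1.1, 1.2, 1.3, 1.5, 1.6, 1.8, 2.0]
        time = [20.0, 15.0, 10.0, 8.0, 6.0, 14.0, 4.0, 9.0]
        event = [0, 1, 1, 0, 1, 0, 1, 1]
        roc = td_roc(marker, time, event, 12.0)
        got = {c: (se, sp) for c, se, sp in roc.curve}
        # high stratum {1.5,1.6,1.8,2.0}: events at 4,6,9 -> S(12) = 1/4
        # low stratum {1.0,...,1.3}: event at 10 with 3 at risk -> S(12) = 2/3
        # Se = .5*(3/4) / (1 - (.5*1/4 + .5*2/3)); Sp = .5*(2/3) / (.5*1/4 + .5*2/3)
        assert got[1.3][0] == pytest.approx(0.375 / (1 - 0.4583333333333333))
        assert got[1.3][0] == pytest.approx(0.6923076923076923)
        assert got[1.3][1] == pytest.approx(0.7272727272727273)

    def test_no_events_by_horizon_rejected(self):
        with pytest.raises(RocUndefinedError):
            td_roc([1.0, 2.0, 3.0], [20.0, 25.0, 30.0], [1, 1, 0], 12.0)

    def test_no_survivors_past_horizon_rejected(self):
        with pytest.raises(RocUndefinedError):
            td_roc([1.0, 2.0, 3.0], [2.0, 5.0, 8.0], [1, 1, 1], 12.0)

    def test_youden_ties_break_toward_smaller_cutoff(self):
        # two cutoffs achieve the same Youden index; the smaller one is kept
        marker = [1.0, 1.0, 2.0, 3.0, 3.0]
        time = [20.0, 25.0, 18.0, 3.0, 5.0]
        event = [0, 0, 0, 1, 1]
        roc = td_roc(marker, time, event, 12.0)
        assert roc.optimal_cutoff == pytest.approx(2.0)
        assert roc.youden == pytest.approx(1.0)


class TestStratifyAndReport:
    def _cohort(self, seed=0, n=200, effect=2.5):
        from pet_hetero.phantom import PhantomConfig, simulate_outcomes

        rng = np.random.default_rng(seed)
        marker = np.concatenate([rng.uniform(1.2, 1.4, n // 2),
                                 rng.uniform(1.7, 1.9, n - n // 2)])
        cfg = PhantomConfig(hazard_log_hr=effect)
        out = simulate_outcomes(marker, cfg, rng)
        return marker, out["pfs_months"].to_numpy(), out["event"].to_numpy()

    def test_full_bundle_under_strong_effect(self):
        marker, time, event = self._cohort(seed=11)
        bundle = stratify_and_report(marker, time, event, horizon_months=12.0)
        assert not bundle["degenerate"]
        assert 1.3 < bundle["roc"]["optimal_cutoff"] < 1.8
        assert bundle["logrank"]["p_value"] < 0.05
        assert bundle["spearman"]["rho"] > 0  # higher HI, more progression
        high_med = bundle["km"]["high"]["median_pfs_months"]
        low_med = bundle["km"]["low"]["median_pfs_months"]
        assert low_med == "not reached" or high_med < low_med

    def test_degenerate_stratum_flagged(self):
        marker = [1.0, 1.0, 1.0, 1.0, 1.0, 5.0]
        time = [20.0, 22.0, 25.0, 30.0, 28.0, 2.0]
        event = [0, 0, 0, 0, 0, 1]
        bundle = stratify_and_report(marker, time, event, horizon_months=12.0)
        assert bundle["degenerate"]
        assert "logrank" not in bundle


def test_logrank_p_close_to_permutation_reference():
    """Chi-square p within Monte-Carlo error of a 10,000-permutation reference."""
    rng = np.random.default_rng(7)
    n = 20
    time = rng.exponential(10.0, n)
    event = (rng.random(n) < 0.8).astype(int)
    group = rng.random(n) < 0.5
    if event[group].sum() + event[~group].sum() == 0:  # pragma: no cover
        pytest.skip("degenerate draw")
    chi2 = lambda ta, ea, tb, eb: logrank_test(ta, ea, tb, eb)[0]  # noqa: E731
    p_perm = permutation_logrank_p(time, event, group, chi2, n_perm=10_000, seed=1)
    _, p_chi2 = logrank_test(time[group], event[group], time[~group], event[~group])
    # permutation MC sd at p~0.5 is ~0.005; allow asymptotic-vs-exact slack too
    assert p_chi2 == pytest.approx(p_perm, abs=0.05)
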