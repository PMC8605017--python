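import itertools
import math
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import optimize, stats

from ctdyn.survival import (SubjectRecord, classify_landmark_status, cox_fit,
                            cox_score_test, km_estimate, lead_time_analysis,
                            logrank_test, signed_rank_test)


class TestKM:
    def test_all_censored_survival_one(self):
        km = km_estimate([5.0, 8.0, 12.0], [False, False, False])
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_all_events_closed_form(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_computed_with_censoring(self):
        # times 2(e), 3(c), 5(e), 7(e), 9(c):
        # S(2) = 4/5; S(5) = 4/5 * 2/3 = 8/15; S(7) = 8/15 * 1/2 = 4/15
        km = km_estimate([2, 3, 5, 7, 9.0], [1, 0, 1, 1, 0])
        assert np.allclose(km.times, [2, 5, 7])
        assert np.allclose(km.survival, [4 / 5, 8 / 15, 4 / 15])
        # Greenwood at t=5: S^2 * (1/(5*4) + 1/(3*2))
        gw = (8 / 15) ** 2 * (1 / 20 + 1 / 6)
        assert km.variance[1] == pytest.approx(gw)

    def test_no_censoring_equals_empirical(self, rng):
        t = rng.exponential(10, 60)
        km = km_estimate(t, np.ones(60, dtype=bool))
        grid = np.quantile(t, [0.1, 0.4, 0.8])
        emp = [(t > g).mean() for g in grid]
        assert np.allclose(km.survival_at(grid), emp)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([0.0], [True])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([3, 5, 7, 11.0])
        e = np.array([1, 1, 0, 1], dtype=bool)
        stat, p = logrank_test([(t, e), (t, e)])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        t1, e1 = np.array([2, 4, 6, 8.0]), np.array([1, 1, 0, 1], dtype=bool)
        t2, e2 = np.array([3, 5, 7, 9.0]), np.array([1, 0, 1, 1], dtype=bool)
        stat, _ = logrank_test([(t1, e1), (t2, e2)])
        # brute force observed-expected and hypergeometric variance per
        # event time for group 1
        t = np.concatenate([t1, t2])
        e = np.concatenate([e1, e2])
        g = np.array([0] * 4 + [1] * 4)
        O = E = V = 0.0
        for u in sorted(t[e]):
            at = t >= u
            n = at.sum()
            n1 = (at & (g == 0)).sum()
            d = (e & (t == u)).sum()
            d1 = (e & (t == u) & (g == 0)).sum()
            O += d1
            E += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert stat == pytest.approx((O - E) ** 2 / V)

    def test_equals_cox_score_test(self, rng):
        n = 40
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(8 * np.exp(-0.7 * x))
        c = rng.exponential(10, n)
        times, events = np.minimum(t, c), t <= c
        stat, _ = logrank_test([(times[x == 0], events[x == 0]),
                                (times[x == 1], events[x == 1])])
        score, _ = cox_score_test(x, times, events)
        assert stat == pytest.approx(score, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([(np.array([1.0]), np.array([True])),
                          (np.array([]), np.array([]))])


class TestCox:
    def test_no_information_beta_zero(self):
        # covariate uncorrelated by symmetry: pairs of identical times
        t = np.array([1, 1, 2, 2, 3, 3.0])
        e = np.ones(6, dtype=bool)
        x = np.array([0, 1, 0, 1, 0, 1.0])
        fit = cox_fit(x, t, e)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_brute_force_small_dataset(self):
        t = np.array([2, 3, 5, 7, 11, 13.0])
        e = np.array([1, 1, 0, 1, 1, 0], dtype=bool)
        x = np.array([0.5, -0.2, 1.0, 0.1, -1.0, 0.7])
        fit = cox_fit(x, t, e)

        def neg_pl(beta):
            # Efron reduces to Breslow here (no ties): direct partial lik
            ll = 0.0
            for i in range(6):
                if not e[i]:
                    continue
                risk = t >= t[i]
                ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
            return -ll

        res = optimize.minimize_scalar(neg_pl, bounds=(-5, 5),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-neg_pl(fit.coef[0]), abs=1e-9)

    def test_efron_ties_against_lifelines(self, rng):
        from lifelines import CoxPHFitter
        import pandas as pd
        n = 80
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(5 * np.exp(-0.5 * x)))  # heavy ties
        e = rng.random(n) < 0.8
        fit = cox_fit(x, t, e)
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert fit.coef[0] == pytest.approx(float(ref.params_.iloc[0]),
                                            abs=1e-5)
        assert fit.se[0] == pytest.approx(
            float(ref.standard_errors_.iloc[0]), rel=1e-4)

    def test_sign_flip_on_label_flip(self, rng):
        x = rng.binomial(1, 0.5, 50).astype(float)
        t = rng.exponential(5 * np.exp(-x))
        e = np.ones(50, dtype=bool)
        f1 = cox_fit(x, t, e)
        f2 = cox_fit(1 - x, t, e)
        assert f1.coef[0] == pytest.approx(-f2.coef[0], abs=1e-8)

    def test_centering_invariance(self, rng):
        x = rng.normal(size=50)
        t = rng.exponential(5 * np.exp(-0.5 * x))
        e = np.ones(50, dtype=bool)
        f1 = cox_fit(x, t, e)
        f2 = cox_fit(x - 3.7, t, e)
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-8)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_coverage_two_group_hr4(self):
        # 200 replicates of n=500 piecewise-exponential two-group data with
        # true HR 4; 95% CI coverage must be >= 93%
        rng = np.random.default_rng(2024)
        covered = 0
        reps = 200
        for _ in range(reps):
            x = rng.binomial(1, 0.5, 500).astype(float)
            t = rng.exponential(1.0 / (0.05 * np.exp(math.log(4) * x)))
            c = rng.exponential(25, 500)
            times, events = np.minimum(t, c), t <= c
            fit = cox_fit(x, times, events)
            lo, hi = fit.hr_ci()
            if lo[0] <= 4.0 <= hi[0]:
                covered += 1
        assert covered >= 0.93 * reps

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(np.zeros(10), np.arange(1, 11.0), np.ones(10, dtype=bool))

    def test_separation_flagged(self):
        t = np.array([1, 2, 3, 10, 11, 12.0])
        e = np.ones(6, dtype=bool)
        x = np.array([1, 1, 1, 0, 0, 0.0])
        fit = cox_fit(x, t, e)
        assert fit.separation_flag


def _result(pid, day, pos):
    return SimpleNamespace(patient=pid, draw_day=float(day),
                           positive=bool(pos), unevaluable=False)


def _subj(pid, rfs=700.0, event=False, act=False, act_start=float("nan"),
          act_end=float("nan")):
    return SubjectRecord(patient=pid, tp53_mut=False, t4_stage=False,
                         act_received=act, act_start_day=act_start,
                         act_end_day=act_end, rfs_day=rfs, event=event)


class TestLandmarkStatus:
    def test_postsurgical_positive_before_act(self):
        subj = _subj("P1", act=True, act_start=40.0, act_end=100.0)
        st = classify_landmark_status([subj], [_result("P1", 25, True)])
        assert st["P1"]["postsurgical"] is True

    def test_window_miss_gives_absent_status(self):
        st = classify_landmark_status([_subj("P1")], [_result("P1", 45, True)])
        assert st["P1"]["postsurgical"] is None
        assert st["P1"]["longitudinal"] is True

    def test_longitudinal_any_positive(self):
        st = classify_landmark_status(
            [_subj("P1")],
            [_result("P1", 20, False), _result("P1", 200, True)])
        assert st["P1"]["postsurgical"] is False
        assert st["P1"]["longitudinal"] is True

    def test_post_act_window(self):
        subj = _subj("P1", act=True, act_start=40.0, act_end=120.0)
        st = classify_landmark_status(
            [subj], [_result("P1", 150, True)])
        assert st["P1"]["post_act"] is True
        st2 = classify_landmark_status(
            [subj], [_result("P1", 120.0 + 4 * 30.44 + 1, True)])
        assert st2["P1"]["post_act"] is None

    def test_sample_after_recurrence_excluded(self, caplog):
        subj = _subj("P1", rfs=100.0, event=True)
        with caplog.at_level("WARNING"):
            st = classify_landmark_status([subj], [_result("P1", 150, True)])
        assert "after recurrence" in caplog.text
        assert st["P1"]["longitudinal"] is None

    def test_latest_vs_any_positive_rule(self):
        results = [_result("P1", 10, True), _result("P1", 25, False)]
        st = classify_landmark_status([_subj("P1")], results)
        assert st["P1"]["postsurgical"] is False
        st2 = classify_landmark_status([_subj("P1")], results,
                                       postsurgical_rule="any_positive")
        assert st2["P1"]["postsurgical"] is True

    def test_idempotent_and_order_invariant(self):
        results = [_result("P1", 10, True), _result("P1", 95, False),
                   _result("P1", 200, True)]
        a = classify_landmark_status([_subj("P1")], results)
        b = classify_landmark_status([_subj("P1")], results[::-1])
        assert a == b


class TestSignedRank:
    def test_all_zero_differences(self):
        w, p = signed_rank_test(np.zeros(8))
        assert w == 0.0
        assert p == 1.0

    def test_exact_matches_enumeration_n6(self):
        d = np.array([3.0, -1.5, 2.0, 2.0, -0.5, 4.0])
        w, p = signed_rank_test(d)
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        tots = []
        for signs in itertools.product([0, 1], repeat=6):
            tots.append(ranks[np.array(signs) == 1].sum())
        tots = np.array(tots)
        p_exact = min(1.0, 2 * min((tots <= w_obs).mean(),
                                   (tots >= w_obs).mean()))
        assert w == pytest.approx(w_obs)
        assert p == pytest.approx(p_exact)

    def test_matches_scipy_exact_no_ties(self, rng):
        d = rng.normal(0.4, 1.0, 14)
        _, p = signed_rank_test(d)
        ref = stats.wilcoxon(d, mode="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_large_sample_normal_approx(self, rng):
        d = rng.normal(0.3, 1.0, 60)
        _, p = signed_rank_test(d)
        ref = stats.wilcoxon(d, mode="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestLeadTime:
    def test_single_pair_lead(self):
        med, _ = lead_time_analysis([(100.0, 289.0)])
        assert med == 189.0

    def test_all_zero_leads(self):
        med, p = lead_time_analysis([(50.0, 50.0)] * 5)
        assert med == 0.0
        assert p == 1.0

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            lead_time_analysis([])

    def test_median_and_p(self):
        pairs = [(10, 98.0), (20, 40.0), (30, 150.0), (5, 10.0), (40, 130.0)]
        med, p = lead_time_analysis(pairs)
        leads = np.array([b - a for a, b in pairs])
        assert med == np.median(leads)
        assert 0 < p < 1
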