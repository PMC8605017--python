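import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdyn.evaluation import (DEFAULT_LANDMARK, DEFAULT_WINDOWS,
                              EvaluationWindow, LandmarkCoxSpec,
                              MetricDistribution, StaticCoxSpec,
                              compare_prediction_models, comparison_table,
                              hosmer_lemeshow, loocv_hosmer_lemeshow,
                              prediction_error, repeated_kfold_cv,
                              time_dependent_auroc)
from ctdyn.survival import km_estimate
from ctdyn.synthetic import simulate_joint_cohort, strong_association_params

W = EvaluationWindow(100.0, 200.0)


class TestWindow:
    def test_defaults_are_8_12_15_months(self):
        assert DEFAULT_LANDMARK == pytest.approx(8 * 30.44)
        assert [w.u for w in DEFAULT_WINDOWS] == \
            pytest.approx([12 * 30.44, 15 * 30.44])

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            EvaluationWindow(200.0, 100.0)


class TestAUROC:
    def test_identical_predictions_half(self):
        times = np.array([150, 150, 250, 250.0])
        events = np.array([1, 1, 0, 0], dtype=bool)
        a = time_dependent_auroc(np.full(4, 0.7), times, events, W)
        assert a == 0.5

    def test_perfect_separation_one(self):
        times = np.array([150, 160, 250, 260.0])
        events = np.array([1, 1, 0, 0], dtype=bool)
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        assert time_dependent_auroc(scores, times, events, W) == 1.0

    def test_brute_force_eight_subjects(self, rng):
        times = np.array([120, 140, 160, 180, 210, 230, 260, 300.0])
        events = np.array([1, 1, 0, 1, 0, 0, 0, 0], dtype=bool)
        # fully observed: censored-after-u subjects are controls;
        # subject censored at 160 in-window gets dropped without weights
        scores = rng.random(8)
        got = time_dependent_auroc(scores, times, events, W)
        cases = [i for i in range(8) if events[i] and times[i] <= 200]
        controls = [i for i in range(8) if times[i] > 200]
        num = den = 0.0
        for i in cases:
            for j in controls:
                num += (scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
                den += 1
        assert got == pytest.approx(num / den)

    def test_censored_in_window_fractional_weight(self):
        times = np.array([150, 170, 250, 250.0])
        events = np.array([1, 0, 0, 0], dtype=bool)   # idx 1 censored at 170
        scores = np.array([0.9, 0.6, 0.3, 0.2])
        cep = np.array([np.nan, 0.5, np.nan, np.nan])
        got = time_dependent_auroc(scores, times, events, W,
                                   cens_event_prob=cep)
        # hand computation: weights w = [1, .5, 0, 0]
        w = np.array([1.0, 0.5, 0.0, 0.0])
        num = den = 0.0
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                pw = w[i] * (1 - w[j])
                num += pw * ((scores[i] > scores[j])
                             + 0.5 * (scores[i] == scores[j]))
                den += pw
        assert got == pytest.approx(num / den)

    def test_no_cases_flagged(self):
        times = np.array([250, 260.0])
        events = np.array([0, 0], dtype=bool)
        with pytest.raises(ValueError):
            time_dependent_auroc(np.array([0.1, 0.2]), times, events, W)

    @given(st.floats(min_value=0.1, max_value=5.0),
           st.floats(min_value=-2.0, max_value=2.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, a, b):
        rng = np.random.default_rng(0)
        times = np.array([120, 150, 180, 240, 260, 280, 320, 400.0])
        events = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
        scores = rng.random(8)
        v1 = time_dependent_auroc(scores, times, events, W)
        v2 = time_dependent_auroc(a * scores + b, times, events, W)
        assert v1 == pytest.approx(v2)


class TestPredictionError:
    def test_perfect_predictions_zero(self):
        times = np.array([150, 250.0])
        events = np.array([1, 0], dtype=bool)
        pe = prediction_error(np.array([0.0, 1.0]), times, events, W)
        assert pe == 0.0

    def test_constant_half_quarter(self):
        times = np.array([150, 150, 250, 250.0])
        events = np.array([1, 1, 0, 0], dtype=bool)
        pe = prediction_error(np.full(4, 0.5), times, events, W)
        assert pe == 0.25

    def test_constant_event_fraction_identity(self):
        # PE of the constant predictor pi = 1 - p equals p(1-p) exactly
        times = np.array([150, 150, 150, 250, 250, 250, 250, 250.0])
        events = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
        p = 3 / 8
        pe = prediction_error(np.full(8, 1 - p), times, events, W)
        assert pe == pytest.approx(p * (1 - p))

    def test_censored_three_term_decomposition(self):
        # hand computation: survivor (1-.8)^2; event .6^2;
        # censored at 170 with pi(u|c)=.7: .7*(1-.5)^2 + .3*(.5)^2
        times = np.array([250, 150, 170.0])
        events = np.array([0, 1, 0], dtype=bool)
        pi = np.array([0.8, 0.6, 0.5])
        cens = np.array([np.nan, np.nan, 0.7])
        pe = prediction_error(pi, times, events, W, cens_surv_prob=cens)
        expect = ((1 - 0.8) ** 2 + 0.36 + (0.7 * 0.25 + 0.3 * 0.25)) / 3
        assert pe == pytest.approx(expect)

    def test_empty_risk_set_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(np.array([]), np.array([]), np.array([]), W)


class TestHosmerLemeshow:
    def test_perfect_calibration_zero(self):
        # constant predictions keep the stable sort order, so each third is
        # one group with exactly 10 events and 20 survivors -> observed 1/3
        pattern_t = np.concatenate([np.full(10, 150.0), np.full(20, 250.0)])
        pattern_e = np.concatenate([np.ones(10, bool), np.zeros(20, bool)])
        times = np.tile(pattern_t, 3)
        events = np.tile(pattern_e, 3)
        C, p, table = hosmer_lemeshow(np.full(90, 1 / 3), times, events, W,
                                      n_groups=3)
        assert C == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_observed_is_km_not_raw_fraction(self):
        # a censor before the event time makes KM differ from the raw
        # event fraction: [140(c), 150(e), 250(s)] -> KM event prob 1/2,
        # raw fraction 1/3
        grp_t = np.array([140.0, 150.0, 250.0])
        grp_e = np.array([0, 1, 0], dtype=bool)
        times = np.tile(grp_t, 2)
        events = np.tile(grp_e, 2)
        C, p, table = hosmer_lemeshow(np.full(6, 0.5), times, events, W,
                                      n_groups=2)
        km = km_estimate(grp_t, grp_e)
        for g in table:
            assert g["observed"] == pytest.approx(1 - km.survival_at(200.0))
            assert g["observed"] == pytest.approx(0.5)
            assert g["observed"] != pytest.approx(grp_e.mean())
        assert C == pytest.approx(0.0, abs=1e-12)

    def test_three_group_hand_computation(self):
        times = np.concatenate([[150.0] * 2 + [250.0] * 4,
                                [150.0] * 3 + [250.0] * 3,
                                [150.0] * 4 + [250.0] * 2])
        events = np.concatenate([[True] * 2 + [False] * 4,
                                 [True] * 3 + [False] * 3,
                                 [True] * 4 + [False] * 2])
        pred = np.concatenate([np.full(6, 0.2), np.full(6, 0.5),
                               np.full(6, 0.7)])
        C, p, table = hosmer_lemeshow(pred, times, events, W, n_groups=3)
        # no censoring: observed = raw fractions 2/6, 3/6, 4/6
        expect = sum((o - e) ** 2 * 6 / (e * (1 - e))
                     for o, e in [(2 / 6, 0.2), (3 / 6, 0.5), (4 / 6, 0.7)])
        assert C == pytest.approx(expect)
        assert len(table) == 3

    def test_c_nonnegative_and_merge_logged(self, caplog):
        times = np.array([150.0, 150, 160, 170, 180, 190])
        events = np.array([1, 1, 0, 0, 0, 0], dtype=bool)
        with caplog.at_level("WARNING"):
            C, p, table = hosmer_lemeshow(
                np.linspace(0.1, 0.9, 6), times, events, W, n_groups=3)
        assert C >= 0


class TestCompare:
    def mk(self, vals):
        return MetricDistribution("m", "AUROC", W, np.asarray(vals))

    def test_identical_distributions_p_one(self):
        a = self.mk([0.7, 0.8, 0.75, 0.72])
        diff, p = compare_prediction_models(a, self.mk([0.7, 0.8, 0.75,
                                                       0.72]))
        assert diff == 0.0
        assert p == 1.0

    def test_exact_enumeration_n6(self):
        a = self.mk([0.70, 0.72, 0.74, 0.76, 0.78, 0.80])
        b = self.mk([0.68, 0.73, 0.70, 0.74, 0.72, 0.79])
        _, p = compare_prediction_models(a, b)
        d = a.values - b.values
        from scipy.stats import rankdata
        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        tots = [ranks[np.array(s) == 1].sum()
                for s in itertools.product([0, 1], repeat=6)]
        tots = np.array(tots)
        p_exact = min(1.0, 2 * min((tots <= w_obs).mean(),
                                   (tots >= w_obs).mean()))
        assert p == pytest.approx(p_exact)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_prediction_models(self.mk([0.7, 0.8]), self.mk([0.7]))

    def test_metric_bounds_enforced(self):
        with pytest.raises(ValueError):
            MetricDistribution("m", "AUROC", W, np.array([1.2]))
        with pytest.raises(ValueError):
            MetricDistribution("m", "PE", W, np.array([-0.1]))


@pytest.fixture(scope="module")
def cv_cohort():
    return simulate_joint_cohort(strong_association_params(120, seed=99))


class TestCVHarness:
    def test_cox_only_cv_runs_and_partitions(self, cv_cohort):
        specs = {"landmark": LandmarkCoxSpec(), "static": StaticCoxSpec()}
        d = repeated_kfold_cv(cv_cohort, specs, k=5, repeats=2, seed=11)
        assert len(d) == 2 * 2 * 2
        for dist in d.values():
            assert dist.values.shape == (2,)

    def test_same_seed_same_metrics(self, cv_cohort):
        specs = {"landmark": LandmarkCoxSpec()}
        a = repeated_kfold_cv(cv_cohort, specs, k=5, repeats=2, seed=13)
        b = repeated_kfold_cv(cv_cohort, specs, k=5, repeats=2, seed=13)
        for key in a:
            assert np.array_equal(a[key].values, b[key].values)

    def test_fold_partition_property(self, cv_cohort):
        from ctdyn.evaluation import _stratified_folds
        events = np.array([s.event for s in cv_cohort.subjects])
        rng = np.random.default_rng(0)
        labels = _stratified_folds(events, 5, rng)
        assert labels.size == events.size
        for f in range(5):
            assert (labels == f).sum() >= events.size // 5 - 2
        # stratification: every fold contains events
        for f in range(5):
            assert events[labels == f].sum() >= 1

    def test_comparison_table_grid(self, cv_cohort):
        specs = {"landmark": LandmarkCoxSpec(), "static": StaticCoxSpec()}
        d = repeated_kfold_cv(cv_cohort, specs, k=5, repeats=6, seed=17)
        rows = comparison_table(d, models=("landmark", "static"))
        assert len(rows) == 2 * 2 * 1   # metric x window x one pair
        for r in rows:
            assert 0 <= r["p"] <= 1

    def test_k_below_two_rejected(self, cv_cohort):
        with pytest.raises(ValueError):
            repeated_kfold_cv(cv_cohort, {"landmark": LandmarkCoxSpec()},
                              k=1, repeats=1)


class TestLOOCVHL:
    def test_loocv_with_cox_spec(self, cv_cohort):
        C, p, table = loocv_hosmer_lemeshow(
            cv_cohort, lambda: LandmarkCoxSpec(),
            EvaluationWindow(DEFAULT_LANDMARK, 12 * 30.44), n_groups=3)
        assert C >= 0
        assert 0 <= p <= 1
        assert sum(g["n"] for g in table) > 0
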