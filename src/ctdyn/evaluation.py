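"""Censoring-aware model evaluation: discrimination, calibration, CV harness.

Discrimination uses the pair-based time-dependent AUROC and calibration the
expected quadratic prediction error, both over a window (t, u]; subjects
censored inside the window contribute fractionally through their own
model-based conditional event probability (Rizopoulos-style weighting; an
IPCW alternative is available as a flag).  The cross-validation harness runs
repeated stratified k-fold CV over joint-model / landmark-Cox / static-Cox
predictors and paired Wilcoxon comparisons of the resulting metric
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
from scipy import stats

from . import DAYS_PER_MONTH
from .jointmodel import JointData, fit_joint_model
from .lmm import fit_lmm
from .prediction import (SubjectHistory, conditional_rfs_point,
                         landmark_cox_predict, static_cox_predict)
from .splines import NaturalCubicBasis
from .survival import km_estimate, signed_rank_test

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationWindow", "MetricDistribution", "time_dependent_auroc",
    "prediction_error", "repeated_kfold_cv", "loocv_hosmer_lemeshow",
    "compare_prediction_models", "JointSpec", "LandmarkCoxSpec",
    "StaticCoxSpec", "cv_auroc_for_association", "DEFAULT_WINDOWS",
]


@dataclass(frozen=True)
class EvaluationWindow:
    t: float   # landmark (days)
    u: float   # horizon (days)

    def __post_init__(self):
        if not self.u > self.t >= 0:
            raise ValueError("need u > t >= 0")

    @property
    def delta(self):
        return self.u - self.t


#: landmark 8 months, horizons 12 and 15 months post-surgery
DEFAULT_LANDMARK = 8 * DAYS_PER_MONTH
DEFAULT_WINDOWS = (EvaluationWindow(DEFAULT_LANDMARK, 12 * DAYS_PER_MONTH),
                   EvaluationWindow(DEFAULT_LANDMARK, 15 * DAYS_PER_MONTH))


@dataclass
class MetricDistribution:
    model: str
    metric: str            # "AUROC" or "PE"
    window: EvaluationWindow
    values: np.ndarray     # one entry per CV repeat
    seed: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.metric == "AUROC" and np.any(
                (self.values < 0) | (self.values > 1)):
            raise ValueError("AUROC values outside [0, 1]")
        if self.metric == "PE" and np.any(self.values < 0):
            raise ValueError("PE must be non-negative")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _case_weights(times, events, window, cens_event_prob, ipcw_censoring=None):
    """Per-subject probability of being a case (event inside the window).

    1 for observed in-window events, 0 for subjects known event-free at u,
    model-based conditional event probability for subjects censored inside
    the window (NaN drops the subject).
    """
    t, u = window.t, window.u
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times <= t):
        raise ValueError("all subjects must be at risk at the landmark")
    w = np.full(times.size, np.nan)
    w[(times > u)] = 0.0
    w[(times <= u) & events] = 1.0
    cens_in = (times <= u) & ~events
    if cens_in.any():
        if cens_event_prob is None:
            logger.warning("%d subjects censored in-window dropped "
                           "(no conditional predictions supplied)",
                           int(cens_in.sum()))
        else:
            cep = np.asarray(cens_event_prob, dtype=float)
            w[cens_in] = cep[cens_in]
    return w


def time_dependent_auroc(risk_scores, times, events, window: EvaluationWindow,
                         cens_event_prob=None) -> float:
    """Pair-based time-dependent AUROC over (t, u].

    ``risk_scores``: predicted event probability by u given alive at t
    (any strictly monotone transform gives the same value).
    ``cens_event_prob``: per-subject conditional event probability for
    subjects censored inside the window (their fractional case weight).
    """
    r = np.asarray(risk_scores, dtype=float)
    w = _case_weights(times, events, window, cens_event_prob)
    ok = ~np.isnan(w)
    r, w = r[ok], w[ok]
    if np.all(w == 0) or np.all(w == 1):
        raise ValueError("no comparable case-control pairs")
    gt = (r[:, None] > r[None, :]).astype(float)
    eq = 0.5 * (r[:, None] == r[None, :])
    conc = gt + eq
    np.fill_diagonal(conc, 0.0)
    pair_w = w[:, None] * (1.0 - w)[None, :]
    np.fill_diagonal(pair_w, 0.0)
    denom = pair_w.sum()
    if denom <= 0:
        raise ValueError("no comparable case-control pairs")
    return float((pair_w * conc).sum() / denom)


def prediction_error(surv_probs, times, events, window: EvaluationWindow,
                     cens_surv_prob=None) -> float:
    """Expected quadratic prediction error PE(u|t) over the landmark risk set.

    ``surv_probs``: predicted event-free probability pi(u|t).  Known
    survivors contribute (1-pi)^2, observed events pi^2, and subjects
    censored in-window split between both branches by their own conditional
    event-free probability pi(u|c).
    """
    t, u = window.t, window.u
    pi = np.asarray(surv_probs, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty risk set")
    if np.any(times <= t):
        raise ValueError("all subjects must be at risk at the landmark")
    loss = np.empty(times.size)
    surv = times > u
    ev = (times <= u) & events
    cens = (times <= u) & ~events
    loss[surv] = (1.0 - pi[surv]) ** 2
    loss[ev] = pi[ev] ** 2
    if cens.any():
        if cens_surv_prob is None:
            raise ValueError("conditional predictions required for "
                             "in-window censored subjects")
        ps = np.asarray(cens_surv_prob, dtype=float)[cens]
        loss[cens] = ps * (1.0 - pi[cens]) ** 2 + (1.0 - ps) * pi[cens] ** 2
    return float(loss.mean())


# ---------------------------------------------------------------------------
# model specs for the harness
# ---------------------------------------------------------------------------

def _status_records(series):
    recs = []
    for s in series:
        for day, pos in zip(s.days, s.positive):
            recs.append(SimpleNamespace(patient=s.patient, draw_day=float(day),
                                        positive=bool(pos)))
    return recs


def _last_status_before(series, t):
    """Last observed ctDNA positivity at or before t, None if no sample."""
    out = {}
    for s in series:
        mask = s.days <= t
        if mask.any():
            out[s.patient] = bool(np.asarray(s.positive)[mask][-1])
    return out


def _postsurgical_status(series, window_days=DAYS_PER_MONTH):
    """Status of the latest draw in (0, 1 month] (the postsurgical window)."""
    out = {}
    for s in series:
        mask = (s.days > 0) & (s.days <= window_days)
        if mask.any():
            out[s.patient] = bool(np.asarray(s.positive)[mask][-1])
    return out


class JointSpec:
    """Joint-model predictor for the CV harness."""

    def __init__(self, association="value", gh_nodes=5, n_intervals=5,
                 pred_gh_nodes=7, **fit_kw):
        self.association = association
        self.gh_nodes = gh_nodes
        self.n_intervals = n_intervals
        self.pred_gh_nodes = pred_gh_nodes
        self.fit_kw = fit_kw
        self.name = f"joint[{association}]"

    _lmm_warm = None   # carries the last LMM solution as a warm start

    def fit(self, subjects, series, basis: NaturalCubicBasis, seed=0):
        data = JointData(subjects, series, basis,
                         n_intervals=self.n_intervals)
        lmm = fit_lmm(series, basis, q=data.q, init=self._lmm_warm)
        self._lmm_warm = lmm
        self._fit = fit_joint_model(data, self.association, seed=seed,
                                    gh_nodes=self.gh_nodes, lmm_fit=lmm,
                                    compute_cov=False, **self.fit_kw)
        return self

    def _history(self, subject, ser, upto):
        mask = np.asarray(ser.days) <= upto
        return SubjectHistory(
            patient=subject.patient, tp53_mut=subject.tp53_mut,
            t4_stage=subject.t4_stage, days=np.asarray(ser.days)[mask],
            log_level=np.asarray(ser.log_level)[mask], t=float(upto))

    def predict(self, subjects, series, t, horizons):
        """Event-free probabilities pi(u|t); keys = patients at risk at t."""
        by = {s.patient: s for s in series}
        out = {}
        for subj in subjects:
            if subj.rfs_day <= t:
                continue
            hist = self._history(subj, by[subj.patient], t)
            out[subj.patient] = conditional_rfs_point(
                self._fit, hist, horizons, gh_nodes=self.pred_gh_nodes)
        return out

    def predict_from(self, subject, ser, c, u):
        """pi(u|c) using measurements up to the censoring time c."""
        hist = self._history(subject, ser, c)
        return float(conditional_rfs_point(self._fit, hist, [u],
                                           gh_nodes=self.pred_gh_nodes)[0])


class LandmarkCoxSpec:
    """Landmark Cox predictor: last observed ctDNA status at the landmark."""

    name = "landmark"

    def __init__(self, landmark=DEFAULT_LANDMARK):
        self.landmark = landmark

    def fit(self, subjects, series, basis=None, seed=0):
        status = _last_status_before(series, self.landmark)
        risk = [s for s in subjects if s.rfs_day > self.landmark]
        times = np.array([s.rfs_day for s in risk])
        events = np.array([s.event for s in risk], dtype=bool)
        from .prediction import _cox_status_fit
        self._cox, _ = _cox_status_fit(risk, status, times, events,
                                       self.landmark)
        return self

    def _survival(self, subject, status, from_time, horizons):
        import math as _m
        lp = float(np.dot(self._cox.coef,
                          [float(status), float(subject.tp53_mut),
                           float(subject.t4_stage)]))
        H0 = self._cox.cumhaz_at(np.atleast_1d(horizons)) \
            - self._cox.cumhaz_at(from_time)
        return np.exp(-np.maximum(H0, 0.0) * _m.exp(lp))

    def predict(self, subjects, series, t, horizons):
        status = _last_status_before(series, self.landmark)
        out = {}
        for subj in subjects:
            if subj.rfs_day <= t or subj.patient not in status:
                continue
            out[subj.patient] = self._survival(subj, status[subj.patient],
                                               t, horizons)
        return out

    def predict_from(self, subject, ser, c, u):
        status = _last_status_before([ser], self.landmark).get(
            subject.patient, False)
        return float(self._survival(subject, status, c, [u])[0])


class StaticCoxSpec(LandmarkCoxSpec):
    """Static Cox predictor: fixed postsurgical ctDNA status from baseline."""

    name = "static"

    def fit(self, subjects, series, basis=None, seed=0):
        status = _postsurgical_status(series)
        times = np.array([s.rfs_day for s in subjects])
        events = np.array([s.event for s in subjects], dtype=bool)
        from .prediction import _cox_status_fit
        self._cox, _ = _cox_status_fit(subjects, status, times, events, 0.0)
        return self

    def predict(self, subjects, series, t, horizons):
        status = _postsurgical_status(series)
        out = {}
        for subj in subjects:
            if subj.rfs_day <= t or subj.patient not in status:
                continue
            out[subj.patient] = self._survival(subj, status[subj.patient],
                                               t, horizons)
        return out

    def predict_from(self, subject, ser, c, u):
        status = _postsurgical_status([ser]).get(subject.patient, False)
        return float(self._survival(subject, status, c, [u])[0])


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

def _stratified_folds(events, k, rng, max_redraw=20):
    """Event-stratified fold labels; folds with zero training events redrawn."""
    n = events.size
    for attempt in range(max_redraw):
        labels = np.empty(n, dtype=int)
        for cls in (True, False):
            idx = np.where(events == cls)[0]
            rng.shuffle(idx)
            labels[idx] = np.arange(idx.size) % k
        ok = all((events[labels != f].sum() >= 2) for f in range(k))
        if ok:
            return labels
        logger.warning("fold redraw %d: a training split had <2 events",
                       attempt + 1)
    raise RuntimeError("could not build event-stratified folds")


def repeated_kfold_cv(cohort, specs: dict, windows=DEFAULT_WINDOWS,
                      k: int = 5, repeats: int = 20, seed: int = 0,
                      basis: NaturalCubicBasis = None) -> dict:
    """Repeated stratified k-fold CV of the supplied model specs.

    Per repeat, test-fold predictions are pooled before computing each
    metric (AUROC, PE) per window.  Returns
    {(model, metric, window): MetricDistribution}.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    subjects = cohort.subjects
    series_by = {s.patient: s for s in cohort.series}
    events = np.array([s.event for s in subjects], dtype=bool)
    if basis is None:
        alldays = np.concatenate([s.days for s in cohort.series])
        basis = NaturalCubicBasis.from_times(alldays)
    t_land = windows[0].t
    if any(w.t != t_land for w in windows):
        raise ValueError("all windows must share the landmark")
    horizons = np.array([w.u for w in windows])

    rng = np.random.default_rng(seed)
    values = {(name, metric, w): []
              for name in specs for metric in ("AUROC", "PE") for w in windows}
    spec_objs = {name: (mk() if callable(mk) else mk)
                 for name, mk in specs.items()}
    for rep in range(repeats):
        folds = _stratified_folds(events, k, rng)
        pooled = {name: {} for name in specs}       # patient -> pi vector
        cens_cond = {name: {} for name in specs}    # patient -> pi(u|c) vec
        for f in range(k):
            train_idx = np.where(folds != f)[0]
            test_idx = np.where(folds == f)[0]
            train_subj = [subjects[i] for i in train_idx]
            train_ser = [series_by[s.patient] for s in train_subj]
            test_subj = [subjects[i] for i in test_idx]
            test_ser = [series_by[s.patient] for s in test_subj]
            for name in specs:
                spec = spec_objs[name]
                spec.fit(train_subj, train_ser, basis,
                         seed=seed * 1000 + rep * k + f)
                preds = spec.predict(test_subj, test_ser, t_land, horizons)
                pooled[name].update(preds)
                # conditional predictions for in-window censored subjects
                for subj in test_subj:
                    if (subj.patient in preds and not subj.event
                            and t_land < subj.rfs_day <= horizons.max()):
                        # pi(u|c) only for windows whose horizon lies beyond c
                        cens_cond[name][subj.patient] = np.array([
                            spec.predict_from(subj, series_by[subj.patient],
                                              subj.rfs_day, w.u)
                            if w.u > subj.rfs_day else np.nan
                            for w in windows])
        # common patient set across models keeps comparisons paired
        common = set.intersection(*(set(pooled[name]) for name in specs))
        pids = sorted(common)
        times = np.array([next(s.rfs_day for s in subjects
                               if s.patient == p) for p in pids])
        evs = np.array([next(s.event for s in subjects
                             if s.patient == p) for p in pids])
        for name in specs:
            for j, w in enumerate(windows):
                pi = np.array([pooled[name][p][j] for p in pids])
                cep = np.array([1.0 - cens_cond[name].get(p, [np.nan] *
                                                          len(windows))[j]
                                for p in pids])
                auroc = time_dependent_auroc(1.0 - pi, times, evs, w,
                                             cens_event_prob=cep)
                pe = prediction_error(pi, times, evs, w,
                                      cens_surv_prob=1.0 - cep)
                values[(name, "AUROC", w)].append(auroc)
                values[(name, "PE", w)].append(pe)
    return {key: MetricDistribution(model=key[0], metric=key[1],
                                    window=key[2], values=np.array(vals),
                                    seed=seed)
            for key, vals in values.items()}


def compare_prediction_models(dist_a: MetricDistribution,
                              dist_b: MetricDistribution):
    """Paired two-sided Wilcoxon signed-rank test over CV repeats."""
    if dist_a.values.size != dist_b.values.size:
        raise ValueError("paired metric vectors must have equal length")
    _, p = signed_rank_test(dist_a.values - dist_b.values)
    return float(np.median(dist_a.values) - np.median(dist_b.values)), p


def comparison_table(dists: dict, models=("joint", "landmark", "static")):
    """All pairwise model comparisons per metric and window (Fig.-4b style)."""
    rows = []
    windows = sorted({k[2] for k in dists}, key=lambda w: w.u)
    for metric in ("AUROC", "PE"):
        for w in windows:
            for i in range(len(models)):
                for j in range(i + 1, len(models)):
                    a = dists[(models[i], metric, w)]
                    b = dists[(models[j], metric, w)]
                    diff, p = compare_prediction_models(a, b)
                    rows.append({"metric": metric, "u_days": w.u,
                                 "model_a": models[i], "model_b": models[j],
                                 "median_diff": diff, "p": p})
    return rows


# ---------------------------------------------------------------------------
# LOOCV calibration (Hosmer-Lemeshow with KM-observed probabilities)
# ---------------------------------------------------------------------------

def hosmer_lemeshow(pred_event, times, events, window: EvaluationWindow,
                    n_groups: int = 5):
    """H-L C-statistic on a landmark risk set with KM-observed event rates.

    Groups of near-equal size by predicted event probability; observed group
    probability is 1 - KM survival at u (KM on the group's follow-up beyond
    the landmark).  Groups where KM is undefined at u are merged rightward.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    pred_event = np.asarray(pred_event, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    order = np.argsort(pred_event, kind="stable")
    group_idx = np.array_split(order, n_groups)

    merged = []
    pending = None
    for g in group_idx:
        if pending is not None:
            g = np.concatenate([pending, g])
            pending = None
        tg, eg = times[g], events[g]
        km = km_estimate(tg, eg) if eg.any() else None
        well_defined = (tg > window.u).any() or (
            km is not None and km.survival_at(window.u) == 0)
        if not well_defined and km is None:
            pending = g
            continue
        merged.append(g)
    if pending is not None:
        if not merged:
            raise ValueError("calibration groups undefined at the horizon")
        logger.warning("merging trailing H-L group with its neighbor")
        merged[-1] = np.concatenate([merged[-1], pending])

    C = 0.0
    table = []
    for g in merged:
        tg, eg = times[g], events[g]
        expected = float(pred_event[g].mean())
        if eg.any():
            km = km_estimate(tg, eg)
            observed = float(1.0 - km.survival_at(window.u))
        else:
            observed = 0.0
        e = min(max(expected, 1e-10), 1 - 1e-10)
        C += (observed - expected) ** 2 * g.size / (e * (1 - e))
        table.append({"n": int(g.size), "expected": expected,
                      "observed": observed})
    df = max(len(merged) - 2, 1)
    return float(C), float(stats.chi2.sf(C, df)), table


def loocv_hosmer_lemeshow(cohort, spec_factory, window: EvaluationWindow,
                          n_groups: int = 5,
                          basis: NaturalCubicBasis = None):
    """Leave-one-out predictions + Hosmer-Lemeshow calibration test."""
    subjects = cohort.subjects
    series_by = {s.patient: s for s in cohort.series}
    if basis is None:
        alldays = np.concatenate([s.days for s in cohort.series])
        basis = NaturalCubicBasis.from_times(alldays)
    risk = [s for s in subjects if s.rfs_day > window.t]
    preds, times, events = [], [], []
    for held in risk:
        train = [s for s in subjects if s.patient != held.patient]
        train_ser = [series_by[s.patient] for s in train]
        spec = spec_factory() if callable(spec_factory) else spec_factory
        spec.fit(train, train_ser, basis)
        out = spec.predict([held], [series_by[held.patient]], window.t,
                           [window.u])
        if held.patient not in out:
            continue
        preds.append(1.0 - float(out[held.patient][0]))
        times.append(held.rfs_day)
        events.append(held.event)
    C, p, table = hosmer_lemeshow(np.array(preds), np.array(times),
                                  np.array(events), window, n_groups)
    return C, p, table


def cv_auroc_for_association(data: JointData, association: str, seed: int = 0,
                             repeats: int = 1, k: int = 5,
                             windows=DEFAULT_WINDOWS):
    """Mean CV AUROC of a joint-model association (used for model ranking)."""
    cohort = SimpleNamespace(subjects=data.subjects, series=data.series)
    dists = repeated_kfold_cv(
        cohort, {"joint": lambda: JointSpec(association)}, windows=windows,
        k=k, repeats=repeats, seed=seed, basis=data.basis)
    return float(np.mean([np.mean(dists[("joint", "AUROC", w)].values)
                          for w in windows]))
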