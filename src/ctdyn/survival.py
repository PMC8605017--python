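"""Survival statistics: Kaplan-Meier, log-rank, Cox PH, landmark status, lead time.

All estimators are implemented from first principles (the partial likelihood
is maximized by Newton-Raphson with Efron tie handling by default) so that
they can be cross-checked against brute-force oracles and, optionally,
external packages.  Times are in days from surgery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import DAYS_PER_MONTH

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord", "KMCurve", "CoxFit", "km_estimate", "logrank_test",
    "cox_fit", "cox_score_test", "classify_landmark_status",
    "lead_time_analysis", "signed_rank_test",
]


@dataclass
class SubjectRecord:
    """Baseline covariates and follow-up for one subject (t=0 at surgery)."""
    patient: str
    tp53_mut: bool
    t4_stage: bool
    stage: str = ""
    act_received: bool = False
    act_start_day: float = float("nan")
    act_end_day: float = float("nan")
    rfs_day: float = float("nan")
    event: bool = False

    def __post_init__(self):
        if not math.isnan(self.rfs_day) and self.rfs_day <= 0:
            raise ValueError(f"rfs_day must be positive, got {self.rfs_day}")
        if (not math.isnan(self.act_start_day)
                and not math.isnan(self.act_end_day)
                and self.act_end_day < self.act_start_day):
            raise ValueError("act_end_day precedes act_start_day")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    times: np.ndarray       # distinct event times
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray    # Greenwood variance of S(t)

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t); S=1 before the first event."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            s = np.ones_like(t)
            return s if s.ndim else float(s)
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return s if s.ndim else float(s)


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator with Greenwood variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, start = np.unique(t, return_index=True)
    n = times.size
    at_risk = n - start
    d = np.add.reduceat(e.astype(int), start)
    keep = d > 0
    uniq, at_risk, d = uniq[keep], at_risk[keep], d[keep]
    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    safe = at_risk > d
    gw_terms = np.where(safe, d / (at_risk * np.where(safe, at_risk - d, 1)), 0.0)
    var = surv ** 2 * np.cumsum(gw_terms)  # Greenwood; 0 once S hits 0
    return KMCurve(times=uniq, survival=surv, at_risk=at_risk, n_events=d,
                   variance=var)


def logrank_test(groups):
    """k-sample log-rank test.

    ``groups`` is a list of (times, events) pairs.  Returns (chi2, p) with
    k-1 degrees of freedom.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        if t.size == 0:
            raise ValueError(f"group {g} is empty")
        times.append(t)
        events.append(np.asarray(e, dtype=bool))
        labels.append(np.full(t.size, g))
    t = np.concatenate(times)
    e = np.concatenate(events)
    g = np.concatenate(labels)
    if not e.any():
        raise ValueError("no events in any group")
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in np.unique(t[e]):
        at_risk = t >= u
        n = at_risk.sum()
        ng = np.bincount(g[at_risk], minlength=k)
        dg = np.bincount(g[at_risk & e & (t == u)], minlength=k)
        d = dg.sum()
        O += dg
        E += d * ng / n
        if n > 1:
            p = ng / n
            V += d * (n - d) / (n - 1) * (np.diag(p) - np.outer(p, p))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    return stat, float(stats.chi2.sf(stat, k - 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n_events: int
    names: list = field(default_factory=list)
    ties: str = "efron"
    separation_flag: bool = False
    baseline_times: np.ndarray = None    # distinct event times
    baseline_cumhaz: np.ndarray = None   # Breslow H0 at those times

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def hr_ci(self, level: float = 0.95):
        z = stats.norm.ppf(0.5 + level / 2)
        return np.exp(self.coef - z * self.se), np.exp(self.coef + z * self.se)

    @property
    def wald_p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2 * stats.norm.sf(np.abs(z))

    @property
    def lr_p(self) -> float:
        lr = 2 * (self.loglik - self.loglik_null)
        return float(stats.chi2.sf(lr, self.coef.size))

    def cumhaz_at(self, t):
        """Breslow baseline cumulative hazard H0(t), step function."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        h = np.where(idx >= 0, self.baseline_cumhaz[np.maximum(idx, 0)], 0.0)
        return h if h.ndim else float(h)


def _cox_quantities(beta, X, t_sorted, e_sorted, ties):
    """Log partial likelihood, gradient and Hessian (data pre-sorted by time)."""
    n, p = X.shape
    lp = X @ beta
    elp = np.exp(lp)
    # suffix sums over the risk set
    c0 = np.cumsum(elp[::-1])[::-1]
    c1 = np.cumsum((X * elp[:, None])[::-1], axis=0)[::-1]
    xxe = X[:, :, None] * X[:, None, :] * elp[:, None, None]
    c2 = np.cumsum(xxe[::-1], axis=0)[::-1]

    uniq, start = np.unique(t_sorted, return_index=True)
    end = np.append(start[1:], n)
    ll = float(lp[e_sorted].sum())
    grad = X[e_sorted].sum(axis=0).astype(float)
    hess = np.zeros((p, p))
    for s, eidx in zip(start, end):
        d_mask = e_sorted[s:eidx]
        d = int(d_mask.sum())
        if d == 0:
            continue
        R0, R1, R2 = c0[s], c1[s], c2[s]
        if ties == "breslow" or d == 1:
            fracs = np.zeros(d)
        else:
            fracs = np.arange(d) / d
        De = elp[s:eidx][d_mask]
        Dx = X[s:eidx][d_mask]
        S0 = De.sum()
        S1 = (Dx * De[:, None]).sum(axis=0)
        S2 = (Dx[:, :, None] * Dx[:, None, :] * De[:, None, None]).sum(axis=0)
        for f in fracs:
            a0 = R0 - f * S0
            a1 = R1 - f * S1
            a2 = R2 - f * S2
            ll -= math.log(a0)
            m = a1 / a0
            grad -= m
            hess -= a2 / a0 - np.outer(m, m)
    return ll, grad, hess


def cox_fit(covariates, times, events, ties: str = "efron",
            names=None, max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson maximum partial likelihood estimate.

    Raises on non-convergence; flags monotone likelihood (separation) when a
    coefficient runs away.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n, p = X.shape
    if events.sum() < p:
        raise ValueError("fewer events than covariates")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    order = np.argsort(times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]

    beta = np.zeros(p)
    ll_null, _, _ = _cox_quantities(beta, Xs, ts, es, ties)
    ll_old = ll_null
    separation = False
    for it in range(max_iter):
        ll, grad, hess = _cox_quantities(beta, Xs, ts, es, ties)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular information matrix at iter {it}") from exc
        # step-halving safeguard
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            ll_new, _, _ = _cox_quantities(cand, Xs, ts, es, ties)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.any(np.abs(beta) > 15):
            separation = True
            logger.warning("possible monotone partial likelihood (separation)")
            break
        if abs(ll_new - ll_old) < tol and np.max(np.abs(grad)) < 1e-6:
            break
        ll_old = ll_new
    else:
        raise RuntimeError(
            f"Cox Newton-Raphson failed to converge in {max_iter} iterations "
            f"(|grad|={np.max(np.abs(grad)):.2e})")
    ll, grad, hess = _cox_quantities(beta, Xs, ts, es, ties)
    cov = np.linalg.inv(-hess)

    # Breslow baseline cumulative hazard
    elp = np.exp(Xs @ beta)
    c0 = np.cumsum(elp[::-1])[::-1]
    uniq, start = np.unique(ts, return_index=True)
    end = np.append(start[1:], n)
    bt, bh = [], []
    H = 0.0
    for u, s, eidx in zip(uniq, start, end):
        d = int(es[s:eidx].sum())
        if d == 0:
            continue
        H += d / c0[s]
        bt.append(u)
        bh.append(H)
    return CoxFit(coef=beta, cov=cov, loglik=ll, loglik_null=ll_null,
                  n_events=int(events.sum()),
                  names=list(names) if names else [f"x{j}" for j in range(p)],
                  ties=ties, separation_flag=separation,
                  baseline_times=np.array(bt), baseline_cumhaz=np.array(bh))


def cox_score_test(covariates, times, events):
    """Score test at beta=0 with Breslow ties (equals the log-rank test for
    a single binary group indicator)."""
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    order = np.argsort(times, kind="stable")
    _, grad, hess = _cox_quantities(
        np.zeros(X.shape[1]), X[order], times[order], events[order], "breslow")
    stat = float(grad @ np.linalg.solve(-hess, grad))
    return stat, float(stats.chi2.sf(stat, X.shape[1]))


# ---------------------------------------------------------------------------
# landmark ctDNA status
# ---------------------------------------------------------------------------

def classify_landmark_status(subjects, results, *,
                             postsurgical_window_days: float = DAYS_PER_MONTH,
                             post_act_window_days: float = 4 * DAYS_PER_MONTH,
                             postsurgical_rule: str = "latest") -> dict:
    """Per-subject postsurgical / post-ACT / longitudinal ctDNA status.

    ``results`` carry ``patient``, ``draw_day`` and ``positive`` attributes
    (PlasmaCallResult or equivalent).  Samples drawn after the recurrence
    date are excluded.  A missing window yields ``None`` for that status.

    postsurgical_rule: "latest" uses the last in-window pre-ACT sample
    (closest to the treatment decision); "any_positive" calls positive if any
    in-window sample is positive.
    """
    if postsurgical_rule not in ("latest", "any_positive"):
        raise ValueError("postsurgical_rule must be 'latest' or 'any_positive'")
    by_patient: dict = {}
    for r in results:
        by_patient.setdefault(r.patient, []).append(r)
    out = {}
    for s in subjects:
        samples = sorted(by_patient.get(s.patient, []), key=lambda r: r.draw_day)
        usable = []
        for r in samples:
            if s.event and r.draw_day > s.rfs_day:
                logger.warning("sample for %s at day %.0f is after recurrence; "
                               "excluded", s.patient, r.draw_day)
                continue
            if getattr(r, "unevaluable", False):
                continue
            usable.append(r)

        act_start = s.act_start_day if s.act_received else float("inf")
        if math.isnan(act_start):
            act_start = float("inf")
        in_ps = [r for r in usable
                 if 0 < r.draw_day <= postsurgical_window_days
                 and r.draw_day < act_start]
        if not in_ps:
            postsurgical = None
        elif postsurgical_rule == "latest":
            postsurgical = bool(in_ps[-1].positive)
        else:
            postsurgical = any(r.positive for r in in_ps)

        post_act = None
        if s.act_received and not math.isnan(s.act_end_day):
            in_pa = [r for r in usable
                     if s.act_end_day < r.draw_day
                     <= s.act_end_day + post_act_window_days]
            if in_pa:
                post_act = bool(in_pa[-1].positive)

        longitudinal = any(r.positive for r in usable) if usable else None
        out[s.patient] = {"postsurgical": postsurgical, "post_act": post_act,
                          "longitudinal": longitudinal}
    return out


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank and lead time
# ---------------------------------------------------------------------------

def signed_rank_test(diffs, exact_max_n: int = 25):
    """Two-sided one-sample Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (Wilcoxon's rule).  For n <= ``exact_max_n`` the exact
    null distribution is computed by dynamic programming over doubled
    midranks (ties handled exactly); larger samples use the normal
    approximation with tie correction.  Returns (W_plus, p).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if m <= exact_max_n:
        # DP over 2*ranks (integers even with midranks)
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:-r]
            counts = counts + shifted
        counts /= counts.sum()
        w2 = int(round(2 * w_plus))
        lo = counts[: w2 + 1].sum()
        hi = counts[w2:].sum()
        p = min(1.0, 2 * min(lo, hi))
        return w_plus, float(p)
    mean = m * (m + 1) / 4
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = m * (m + 1) * (2 * m + 1) / 24 - (tie_counts ** 3 - tie_counts).sum() / 48
    z = (w_plus - mean) / math.sqrt(var)
    return w_plus, float(2 * stats.norm.sf(abs(z)))


def lead_time_analysis(pairs):
    """Median lead time (recurrence minus first ctDNA-positive day) and
    two-sided signed-rank p.

    ``pairs`` is a sequence of (first_positive_day, recurrence_day).
    """
    if len(pairs) == 0:
        raise ValueError("no pairs")
    first_pos = np.array([p[0] for p in pairs], dtype=float)
    recur = np.array([p[1] for p in pairs], dtype=float)
    leads = recur - first_pos
    _, p = signed_rank_test(leads)
    return float(np.median(leads)), float(p)
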