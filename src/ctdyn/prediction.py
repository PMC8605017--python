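"""Individualized conditional recurrence-free probabilities.

pi(u | t) = P(T >= u | T > t, measurements up to t, covariates) under a
fitted joint model, computed by Monte Carlo over the random-effects
posterior (and, optionally, parameter draws), with percentile uncertainty
bands.  Landmark-Cox and static-Cox comparator predictors are provided for
the model-comparison layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .jointmodel import JointModelFit, model_cum_hazard
from .lmm import trajectory_design
from .survival import cox_fit

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectHistory", "PredictionSet", "predict_conditional_rfs",
    "update_prediction", "conditional_rfs_point", "landmark_cox_predict",
    "static_cox_predict", "CoxPrediction",
]


@dataclass
class SubjectHistory:
    """Measurements and covariates of one event-free subject up to time t."""
    patient: str
    tp53_mut: bool
    t4_stage: bool
    days: np.ndarray
    log_level: np.ndarray
    t: float             # conditioning time (days); subject event-free at t

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.log_level = np.asarray(self.log_level, dtype=float)
        if self.days.size and self.t < self.days.max():
            raise ValueError("conditioning time precedes last measurement")

    @property
    def w(self):
        return np.array([self.tp53_mut, self.t4_stage], dtype=float)

    def extended(self, new_days, new_levels) -> "SubjectHistory":
        new_days = np.atleast_1d(np.asarray(new_days, dtype=float))
        new_levels = np.atleast_1d(np.asarray(new_levels, dtype=float))
        if new_days.size == 0:
            return self
        if new_days.min() <= self.t:
            raise ValueError("new measurements must be later than current t")
        if np.any(np.diff(new_days) <= 0):
            raise ValueError("new measurement times must be increasing")
        return SubjectHistory(
            patient=self.patient, tp53_mut=self.tp53_mut,
            t4_stage=self.t4_stage,
            days=np.concatenate([self.days, new_days]),
            log_level=np.concatenate([self.log_level, new_levels]),
            t=float(new_days.max()))


@dataclass
class PredictionSet:
    patient: str
    t: float
    horizons: np.ndarray
    median: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_draws: int
    seed: int
    draws: np.ndarray = field(default=None, repr=False)


def _posterior_b_logpdf(fit: JointModelFit, hist: SubjectHistory):
    """Return f(b) = log p(y | b) + log S(t | b) + log phi_D(b) and pieces."""
    p = fit.params
    beta, D, sigma = p["beta"], p["D"], p["sigma"]
    q = fit.layout.q
    Dinv = np.linalg.inv(D)
    _, logdetD = np.linalg.slogdet(D)
    X = trajectory_design(fit.basis, hist.days)
    Z = X[:, :q]
    r0 = hist.log_level - X @ beta

    def logpdf(b, theta=None):
        b = np.asarray(b, dtype=float)
        single = b.ndim == 1
        B = np.atleast_2d(b)
        r = r0[None, :] - B @ Z.T
        ll = -0.5 * (r ** 2).sum(axis=1) / sigma ** 2
        ll = ll - model_cum_hazard(fit, hist.w, B, hist.t, theta=theta)
        quad = np.einsum("ni,ij,nj->n", B, Dinv, B)
        ll = ll - 0.5 * (quad + logdetD)
        return float(ll[0]) if single else ll

    return logpdf


def _posterior_mode(fit, hist):
    logpdf = _posterior_b_logpdf(fit, hist)
    q = fit.layout.q
    res = optimize.minimize(lambda b: -logpdf(b), np.zeros(q),
                            method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8})
    mode = res.x
    # numeric Hessian for the proposal covariance
    h = 1e-4
    H = np.zeros((q, q))
    for j in range(q):
        e = np.zeros(q); e[j] = h
        for k in range(q):
            f = np.zeros(q); f[k] = h
            H[j, k] = (logpdf(mode + e + f) - logpdf(mode + e - f)
                       - logpdf(mode - e + f) + logpdf(mode - e - f)) / (4 * h * h)
    try:
        cov = np.linalg.inv(-H)
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = np.eye(q) * 0.5
    return mode, cov, logpdf


def predict_conditional_rfs(fit: JointModelFit, history: SubjectHistory,
                            horizons, n_draws: int = 500, burn: int = 200,
                            seed: int = 0, param_uncertainty: bool = True,
                            proposal_scale: float = 1.5) -> PredictionSet:
    """Monte-Carlo conditional recurrence-free probabilities.

    Random effects are sampled by an independence Metropolis-Hastings chain
    (Gaussian proposal at the conditional mode); parameter uncertainty is
    propagated by pairing each kept draw with a draw from the fit's
    covariance (map_ml) or posterior draws (mcmc).  pi(t|t) = 1 exactly.
    """
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if np.any(horizons < history.t):
        raise ValueError("horizons must be at or after the conditioning time")
    if history.days.size == 0:
        logger.warning("subject %s has no measurements; covariate-only "
                       "prediction", history.patient)
    rng = np.random.default_rng(seed)
    mode, cov, logpdf = _posterior_mode(fit, history)
    Lp = np.linalg.cholesky(cov * proposal_scale)
    q = fit.layout.q

    def propose():
        return mode + Lp @ rng.standard_normal(q)

    def prop_logq(b):
        z = np.linalg.solve(Lp, b - mode)
        return -0.5 * z @ z

    # parameter draws
    if param_uncertainty and fit.draws is not None:
        idx = rng.integers(fit.draws.shape[0], size=n_draws)
        thetas = fit.draws[idx]
    elif param_uncertainty and fit.cov is not None:
        Lt = np.linalg.cholesky(fit.cov + 1e-12 * np.eye(fit.layout.size))
        thetas = fit.theta[None, :] + \
            rng.standard_normal((n_draws, fit.layout.size)) @ Lt.T
    else:
        thetas = None

    b = mode.copy()
    lp_b = logpdf(b)
    # burn-in at the point estimate
    for _ in range(burn):
        cand = propose()
        lp_c = logpdf(cand)
        if math.log(rng.random()) < (lp_c - lp_b) - (prop_logq(cand)
                                                     - prop_logq(b)):
            b, lp_b = cand, lp_c

    pis = np.empty((n_draws, horizons.size))
    for l in range(n_draws):
        theta_l = thetas[l] if thetas is not None else None
        cand = propose()
        lp_c = logpdf(cand, theta=theta_l)
        lp_cur = logpdf(b, theta=theta_l)
        if math.log(rng.random()) < (lp_c - lp_cur) - (prop_logq(cand)
                                                       - prop_logq(b)):
            b = cand
        Ht = model_cum_hazard(fit, history.w, b[None, :], history.t,
                              theta=theta_l)[0]
        Hu = model_cum_hazard(fit, history.w,
                              np.repeat(b[None, :], horizons.size, axis=0),
                              horizons, theta=theta_l)
        pis[l] = np.exp(-(np.maximum(Hu - Ht, 0.0)))
    pis[:, horizons == history.t] = 1.0

    med = np.median(pis, axis=0)
    lo = np.quantile(pis, 0.025, axis=0)
    hi = np.quantile(pis, 0.975, axis=0)
    return PredictionSet(patient=history.patient, t=history.t,
                         horizons=horizons, median=med, lo=lo, hi=hi,
                         n_draws=n_draws, seed=seed, draws=pis)


def update_prediction(fit: JointModelFit, history: SubjectHistory,
                      new_days, new_levels, horizons, **kw) -> PredictionSet:
    """Advance the conditioning time with newly arrived measurements."""
    extended = history.extended(new_days, new_levels)
    return predict_conditional_rfs(fit, extended, horizons, **kw)


def conditional_rfs_point(fit: JointModelFit, history: SubjectHistory,
                          horizons, gh_nodes: int = 9) -> np.ndarray:
    """Deterministic point estimate of pi(u|t) via adaptive Gauss-Hermite.

    pi(u|t) = Integral exp(l_y + log phi) S(u|b) db /
              Integral exp(l_y + log phi) S(t|b) db,
    with nodes centered at the conditional mode.  Used by the CV harness
    where Monte-Carlo bands are unnecessary.
    """
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if np.any(horizons < history.t):
        raise ValueError("horizons must be at or after the conditioning time")
    mode, cov, _ = _posterior_mode(fit, history)
    q = fit.layout.q
    x, wgh = special.roots_hermite(gh_nodes)
    grids = np.meshgrid(*([x] * q), indexing="ij")
    S = np.stack([g.ravel() for g in grids], axis=-1)
    wg = np.meshgrid(*([wgh] * q), indexing="ij")
    Wg = np.prod(np.stack([g.ravel() for g in wg], axis=-1), axis=-1)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(q))
    B = mode[None, :] + math.sqrt(2.0) * S @ L.T            # (K, q)
    logW = np.log(Wg) + (S ** 2).sum(axis=1)

    p = fit.params
    beta, D, sigma = p["beta"], p["D"], p["sigma"]
    Dinv = np.linalg.inv(D)
    _, logdetD = np.linalg.slogdet(D)
    X = trajectory_design(fit.basis, history.days)
    Z = X[:, :q]
    r = (history.log_level - X @ beta)[None, :] - B @ Z.T
    ll_y = -0.5 * (r ** 2).sum(axis=1) / sigma ** 2
    ll_b = -0.5 * (np.einsum("ni,ij,nj->n", B, Dinv, B) + logdetD)
    base = logW + ll_y + ll_b

    Ht = model_cum_hazard(fit, history.w, B, history.t)
    denom = special.logsumexp(base - Ht)
    out = np.empty(horizons.size)
    for j, u in enumerate(horizons):
        if u == history.t:
            out[j] = 1.0
            continue
        Hu = model_cum_hazard(fit, history.w, B, u)
        Hu = np.maximum(Hu, Ht)   # monotone guard against quadrature noise
        out[j] = math.exp(special.logsumexp(base - Hu) - denom)
    return out


# ---------------------------------------------------------------------------
# Cox comparators
# ---------------------------------------------------------------------------

@dataclass
class CoxPrediction:
    fit: object               # CoxFit
    landmark: float
    names: list

    def conditional_survival(self, status, tp53, t4, from_time, horizons):
        """exp(-(H0(u) - H0(s)) e^lp) for one subject."""
        horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
        lp = float(np.dot(self.fit.coef,
                          np.array([status, tp53, t4], dtype=float)))
        H0s = self.fit.cumhaz_at(from_time)
        H0u = self.fit.cumhaz_at(horizons)
        return np.exp(-np.maximum(H0u - H0s, 0.0) * math.exp(lp))


def _cox_status_fit(subjects, status_map, times, events, landmark):
    rows, use = [], []
    for i, s in enumerate(subjects):
        st = status_map.get(s.patient)
        if st is None:
            continue
        rows.append([float(st), float(s.tp53_mut), float(s.t4_stage)])
        use.append(i)
    if not rows:
        raise ValueError("no subjects with available ctDNA status")
    X = np.array(rows)
    t = times[use]
    e = events[use]
    if not e.any():
        raise ValueError("no events after the landmark")
    fit = cox_fit(X, t, e, names=["ctdna", "tp53", "t4"])
    return fit, use


def landmark_cox_predict(subjects, status_at_landmark: dict, landmark: float,
                         horizons):
    """Landmark Cox comparator: last-observed ctDNA status at the landmark.

    Risk set = subjects event-free and uncensored at the landmark.  Returns
    (CoxPrediction, {patient: conditional event-free probs at horizons}).
    """
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    risk = [s for s in subjects if s.rfs_day > landmark]
    if not risk:
        raise ValueError("empty landmark risk set")
    times = np.array([s.rfs_day for s in risk])
    events = np.array([s.event for s in risk], dtype=bool)
    fit, use = _cox_status_fit(risk, status_at_landmark, times, events,
                               landmark)
    pred = CoxPrediction(fit=fit, landmark=landmark,
                         names=["ctdna", "tp53", "t4"])
    out = {}
    for i in use:
        s = risk[i]
        out[s.patient] = pred.conditional_survival(
            status_at_landmark[s.patient], s.tp53_mut, s.t4_stage,
            landmark, horizons)
    return pred, out


def static_cox_predict(subjects, postsurgical_status: dict, landmark: float,
                       horizons):
    """Static Cox comparator: fixed postsurgical ctDNA status from t=0.

    Fit uses all subjects with an available postsurgical status and full
    follow-up from surgery; predictions condition on survival to the
    landmark.  Status never updates with later measurements.
    """
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    times = np.array([s.rfs_day for s in subjects])
    events = np.array([s.event for s in subjects], dtype=bool)
    fit, use = _cox_status_fit(subjects, postsurgical_status, times, events,
                               0.0)
    pred = CoxPrediction(fit=fit, landmark=landmark,
                         names=["ctdna", "tp53", "t4"])
    out = {}
    for i in use:
        s = subjects[i]
        if s.rfs_day <= landmark:
            continue   # not in the landmark risk set
        out[s.patient] = pred.conditional_survival(
            postsurgical_status[s.patient], s.tp53_mut, s.t4_stage,
            landmark, horizons)
    return pred, out
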