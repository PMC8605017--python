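"""Joint model of longitudinal log-ctDNA level and time to recurrence.

Longitudinal sub-model: natural-cubic-spline LMM (see :mod:`ctdyn.lmm`).
Survival sub-model: proportional hazards with piecewise-constant baseline,
baseline covariates (TP53 status, T stage) and one of three association
structures linking the latent trajectory eta_i(t) to the hazard:

    value        h0(t) exp{g1 TP53 + g2 T4 + a1 eta(t)}
    value+slope  ... + a2 eta'(t)
    value+auc    ... + a3 Integral_0^t eta(s) ds

Random effects are integrated out with pseudo-adaptive Gauss-Hermite
quadrature (nodes centered at each subject's LMM empirical-Bayes mode), the
hazard integral with fixed Gauss-Legendre rules per baseline interval.  The
marginal log-likelihood carries an analytic gradient, so the ``map_ml``
engine is a plain quasi-Newton maximization with observed-information
covariance; the ``mcmc`` engine runs blockwise random-walk Metropolis on the
same marginal likelihood under weakly-informative priors.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .lmm import LongitudinalSubmodel, fit_lmm, trajectory_design
from .splines import NaturalCubicBasis
from .survival import cox_fit

logger = logging.getLogger(__name__)

__all__ = [
    "ASSOCIATIONS", "JointData", "JointModelFit", "joint_log_likelihood",
    "fit_joint_model", "compare_association_structures", "model_cum_hazard",
]

ASSOCIATIONS = ("value", "value+slope", "value+auc")

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)

#: internal rescaling of the cumulative-effect (AUC) covariate, in days;
#: keeps the working alpha parameter O(1) so quasi-Newton steps are sane.
#: Reported alpha3 is always on the per-day scale.
AUC_SCALE = 100.0


def _alpha_mask(association):
    """(use_value, use_slope, use_auc) flags."""
    if association == "value":
        return (True, False, False)
    if association == "value+slope":
        return (True, True, False)
    if association == "value+auc":
        return (True, False, True)
    raise ValueError(f"association must be one of {ASSOCIATIONS}")


# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------

@dataclass
class ParamLayout:
    p: int              # fixed-effect dimension (1 + df)
    q: int              # random-effect dimension
    n_gamma: int
    n_alpha: int
    n_rates: int

    @property
    def n_chol(self):
        return self.q * (self.q + 1) // 2

    @property
    def size(self):
        return self.p + self.n_chol + 1 + self.n_gamma + self.n_alpha + self.n_rates

    def split(self, theta):
        i = 0
        beta = theta[i:i + self.p]; i += self.p
        chol = theta[i:i + self.n_chol]; i += self.n_chol
        log_sigma = theta[i]; i += 1
        gamma = theta[i:i + self.n_gamma]; i += self.n_gamma
        alpha = theta[i:i + self.n_alpha]; i += self.n_alpha
        log_rates = theta[i:i + self.n_rates]
        return beta, chol, log_sigma, gamma, alpha, log_rates

    def join(self, beta, chol, log_sigma, gamma, alpha, log_rates):
        return np.concatenate([beta, chol, [log_sigma], gamma, alpha, log_rates])

    def chol_to_L(self, chol):
        L = np.zeros((self.q, self.q))
        L[np.tril_indices(self.q)] = chol
        d = np.diag_indices(self.q)
        L[d] = np.exp(L[d])
        return L

    def L_to_chol(self, L):
        M = L.copy()
        d = np.diag_indices(self.q)
        M[d] = np.log(np.maximum(M[d], 1e-8))
        return M[np.tril_indices(self.q)]


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

def _baseline_edges_from_events(times, events, n_intervals):
    """Piecewise-constant baseline cut points at event-time quantiles."""
    et = np.sort(np.asarray(times)[np.asarray(events, dtype=bool)])
    if et.size == 0:
        raise ValueError("no events: cannot place baseline intervals")
    probs = np.linspace(0, 1, n_intervals + 1)[1:-1]
    cuts = np.unique(np.quantile(et, probs))
    return np.concatenate([[0.0], cuts, [np.inf]])


class JointData:
    """Pre-computed design arrays for the joint likelihood.

    Measurements at or after the observed event/censoring time are excluded
    from the longitudinal part.
    """

    def __init__(self, subjects, series, basis: NaturalCubicBasis,
                 n_intervals: int = 5, q: int = 2, edges=None,
                 gl_points: int = 7):
        order = {s.patient: s for s in series}
        self.subjects = list(subjects)
        self.series = [order[s.patient] for s in subjects]
        self.basis = basis
        self.q = q
        n = len(subjects)
        self.n = n

        self.T = np.array([s.rfs_day for s in subjects])
        self.delta = np.array([s.event for s in subjects], dtype=bool)
        self.W = np.array([[s.tp53_mut, s.t4_stage] for s in subjects],
                          dtype=float)
        if edges is None:
            edges = _baseline_edges_from_events(self.T, self.delta, n_intervals)
        self.edges = np.asarray(edges, dtype=float)
        self.n_rates = self.edges.size - 1

        # longitudinal arrays, padded
        ys, ts = [], []
        for ser, subj in zip(self.series, subjects):
            keep = np.asarray(ser.days) < subj.rfs_day
            ys.append(np.asarray(ser.log_level)[keep])
            ts.append(np.asarray(ser.days)[keep])
        m = max(len(y) for y in ys)
        self.Y = np.zeros((n, m))
        self.mask = np.zeros((n, m))
        self.Xl = np.zeros((n, m) + (1 + basis.df,))
        for i, (y, t) in enumerate(zip(ys, ts)):
            self.Y[i, :len(y)] = y
            self.mask[i, :len(y)] = 1.0
            self.Xl[i, :len(y)] = trajectory_design(basis, t)
        self.Zl = self.Xl[..., :q]
        self.n_obs = self.mask.sum()

        # survival quadrature grid (Gauss-Legendre per clipped interval)
        gl_x, gl_w = np.polynomial.legendre.leggauss(gl_points)
        lo = np.minimum(self.edges[None, :-1], self.T[:, None])
        hi = np.minimum(self.edges[None, 1:], self.T[:, None])
        half = 0.5 * (hi - lo)
        mid = 0.5 * (hi + lo)
        sq = mid[..., None] + half[..., None] * gl_x        # (n, K, G)
        self.omega = (half[..., None] * gl_w).reshape(n, -1)  # (n, Q)
        rate_idx = np.repeat(np.arange(self.n_rates), gl_points)
        self.rate_onehot = np.eye(self.n_rates)[rate_idx]   # (Q, K) shared
        sqf = sq.reshape(n, -1)
        self.Xq = trajectory_design(basis, sqf)
        self.XqD = trajectory_design(basis, sqf, "derivative")
        self.XqA = trajectory_design(basis, sqf, "integral") / AUC_SCALE
        self.Zq, self.ZqD, self.ZqA = (A[..., :q] for A in
                                       (self.Xq, self.XqD, self.XqA))
        self.xT = trajectory_design(basis, self.T)
        self.xTD = trajectory_design(basis, self.T, "derivative")
        self.xTA = trajectory_design(basis, self.T, "integral") / AUC_SCALE
        self.zT, self.zTD, self.zTA = (A[..., :q] for A in
                                       (self.xT, self.xTD, self.xTA))
        self.idxT = np.clip(np.searchsorted(self.edges, self.T, side="right")
                            - 1, 0, self.n_rates - 1)
        self.onehotT = np.eye(self.n_rates)[self.idxT]

    @classmethod
    def from_cohort(cls, cohort, basis=None, **kw):
        if basis is None:
            alldays = np.concatenate([s.days for s in cohort.series])
            basis = NaturalCubicBasis.from_times(alldays)
        return cls(cohort.subjects, cohort.series, basis, **kw)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class JointLikelihood:
    """Marginal joint log-likelihood with analytic gradient.

    Pseudo-adaptive Gauss-Hermite: node locations/weights are fixed at the
    LMM empirical-Bayes posteriors, so the likelihood is a smooth
    deterministic function of the parameters.
    """

    def __init__(self, data: JointData, association: str,
                 centers, scales, gh_nodes: int = 9):
        self.data = data
        self.association = association
        self.use_v, self.use_s, self.use_a = _alpha_mask(association)
        n_alpha = 1 + (self.use_s or self.use_a)
        self.layout = ParamLayout(p=1 + data.basis.df, q=data.q,
                                  n_gamma=2, n_alpha=n_alpha,
                                  n_rates=data.n_rates)
        x, w = special.roots_hermite(gh_nodes)
        q = data.q
        grids = np.meshgrid(*([x] * q), indexing="ij")
        S = np.stack([g.ravel() for g in grids], axis=-1)       # (K, q)
        wg = np.meshgrid(*([w] * q), indexing="ij")
        Wg = np.prod(np.stack([g.ravel() for g in wg], axis=-1), axis=-1)
        # prune numerically negligible corner nodes
        keep = Wg > Wg.max() * 1e-10
        S, Wg = S[keep], Wg[keep]
        n = data.n
        L_i = np.linalg.cholesky(scales + 1e-10 * np.eye(q))
        self.b_nodes = centers[:, None, :] + math.sqrt(2.0) * np.einsum(
            "nij,kj->nki", L_i, S)                               # (n, K, q)
        logdet = np.log(np.diagonal(L_i, axis1=1, axis2=2)).sum(axis=1)
        self.logW = (0.5 * q * math.log(2.0) + logdet[:, None]
                     + np.log(Wg)[None, :] + (S ** 2).sum(axis=1)[None, :])
        self.K = S.shape[0]
        d = data
        # node-dependent design contractions (parameter-independent)
        self.Zb_l = np.einsum("nmq,nkq->nkm", d.Zl, self.b_nodes)
        self.etaV_b = np.einsum("nQq,nkq->nkQ", d.Zq, self.b_nodes)
        self.etaT_b = np.einsum("nq,nkq->nk", d.zT, self.b_nodes)
        if self.use_s:
            self.etaD_b = np.einsum("nQq,nkq->nkQ", d.ZqD, self.b_nodes)
            self.etaTD_b = np.einsum("nq,nkq->nk", d.zTD, self.b_nodes)
        if self.use_a:
            self.etaA_b = np.einsum("nQq,nkq->nkQ", d.ZqA, self.b_nodes)
            self.etaTA_b = np.einsum("nq,nkq->nk", d.zTA, self.b_nodes)

    # -- pieces ------------------------------------------------------------

    def _alphas(self, alpha):
        a1 = alpha[0]
        a2 = alpha[1] if self.use_s else 0.0
        a3 = alpha[1] if self.use_a else 0.0
        return a1, a2, a3

    def _node_loglik(self, theta):
        """Per-node complete-data log-likelihood (n, K) plus reusable pieces."""
        d = self.data
        lay = self.layout
        beta, chol, log_sigma, gamma, alpha, log_rates = lay.split(theta)
        a1, a2, a3 = self._alphas(alpha)
        sigma2 = math.exp(2 * log_sigma)
        L = lay.chol_to_L(chol)
        D = L @ L.T
        Dinv = np.linalg.inv(D)
        _, logdetD = np.linalg.slogdet(D)

        # longitudinal
        r0 = (d.Y - d.Xl @ beta) * d.mask                       # (n, m)
        r = r0[:, None, :] - self.Zb_l * d.mask[:, None, :]     # (n, K, m)
        ssq = np.einsum("nkm,nkm->nk", r, r)
        ni = d.mask.sum(axis=1)
        ll_y = -0.5 * ssq / sigma2 - 0.5 * ni[:, None] * (
            math.log(2 * math.pi) + 2 * log_sigma)

        # survival linear predictor at quadrature points
        w_lin = d.W @ gamma                                      # (n,)
        etaV_fix = d.Xq @ beta                                   # (n, Q)
        lp = a1 * (etaV_fix[:, None, :] + self.etaV_b)
        if self.use_s:
            lp = lp + a2 * ((d.XqD @ beta)[:, None, :] + self.etaD_b)
        if self.use_a:
            lp = lp + a3 * ((d.XqA @ beta)[:, None, :] + self.etaA_b)
        rates_q = d.rate_onehot @ np.exp(log_rates)              # (Q,)
        with np.errstate(over="ignore", invalid="ignore"):
            E = (d.omega * rates_q[None, :])[:, None, :] * np.exp(
                lp + w_lin[:, None, None])                       # (n, K, Q)
        H = E.sum(axis=2)                                        # (n, K)

        etaT = (d.xT @ beta)[:, None] + self.etaT_b              # (n, K)
        lpT = a1 * etaT
        if self.use_s:
            lpT = lpT + a2 * ((d.xTD @ beta)[:, None] + self.etaTD_b)
        if self.use_a:
            lpT = lpT + a3 * ((d.xTA @ beta)[:, None] + self.etaTA_b)
        log_hT = (log_rates[d.idxT] + w_lin)[:, None] + lpT
        ll_t = d.delta[:, None] * log_hT - H

        # random-effects density
        u = np.einsum("ij,nkj->nki", Dinv, self.b_nodes)
        quad = np.einsum("nki,nki->nk", self.b_nodes, u)
        ll_b = -0.5 * (lay.q * math.log(2 * math.pi) + logdetD + quad)

        return (ll_y + ll_t + ll_b), dict(
            r=r, ssq=ssq, ni=ni, sigma2=sigma2, E=E, H=H, lp=lp, u=u,
            Dinv=Dinv, L=L, a=(a1, a2, a3), beta=beta, w_lin=w_lin,
            etaV_fix=etaV_fix, etaT=etaT)

    def value(self, theta) -> float:
        ll_nk, _ = self._node_loglik(theta)
        return float(special.logsumexp(self.logW + ll_nk, axis=1).sum())

    def value_grad(self, theta):
        d = self.data
        lay = self.layout
        ll_nk, c = self._node_loglik(theta)
        a1, a2, a3 = c["a"]
        logpost = self.logW + ll_nk
        ll_i = special.logsumexp(logpost, axis=1)
        P = np.exp(logpost - ll_i[:, None])                      # (n, K)

        grad = np.zeros(lay.size)
        i0 = 0
        # beta
        g_beta_y = np.einsum("nkm,nmp->nkp", c["r"], d.Xl) / c["sigma2"]
        XhT = a1 * d.xT
        Xhq = a1 * d.Xq
        if self.use_s:
            XhT = XhT + a2 * d.xTD
            Xhq = Xhq + a2 * d.XqD
        if self.use_a:
            XhT = XhT + a3 * d.xTA
            Xhq = Xhq + a3 * d.XqA
        g_beta_t = (d.delta[:, None, None] * XhT[:, None, :]
                    - np.einsum("nkQ,nQp->nkp", c["E"], Xhq))
        grad[i0:i0 + lay.p] = np.einsum("nk,nkp->p", P, g_beta_y + g_beta_t)
        i0 += lay.p
        # chol(D)
        u = c["u"]                                               # (n,K,q)
        gD = 0.5 * (np.einsum("nki,nkj->nkij", u, u)
                    - c["Dinv"][None, None])                     # d ll_b / dD
        gL = 2.0 * np.einsum("nk,nkij->ij", P, gD) @ c["L"]
        dd = np.diag_indices(lay.q)
        gL[dd] *= np.diag(c["L"])  # log-diagonal chain rule
        grad[i0:i0 + lay.n_chol] = gL[np.tril_indices(lay.q)]
        i0 += lay.n_chol
        # log sigma
        grad[i0] = float((P * (c["ssq"] / c["sigma2"]
                               - c["ni"][:, None])).sum())
        i0 += 1
        # gamma
        dH = d.delta[:, None] - c["H"]
        grad[i0:i0 + lay.n_gamma] = np.einsum("nk,nk,nj->j", P, dH, d.W)
        i0 += lay.n_gamma
        # alpha
        etaT_full = c["etaT"]
        etaq_full = c["etaV_fix"][:, None, :] + self.etaV_b
        g_a1 = (d.delta[:, None] * etaT_full
                - np.einsum("nkQ,nkQ->nk", c["E"], etaq_full))
        grad[i0] = float((P * g_a1).sum())
        if self.use_s:
            etaTD = (d.xTD @ c["beta"])[:, None] + self.etaTD_b
            etaqD = (d.XqD @ c["beta"])[:, None, :] + self.etaD_b
            g_a2 = (d.delta[:, None] * etaTD
                    - np.einsum("nkQ,nkQ->nk", c["E"], etaqD))
            grad[i0 + 1] = float((P * g_a2).sum())
        if self.use_a:
            etaTA = (d.xTA @ c["beta"])[:, None] + self.etaTA_b
            etaqA = (d.XqA @ c["beta"])[:, None, :] + self.etaA_b
            g_a3 = (d.delta[:, None] * etaTA
                    - np.einsum("nkQ,nkQ->nk", c["E"], etaqA))
            grad[i0 + 1] = float((P * g_a3).sum())
        i0 += lay.n_alpha
        # log rates
        g_rates = (np.einsum("nk,n,nj->j", P, d.delta.astype(float), d.onehotT)
                   - np.einsum("nk,nkQ,Qj->j", P, c["E"], d.rate_onehot))
        grad[i0:i0 + lay.n_rates] = g_rates

        return float(ll_i.sum()), grad


def joint_log_likelihood(theta, data: JointData, association: str,
                         centers=None, scales=None, gh_nodes: int = 9,
                         lmm: LongitudinalSubmodel = None) -> float:
    """Marginal joint log-likelihood at packed parameter vector ``theta``.

    ``centers``/``scales`` (or an ``lmm`` fit providing them) define the
    pseudo-adaptive quadrature; defaults re-fit the LMM.
    """
    if centers is None or scales is None:
        if lmm is None:
            lmm = fit_lmm(data.series, data.basis, q=data.q)
        centers, scales = lmm.b_modes, lmm.b_covs
    lik = JointLikelihood(data, association, centers, scales, gh_nodes)
    val = lik.value(np.asarray(theta, dtype=float))
    if not np.isfinite(val):
        bad = np.where(~np.isfinite(
            special.logsumexp(lik.logW + lik._node_loglik(theta)[0], axis=1)))[0]
        pid = data.subjects[bad[0]].patient if bad.size else "?"
        raise FloatingPointError(f"non-finite likelihood (subject {pid})")
    return val


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class JointModelFit:
    association: str
    theta: np.ndarray
    cov: np.ndarray
    loglik: float
    layout: ParamLayout
    basis: NaturalCubicBasis
    edges: np.ndarray
    lmm: LongitudinalSubmodel
    engine: str
    converged: bool
    n_iter: int
    seed: int = 0
    draws: np.ndarray = None          # posterior draws (mcmc engine)
    rhat: dict = field(default_factory=dict)

    @property
    def params(self) -> dict:
        beta, chol, log_sigma, gamma, alpha, log_rates = \
            self.layout.split(self.theta)
        L = self.layout.chol_to_L(chol)
        out = {"beta": beta, "D": L @ L.T, "sigma": math.exp(log_sigma),
               "gamma": gamma, "rates": np.exp(log_rates)}
        use_v, use_s, use_a = _alpha_mask(self.association)
        out["alpha1"] = alpha[0]
        out["alpha2"] = alpha[1] if use_s else 0.0
        # working AUC coefficient is per AUC_SCALE days; report per day
        out["alpha3"] = alpha[1] / AUC_SCALE if use_a else 0.0
        return out

    def param_index(self, name: str) -> int:
        lay = self.layout
        base = {"beta": 0, "chol": lay.p, "log_sigma": lay.p + lay.n_chol,
                "gamma": lay.p + lay.n_chol + 1,
                "alpha": lay.p + lay.n_chol + 1 + lay.n_gamma,
                "log_rates": lay.p + lay.n_chol + 1 + lay.n_gamma + lay.n_alpha}
        if name in base:
            return base[name]
        if name == "gamma1":
            return base["gamma"]
        if name == "gamma2":
            return base["gamma"] + 1
        if name == "alpha1":
            return base["alpha"]
        if name in ("alpha2", "alpha3"):
            return base["alpha"] + 1
        raise KeyError(name)

    def ci(self, name: str, level: float = 0.95):
        """Wald (map_ml) or posterior-quantile (mcmc) interval.

        alpha3 intervals are returned on the per-day scale.
        """
        j = self.param_index(name)
        scale = 1.0 / AUC_SCALE if name == "alpha3" else 1.0
        if self.draws is not None:
            lo, hi = np.quantile(self.draws[:, j],
                                 [0.5 - level / 2, 0.5 + level / 2])
            return float(lo * scale), float(hi * scale)
        se = math.sqrt(max(self.cov[j, j], 0.0))
        z = stats.norm.ppf(0.5 + level / 2)
        return (float((self.theta[j] - z * se) * scale),
                float((self.theta[j] + z * se) * scale))

    def to_json(self, path):
        obj = {
            "association": self.association,
            "theta": self.theta.tolist(),
            "cov": self.cov.tolist() if self.cov is not None else None,
            "loglik": self.loglik,
            "basis": self.basis.to_dict(),
            "edges": [e if math.isfinite(e) else None for e in self.edges],
            "engine": self.engine,
            "seed": self.seed,
            "layout": {"p": self.layout.p, "q": self.layout.q,
                       "n_gamma": self.layout.n_gamma,
                       "n_alpha": self.layout.n_alpha,
                       "n_rates": self.layout.n_rates},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path, lmm=None):
        with open(path) as fh:
            obj = json.load(fh)
        lay = ParamLayout(**obj["layout"])
        edges = np.array([math.inf if e is None else e for e in obj["edges"]])
        return cls(association=obj["association"],
                   theta=np.asarray(obj["theta"]),
                   cov=None if obj["cov"] is None else np.asarray(obj["cov"]),
                   loglik=obj["loglik"], layout=lay,
                   basis=NaturalCubicBasis.from_dict(obj["basis"]),
                   edges=edges, lmm=lmm, engine=obj["engine"],
                   converged=True, n_iter=0, seed=obj["seed"])


def _init_theta(data, lik, lmm_fit):
    """Two-stage starting values: LMM + baseline-covariate Cox."""
    lay = lik.layout
    beta0 = lmm_fit.beta
    chol0 = lay.L_to_chol(np.linalg.cholesky(
        lmm_fit.D + 1e-8 * np.eye(lay.q)))
    try:
        cfit = cox_fit(data.W, data.T, data.delta)
        gamma0 = np.clip(cfit.coef, -3, 3)
    except Exception:   # e.g. constant covariate in a small fold
        gamma0 = np.zeros(2)
    alpha0 = np.full(lay.n_alpha, 0.0)
    alpha0[0] = 0.1
    # crude piecewise-exponential baseline from exposure
    rates0 = np.zeros(lay.n_rates)
    for k in range(lay.n_rates):
        lo, hi = data.edges[k], data.edges[k + 1]
        exposure = np.clip(data.T - lo, 0, hi - lo).sum()
        d_k = np.sum(data.delta & (data.T > lo) & (data.T <= hi))
        rates0[k] = max(d_k, 0.5) / max(exposure, 1.0)
    return lay.join(beta0, chol0, math.log(max(lmm_fit.sigma, 1e-3)),
                    gamma0, alpha0, np.log(rates0))


def _numeric_hessian(grad_fn, theta, rel_step=1e-5):
    n = theta.size
    H = np.zeros((n, n))
    for j in range(n):
        h = rel_step * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        H[:, j] = (grad_fn(tp)[1] - grad_fn(tm)[1]) / (2 * h)
    return 0.5 * (H + H.T)


def fit_joint_model(data: JointData, association: str = "value+auc",
                    engine: str = "map_ml", seed: int = 0,
                    gh_nodes: int = 9, lmm_fit: LongitudinalSubmodel = None,
                    theta0=None, compute_cov: bool = True,
                    mcmc_draws: int = 1000, mcmc_burn: int = 500,
                    maxiter: int = 400) -> JointModelFit:
    """Fit the joint model.

    engine "map_ml": L-BFGS maximization of the marginal likelihood with
    analytic gradient; covariance from the observed information.
    engine "mcmc": blockwise random-walk Metropolis around the ML solution
    with weakly-informative priors (normal on coefficients, half-t-like via
    the log-scale transforms); returns posterior draws.
    """
    if lmm_fit is None:
        lmm_fit = fit_lmm(data.series, data.basis, q=data.q)
    lik = JointLikelihood(data, association, lmm_fit.b_modes, lmm_fit.b_covs,
                          gh_nodes)
    if theta0 is None:
        theta0 = _init_theta(data, lik, lmm_fit)

    def nll_grad(theta):
        v, g = lik.value_grad(theta)
        return -v, -g

    res = optimize.minimize(nll_grad, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-11,
                                     "gtol": 1e-6})
    if not res.success and np.max(np.abs(res.jac)) > 1e-2:
        raise RuntimeError(
            f"joint model did not converge: {res.message} "
            f"(|grad|={np.max(np.abs(res.jac)):.2e})")
    theta = res.x
    cov = None
    if compute_cov:
        H = _numeric_hessian(lik.value_grad, theta)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-H)
        dcov = np.diag(cov)
        if np.any(dcov < 0):
            logger.warning("observed information not PD; clipping variances")
            cov = cov.copy()
            np.fill_diagonal(cov, np.maximum(dcov, 1e-10))

    fit = JointModelFit(association=association, theta=theta, cov=cov,
                        loglik=float(-res.fun), layout=lik.layout,
                        basis=data.basis, edges=data.edges, lmm=lmm_fit,
                        engine="map_ml", converged=bool(res.success),
                        n_iter=int(res.nit), seed=seed)
    if engine == "map_ml":
        return fit
    if engine != "mcmc":
        raise ValueError("engine must be 'map_ml' or 'mcmc'")
    return _run_mcmc(lik, fit, seed, mcmc_draws, mcmc_burn)


def _log_prior(theta, lay: ParamLayout):
    beta, chol, log_sigma, gamma, alpha, log_rates = lay.split(theta)
    lp = 0.0
    # N(0, 10^2) on location-type parameters
    for v in (beta, gamma, alpha):
        lp += float(stats.norm.logpdf(v, 0, 10).sum())
    # half-t(3, 2.5) on sigma and random-effect SDs (log-scale Jacobian)
    sigma = math.exp(log_sigma)
    lp += float(stats.t.logpdf(sigma / 2.5, df=3)) + log_sigma
    L = lay.chol_to_L(chol)
    for j in range(lay.q):
        lp += float(stats.t.logpdf(L[j, j] / 2.5, df=3)) + math.log(L[j, j])
    off = chol[np.tril_indices(lay.q)[0] != np.tril_indices(lay.q)[1]]
    lp += float(stats.norm.logpdf(off, 0, 2).sum())
    lp += float(stats.norm.logpdf(log_rates, -8.0, 3.0).sum())
    return lp


def _split_rhat(x):
    """Split-R-hat of a single chain (Gelman et al.)."""
    n = x.size // 2
    chains = np.stack([x[:n], x[n:2 * n]])
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    return math.sqrt((n - 1) / n + B / (n * W))


def _run_mcmc(lik, fit, seed, n_draws, n_burn):
    rng = np.random.default_rng(seed)
    lay = lik.layout
    theta = fit.theta.copy()
    cov = fit.cov if fit.cov is not None else np.eye(lay.size) * 1e-3
    # two blocks: longitudinal vs survival parameters
    idx_long = np.arange(lay.p + lay.n_chol + 1)
    idx_surv = np.arange(lay.p + lay.n_chol + 1, lay.size)
    blocks = []
    for idx in (idx_long, idx_surv):
        C = cov[np.ix_(idx, idx)] + 1e-10 * np.eye(idx.size)
        blocks.append((idx, np.linalg.cholesky(
            C * (2.4 ** 2 / idx.size))))

    def logpost(th):
        return lik.value(th) + _log_prior(th, lay)

    lp = logpost(theta)
    draws = np.empty((n_draws, lay.size))
    accept = np.zeros(len(blocks))
    scale = np.ones(len(blocks))
    total = n_burn + n_draws
    for it in range(total):
        for jb, (idx, C) in enumerate(blocks):
            prop = theta.copy()
            prop[idx] = theta[idx] + scale[jb] * (C @ rng.standard_normal(idx.size))
            lp_prop = logpost(prop)
            if math.log(rng.random()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                accept[jb] += 1
        if it < n_burn and (it + 1) % 100 == 0:
            rate = accept / (it + 1)
            scale *= np.where(rate < 0.15, 0.7, np.where(rate > 0.45, 1.4, 1.0))
        if it >= n_burn:
            draws[it - n_burn] = theta

    rhat = {}
    for name in ("alpha1", "gamma1", "gamma2", "log_sigma"):
        j = fit.param_index(name)
        rhat[name] = _split_rhat(draws[:, j])
    if max(rhat.values()) > 1.1:
        logger.warning("MCMC split-R-hat > 1.1: %s", rhat)
    med = np.median(draws, axis=0)
    return JointModelFit(association=fit.association, theta=med,
                         cov=np.cov(draws.T), loglik=fit.loglik,
                         layout=lay, basis=fit.basis, edges=fit.edges,
                         lmm=fit.lmm, engine="mcmc", converged=True,
                         n_iter=n_draws, seed=seed, draws=draws, rhat=rhat)


# ---------------------------------------------------------------------------
# model-implied cumulative hazard (shared with prediction)
# ---------------------------------------------------------------------------

def model_cum_hazard(fit: JointModelFit, w, b, t, theta=None):
    """H_i(t | b) under fitted parameters, vectorized over draws.

    ``w``: (2,) baseline covariates; ``b``: (..., q) random effects;
    ``t``: scalar or array broadcastable against b's leading shape.
    """
    lay = fit.layout
    beta, chol, _, gamma, alpha, log_rates = lay.split(
        fit.theta if theta is None else theta)
    use_v, use_s, use_a = _alpha_mask(fit.association)
    a1 = alpha[0]
    a2 = alpha[1] if use_s else 0.0
    a3 = alpha[1] / AUC_SCALE if use_a else 0.0
    rates = np.exp(log_rates)
    edges = fit.edges
    b = np.atleast_2d(np.asarray(b, dtype=float))
    t = np.asarray(t, dtype=float)
    tb = np.broadcast_to(t, b.shape[:-1]).astype(float)

    lo = np.minimum(edges[:-1], tb[..., None])
    hi = np.minimum(edges[1:], tb[..., None])
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    s = mid[..., None] + half[..., None] * _GL_NODES        # (..., K, G)
    X = trajectory_design(fit.basis, s)
    lp = a1 * (X @ beta + np.einsum("...kgq,...q->...kg", X[..., :lay.q], b))
    if use_s:
        Xd = trajectory_design(fit.basis, s, "derivative")
        lp = lp + a2 * (Xd @ beta
                        + np.einsum("...kgq,...q->...kg", Xd[..., :lay.q], b))
    if use_a:
        Xa = trajectory_design(fit.basis, s, "integral")
        lp = lp + a3 * (Xa @ beta
                        + np.einsum("...kgq,...q->...kg", Xa[..., :lay.q], b))
    w_lin = float(np.dot(np.asarray(w, dtype=float), gamma))
    seg = half * np.einsum("g,...kg->...k", _GL_WEIGHTS, np.exp(lp + w_lin))
    return (seg * rates).sum(axis=-1)


# ---------------------------------------------------------------------------
# association-structure comparison
# ---------------------------------------------------------------------------

def compare_association_structures(data: JointData, candidates=ASSOCIATIONS,
                                   criterion: str = "aic", seed: int = 0,
                                   cv_kwargs: dict = None):
    """Fit each candidate association and rank by the chosen criterion.

    criterion "aic"/"bic"/"loglik" rank on in-sample fit; "cv_auroc" defers
    to the cross-validation harness in :mod:`ctdyn.evaluation` (mean AUROC
    over windows, higher better).  Failed candidates are reported but do not
    abort the ranking.
    """
    lmm_fit = fit_lmm(data.series, data.basis, q=data.q)
    results, failures = {}, {}
    for assoc in candidates:
        try:
            fit = fit_joint_model(data, assoc, lmm_fit=lmm_fit,
                                  compute_cov=False, seed=seed)
        except Exception as exc:      # ranking proceeds over survivors
            logger.warning("candidate %s failed: %s", assoc, exc)
            failures[assoc] = str(exc)
            continue
        k = fit.layout.size
        n = data.n
        score = {"aic": -(2 * fit.loglik - 2 * k),
                 "bic": -(2 * fit.loglik - k * math.log(n)),
                 "loglik": -fit.loglik}.get(criterion)
        if score is None and criterion == "cv_auroc":
            from .evaluation import cv_auroc_for_association
            score = -cv_auroc_for_association(data, assoc, seed=seed,
                                              **(cv_kwargs or {}))
        elif score is None:
            raise ValueError(f"unknown criterion {criterion!r}")
        results[assoc] = (score, fit)
    ranked = sorted(results, key=lambda a: results[a][0])
    return [(a, results[a][0], results[a][1]) for a in ranked], failures
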