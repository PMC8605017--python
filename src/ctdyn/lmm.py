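"""Linear mixed model for the longitudinal log-ctDNA trajectory.

The subject trajectory is eta_i(t) = x(t)'beta + z(t)'b_i with
x(t) = [1, B(t)] (natural cubic spline basis B) and z(t) the first q columns
of x(t); b_i ~ N(0, D), residuals i.i.d. N(0, sigma^2).  Maximum likelihood
with beta profiled out by GLS; empirical Bayes modes and conditional
covariances are exposed because the joint model uses them as pseudo-adaptive
quadrature centers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .splines import NaturalCubicBasis

logger = logging.getLogger(__name__)

__all__ = ["LongitudinalSubmodel", "fit_lmm", "lmm_marginal_loglik",
           "trajectory_design"]


def trajectory_design(basis: NaturalCubicBasis, t, kind: str = "value"):
    """Fixed-effect design [1, B(t)] (or its derivative / running integral)."""
    t = np.asarray(t, dtype=float)
    if kind == "value":
        lead = np.ones(t.shape + (1,))
        cols = basis.design(t)
    elif kind == "derivative":
        lead = np.zeros(t.shape + (1,))
        cols = basis.derivative(t)
    elif kind == "integral":
        lead = t[..., None]
        cols = basis.antiderivative(t)
    else:
        raise ValueError(f"unknown design kind {kind!r}")
    return np.concatenate([lead, cols], axis=-1)


@dataclass
class LongitudinalSubmodel:
    beta: np.ndarray
    D: np.ndarray
    sigma: float
    basis: NaturalCubicBasis
    patients: list
    b_modes: np.ndarray        # (n, q) empirical Bayes estimates
    b_covs: np.ndarray         # (n, q, q) conditional covariances
    loglik: float

    @property
    def q(self) -> int:
        return self.D.shape[0]

    def eta(self, patient_index: int, t):
        X = trajectory_design(self.basis, t)
        q = self.q
        return X @ self.beta + X[..., :q] @ self.b_modes[patient_index]


def _pack_chol(q):
    idx = np.tril_indices(q)
    m = idx[0].size

    def unpack(theta):
        L = np.zeros((q, q))
        L[idx] = theta
        L[np.diag_indices(q)] = np.exp(np.diag(L))
        return L

    def pack(L):
        M = L.copy()
        M[np.diag_indices(q)] = np.log(np.diag(L))
        return M[idx]

    return m, pack, unpack


def _group_by_length(ys, Xs, Zs):
    groups: dict = {}
    for i, (y, X, Z) in enumerate(zip(ys, Xs, Zs)):
        groups.setdefault(len(y), []).append((i, y, X, Z))
    out = []
    for m, items in groups.items():
        idx = [it[0] for it in items]
        Y = np.stack([it[1] for it in items])
        Xg = np.stack([it[2] for it in items])
        Zg = np.stack([it[3] for it in items])
        out.append((np.array(idx), Y, Xg, Zg))
    return out


def lmm_marginal_loglik(ys, Xs, Zs, beta, D, sigma):
    """Exact Gaussian marginal log-likelihood (random effects integrated out)."""
    ll = 0.0
    for y, X, Z in zip(ys, Xs, Zs):
        V = sigma ** 2 * np.eye(len(y)) + Z @ D @ Z.T
        r = y - X @ beta
        sign, logdet = np.linalg.slogdet(V)
        ll += -0.5 * (len(y) * math.log(2 * math.pi) + logdet
                      + r @ np.linalg.solve(V, r))
    return float(ll)


def fit_lmm(series, basis: NaturalCubicBasis, q: int = 2,
            ridge: float = 1e-8, init: "LongitudinalSubmodel" = None
            ) -> LongitudinalSubmodel:
    """ML fit of the spline LMM; beta profiled out by GLS.

    ``series`` are LongitudinalSeries-like objects with ``days`` and
    ``log_level``.  ``q`` random effects use the leading design columns
    (intercept + q-1 spline columns).
    """
    patients = [s.patient for s in series]
    ys = [np.asarray(s.log_level, dtype=float) for s in series]
    Xs = [trajectory_design(basis, s.days) for s in series]
    Zs = [X[:, :q] for X in Xs]
    p = Xs[0].shape[1]
    n_multi = sum(len(y) >= 2 for y in ys)
    if n_multi < max(2, len(ys) // 10):
        raise ValueError("too few subjects with repeated measurements")
    groups = _group_by_length(ys, Xs, Zs)

    m_chol, pack, unpack = _pack_chol(q)

    def profiled(theta):
        L = unpack(theta[:m_chol])
        D = L @ L.T
        # floor keeps V invertible when sigma collapses (noise-free data)
        sigma2 = math.exp(2 * theta[m_chol]) + 1e-10
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        pieces = []
        for idx, Y, Xg, Zg in groups:
            m = Y.shape[1]
            V = sigma2 * np.eye(m) + Zg @ D @ np.swapaxes(Zg, 1, 2)
            Vi = np.linalg.inv(V)
            sign, logdet = np.linalg.slogdet(V)
            XtVX += np.einsum("gmp,gmn,gnr->pr", Xg, Vi, Xg)
            XtVy += np.einsum("gmp,gmn,gn->p", Xg, Vi, Y)
            pieces.append((idx, Y, Xg, Zg, Vi, logdet, m))
        beta = np.linalg.solve(XtVX + ridge * np.eye(p), XtVy)
        ll = 0.0
        for idx, Y, Xg, Zg, Vi, logdet, m in pieces:
            R = Y - Xg @ beta
            quad = np.einsum("gm,gmn,gn->g", R, Vi, R)
            ll += float(np.sum(-0.5 * (m * math.log(2 * math.pi) + logdet + quad)))
        return -ll, beta

    def objective(theta):
        return profiled(theta)[0]

    if init is not None:
        L0 = np.linalg.cholesky(init.D + 1e-8 * np.eye(q))
        theta0 = np.concatenate([pack(L0), [math.log(max(init.sigma, 1e-3))]])
    else:
        theta0 = np.concatenate([pack(0.5 * np.eye(q)), [math.log(0.5)]])
    res = optimize.minimize(objective, theta0, method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 500})
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        res = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-9,
                                         "maxiter": 2000})
    theta = res.x
    L = unpack(theta[:m_chol])
    D = L @ L.T
    if np.linalg.cond(D) > 1e10:
        logger.warning("near-singular D; ridge-stabilizing")
        D = D + 1e-6 * np.trace(D) / q * np.eye(q)
    sigma = math.exp(theta[m_chol])
    nll, beta = profiled(theta)

    # empirical Bayes modes and conditional covariances
    n = len(ys)
    b_modes = np.zeros((n, q))
    b_covs = np.zeros((n, q, q))
    Dinv = np.linalg.inv(D + ridge * np.eye(q))
    for i, (y, X, Z) in enumerate(zip(ys, Xs, Zs)):
        prec = Z.T @ Z / sigma ** 2 + Dinv
        cov = np.linalg.inv(prec)
        b_modes[i] = cov @ (Z.T @ (y - X @ beta)) / sigma ** 2
        b_covs[i] = cov
    return LongitudinalSubmodel(beta=beta, D=D, sigma=sigma, basis=basis,
                                patients=patients, b_modes=b_modes,
                                b_covs=b_covs, loglik=-nll)
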