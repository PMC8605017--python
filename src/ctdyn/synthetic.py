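"""Synthetic cohorts and read families with the structure the analysis assumes.

The cohort generator is the exact generative inverse of the fitted joint
model: subject trajectories are natural-cubic-spline curves with Gaussian
random effects, and event times are drawn by inverting the cumulative hazard

    h_i(t) = h0(t) * exp{g1*TP53 + g2*T4 + a1*eta(t) + a2*eta'(t) + a3*AUC(t)}

with a piecewise-constant baseline, Gauss-Legendre integration of the
trajectory terms and bisection to 1e-8 days.  Quarterly visits with
independent (MAR) dropout and administrative censoring produce the observed
data; the latent random effects and true event times are retained as truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .splines import NaturalCubicBasis
from .survival import SubjectRecord
from .mrd import ReadFamily, mean_vaf_from_log_level

__all__ = [
    "SimulationParams", "LongitudinalSeries", "SyntheticCohort",
    "simulate_joint_cohort", "piecewise_exp_survival", "cohort_fixture_small",
    "simulate_read_families", "simulate_consensus_counts", "ReadFamilySet",
    "strong_association_params",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)


@dataclass
class SimulationParams:
    """Generative parameters; log-ctDNA units on the longitudinal scale,
    days on the time scale, baseline hazard in events/day."""
    n_subjects: int = 300
    beta: np.ndarray = field(default_factory=lambda: np.array([2.2, -2.4, 0.4]))
    D: np.ndarray = field(default_factory=lambda: np.array([[0.8, 0.1],
                                                            [0.1, 0.9]]))
    sigma: float = 0.35
    gamma1: float = math.log(3.3)   # TP53 mutant log-HR
    gamma2: float = math.log(2.7)   # T4 log-HR
    alpha1: float = 0.8             # current value
    alpha2: float = 0.0             # slope
    alpha3: float = 0.0             # cumulative (per log-ctDNA * day)
    baseline_rates: np.ndarray = field(
        default_factory=lambda: np.array([0.8e-4, 1.6e-4, 1.6e-4, 1.2e-4, 0.8e-4]))
    baseline_cuts: np.ndarray = field(
        default_factory=lambda: np.array([120.0, 240.0, 390.0, 540.0]))
    visit_interval: float = 91.0
    first_visit_day: float = 14.0
    admin_censor: float = 730.0
    dropout_prob: float = 0.03
    tp53_prev: float = 0.4
    t4_prev: float = 0.2
    interior_knots: tuple = (180.0,)
    boundary_knots: tuple = (0.0, 540.0)
    floor_at_zero: bool = True
    seed: int = 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.baseline_rates = np.asarray(self.baseline_rates, dtype=float)
        self.baseline_cuts = np.asarray(self.baseline_cuts, dtype=float)
        if not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric")
        if np.min(np.linalg.eigvalsh(self.D)) < -1e-10:
            raise ValueError("D must be positive semi-definite")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.visit_interval <= 0:
            raise ValueError("visit_interval must be positive")
        if np.any(self.baseline_rates < 0):
            raise ValueError("baseline rates must be non-negative")
        if self.baseline_cuts.size != self.baseline_rates.size - 1:
            raise ValueError("need len(rates) == len(cuts) + 1")
        if self.beta.size != 1 + 1 + len(self.interior_knots):
            raise ValueError("beta must have 1 + df entries")

    @property
    def n_random_effects(self) -> int:
        return self.D.shape[0]

    def basis(self) -> NaturalCubicBasis:
        return NaturalCubicBasis(list(self.interior_knots), self.boundary_knots)


def strong_association_params(n_subjects: int = 200, seed: int = 0,
                              **overrides) -> SimulationParams:
    """Preset with an informative binary ctDNA status and a strong
    value-association, for Fig-4b-style model-comparison experiments.

    Most subjects stay ctDNA-negative (trajectory floored at zero); subjects
    with rising latent trajectories convert to positive and carry most of
    the hazard.  Yields roughly 35% events and ~20% postsurgical positivity.
    """
    base = dict(
        n_subjects=n_subjects, seed=seed,
        beta=np.array([-0.3, 0.5, 1.5]),
        D=np.array([[1.2, 0.3], [0.3, 2.0]]),
        sigma=0.35, alpha1=1.5, alpha2=0.0, alpha3=0.0,
        baseline_rates=np.array([0.75e-4, 1.5e-4, 1.5e-4, 1.1e-4, 0.75e-4]),
        floor_at_zero=True)
    base.update(overrides)
    return SimulationParams(**base)


@dataclass
class LongitudinalSeries:
    """Ordered plasma measurements for one subject."""
    patient: str
    days: np.ndarray
    log_level: np.ndarray
    mean_vaf: np.ndarray
    positive: np.ndarray

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("measurement days must be strictly increasing")


@dataclass
class SyntheticCohort:
    subjects: list
    series: list
    truth: dict     # patient -> {"b": ..., "event_time": ...}
    params: SimulationParams = None

    def subject(self, patient):
        return next(s for s in self.subjects if s.patient == patient)

    def series_for(self, patient):
        return next(s for s in self.series if s.patient == patient)


def piecewise_exp_survival(t, rates, cuts):
    """Closed-form survival of the piecewise-exponential baseline law."""
    t = np.asarray(t, dtype=float)
    edges = np.concatenate([[0.0], np.asarray(cuts, dtype=float), [np.inf]])
    rates = np.asarray(rates, dtype=float)
    H = np.zeros_like(t)
    for k, r in enumerate(rates):
        lo, hi = edges[k], edges[k + 1]
        H += r * np.clip(t - lo, 0.0, hi - lo)
    return np.exp(-H)


def _batch_cum_hazard(params, basis, w_lin, b, t):
    """Cumulative subject-specific hazard H_i(t_i), vectorized over subjects.

    Each baseline interval intersected with [0, t_i] is integrated with
    15-point Gauss-Legendre; the last baseline rate extends beyond the final
    cut.  ``w_lin``: (n,) linear predictor of baseline covariates; ``b``:
    (n, q) random effects; ``t``: (n,) upper limits.
    """
    rates = params.baseline_rates
    edges = np.concatenate([[0.0], params.baseline_cuts, [np.inf]])
    a1, a2, a3 = params.alpha1, params.alpha2, params.alpha3
    beta = params.beta
    q = params.n_random_effects
    t = np.asarray(t, dtype=float)
    n = t.size

    # per-subject clipped interval bounds: (n, K)
    lo = np.minimum(edges[None, :-1], t[:, None])
    hi = np.minimum(edges[None, 1:], t[:, None])
    half = 0.5 * (hi - lo)                       # (n, K)
    mid = 0.5 * (hi + lo)
    s = mid[..., None] + half[..., None] * _GL_NODES      # (n, K, 15)

    X = np.concatenate([np.ones(s.shape + (1,)), basis.design(s)], axis=-1)
    lin = X @ beta + np.einsum("nkgq,nq->nkg", X[..., :q], b)
    total = a1 * lin
    if a2:
        Xd = np.concatenate([np.zeros(s.shape + (1,)), basis.derivative(s)],
                            axis=-1)
        total = total + a2 * (Xd @ beta + np.einsum("nkgq,nq->nkg", Xd[..., :q], b))
    if a3:
        Xa = np.concatenate([s[..., None], basis.antiderivative(s)], axis=-1)
        total = total + a3 * (Xa @ beta + np.einsum("nkgq,nq->nkg", Xa[..., :q], b))
    integrand = np.exp(total + w_lin[:, None, None])
    seg = half * np.einsum("g,nkg->nk", _GL_WEIGHTS, integrand)  # (n, K)
    return (seg * rates[None, :]).sum(axis=1)


def _invert_event_times(params, basis, w_lin, b, targets, t_max, tol=1e-8):
    """Vectorized bisection: solve H_i(t) = target_i on (0, t_max]."""
    n = targets.size
    H_max = _batch_cum_hazard(params, basis, w_lin, b, np.full(n, t_max))
    never = H_max < targets
    lo = np.zeros(n)
    hi = np.full(n, float(t_max))
    n_iter = int(math.ceil(math.log2(t_max / tol))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = _batch_cum_hazard(params, basis, w_lin, b, mid) < targets
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    out[never] = math.inf
    return out


def simulate_joint_cohort(params: SimulationParams) -> SyntheticCohort:
    """Draw a full cohort (subjects, longitudinal series, latent truth)."""
    rng = np.random.default_rng(params.seed)
    basis = params.basis()
    n = params.n_subjects
    q = params.n_random_effects
    # PSD factor tolerant of exactly singular D (degenerate-variance cases)
    eigval, eigvec = np.linalg.eigh(params.D)
    chol = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    # horizon for the truth event time: well beyond administrative censoring
    t_max = max(params.admin_censor, params.baseline_cuts[-1]) * 20

    tp53 = rng.random(n) < params.tp53_prev
    t4 = rng.random(n) < params.t4_prev
    b_all = rng.standard_normal((n, q)) @ chol.T
    w_lin = params.gamma1 * tp53 + params.gamma2 * t4
    targets = rng.exponential(size=n)
    t_events = _invert_event_times(params, basis, w_lin, b_all, targets, t_max)

    subjects, series, truth = [], [], {}
    for i in range(n):
        pid = f"S{i:04d}"
        b = b_all[i]
        t_event = float(t_events[i])

        # visit schedule: surgery-day draw, postsurgical draw, then quarterly;
        # independent per-visit dropout from the second visit on
        horizon = min(t_event, params.admin_censor)
        visits = [0.0, params.first_visit_day]
        t_drop = math.inf
        k = 1
        while k * params.visit_interval <= params.admin_censor:
            v = k * params.visit_interval
            visits.append(v)
            k += 1
            if v >= horizon + params.visit_interval:
                break
        visits = np.unique(np.asarray(visits))
        for v in visits[1:]:
            if v >= horizon:
                break
            if rng.random() < params.dropout_prob:
                t_drop = v
                break
        t_obs = min(t_event, t_drop, params.admin_censor)
        event = t_event <= min(t_drop, params.admin_censor)
        if t_obs <= 0:
            t_obs, event = 0.5, True  # degenerate immediate event

        meas_days = visits[visits < t_obs]
        if meas_days.size == 0:
            meas_days = np.array([0.0])
        X = np.column_stack([np.ones(meas_days.size), basis.design(meas_days)])
        eta = X @ params.beta + X[:, :q] @ b
        y = eta + params.sigma * rng.standard_normal(meas_days.size)
        if params.floor_at_zero:
            y = np.maximum(y, 0.0)
        vaf = mean_vaf_from_log_level(y)

        subjects.append(SubjectRecord(
            patient=pid, tp53_mut=bool(tp53[i]), t4_stage=bool(t4[i]),
            stage="II-III" if t4[i] else "I-II", act_received=False,
            rfs_day=float(t_obs), event=bool(event)))
        series.append(LongitudinalSeries(
            patient=pid, days=meas_days, log_level=y, mean_vaf=vaf,
            positive=vaf > 0))
        truth[pid] = {"b": b, "event_time": t_event, "dropout_time": t_drop}
    return SyntheticCohort(subjects=subjects, series=series, truth=truth,
                           params=params)


# ---------------------------------------------------------------------------
# deterministic small fixture
# ---------------------------------------------------------------------------

def cohort_fixture_small() -> SyntheticCohort:
    """Hand-specified 8-subject cohort used across unit tests (byte-stable).

    Contains events and censorings, TP53-mutant and wild-type subjects, and
    rising/falling trajectories.
    """
    spec = [
        # pid, tp53, t4, rfs_day, event, days, log-levels
        ("F01", True, False, 210.0, True, [0, 14, 91, 182], [8.1, 2.0, 3.5, 5.0]),
        ("F02", False, False, 650.0, False, [0, 14, 91, 182, 273, 364], [6.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
        ("F03", True, True, 150.0, True, [0, 14, 91], [9.2, 4.1, 6.3]),
        ("F04", False, False, 730.0, False, [0, 14, 91, 182, 273, 364, 455], [5.5, 0.0, 0.0, 0.9, 0.0, 0.0, 0.0]),
        ("F05", False, True, 400.0, True, [0, 14, 91, 182, 273], [7.3, 1.2, 1.8, 2.9, 4.4]),
        ("F06", True, False, 520.0, False, [0, 14, 91, 182, 273, 364, 455], [6.8, 0.0, 0.7, 0.0, 0.0, 0.6, 0.0]),
        ("F07", False, False, 300.0, True, [0, 14, 91, 182], [7.9, 3.3, 2.5, 4.8]),
        ("F08", False, False, 730.0, False, [0, 14, 91, 182, 273, 364, 455], [4.9, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
    ]
    subjects, series, truth = [], [], {}
    for pid, tp53, t4, rfs, ev, days, yy in spec:
        y = np.asarray(yy, dtype=float)
        vaf = mean_vaf_from_log_level(y)
        subjects.append(SubjectRecord(
            patient=pid, tp53_mut=tp53, t4_stage=t4,
            stage="II-III" if t4 else "I", act_received=False,
            rfs_day=rfs, event=ev))
        series.append(LongitudinalSeries(
            patient=pid, days=np.asarray(days, dtype=float), log_level=y,
            mean_vaf=vaf, positive=vaf > 0))
        truth[pid] = {"b": np.zeros(2), "event_time": rfs if ev else math.inf}
    params = SimulationParams(n_subjects=8, seed=0)
    return SyntheticCohort(subjects=subjects, series=series, truth=truth,
                           params=params)


# ---------------------------------------------------------------------------
# read families
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class ReadFamilySet:
    families: list
    truth_vaf: float
    contig: str
    loci: list   # list of (position, ref, alt)


def _other_base(rng, base):
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(3)]


def simulate_read_families(truth_vaf: float, depth: int,
                           reads_per_family=3, error_rate: float = 1e-3,
                           seed: int = 0, contig: str = "chr1",
                           position: int = 1000, ref: str = "C",
                           alt: str = "T", duplex_fraction: float = 0.8):
    """Simulate UMI read families at a single locus.

    ``depth`` counts original double-stranded molecules; a ``duplex_fraction``
    share yields both strand families (transposed UMI pairs), the rest one.
    Mutant molecules are Bernoulli(truth_vaf); each read base is corrupted
    independently with probability ``error_rate``.  ``reads_per_family`` is
    either a constant int or a callable rng -> int.
    """
    if not 0 <= truth_vaf <= 1:
        raise ValueError("truth_vaf must lie in [0, 1]")
    if error_rate >= 0.01:
        raise ValueError("error_rate must be < 0.01")
    rng = np.random.default_rng(seed)
    families = []
    for m in range(depth):
        mutant = rng.random() < truth_vaf
        true_base = alt if mutant else ref
        umi_a = f"U{2 * m:06d}"
        umi_b = f"U{2 * m + 1:06d}"
        strands = [("AB", umi_a, umi_b)]
        if rng.random() < duplex_fraction:
            strands.append(("BA", umi_b, umi_a))
        for orient, ua, ub in strands:
            if callable(reads_per_family):
                n_reads = max(1, int(reads_per_family(rng)))
            else:
                n_reads = int(reads_per_family)
            reads = []
            for _ in range(n_reads):
                base = true_base
                if error_rate and rng.random() < error_rate:
                    base = _other_base(rng, base)
                reads.append({position: base})
            families.append(ReadFamily(
                contig=contig, position=position, umi_a=ua, umi_b=ub,
                orientation=orient, reads=tuple(reads)))
    return ReadFamilySet(families=families, truth_vaf=truth_vaf, contig=contig,
                         loci=[(position, ref, alt)])


def simulate_consensus_counts(depth: int, truth_vaf: float,
                              consensus_error_rate: float, n_loci: int,
                              rng) -> tuple:
    """Fast path: consensus-level (mutant_reads, depth) draws at many loci.

    Models the post-consensus pileup directly: true mutant consensus reads
    are Binomial(depth, truth_vaf) and residual errors Binomial(remainder,
    consensus_error_rate).  Returns (mutant_counts, depths) as int arrays of
    length ``n_loci``.
    """
    true_mut = rng.binomial(depth, truth_vaf, size=n_loci)
    errs = rng.binomial(depth - true_mut, consensus_error_rate)
    depths = np.full(n_loci, depth, dtype=int)
    return true_mut + errs, depths
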