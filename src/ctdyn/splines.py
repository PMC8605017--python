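"""Natural cubic spline basis with closed-form derivative and antiderivative.

The basis uses the truncated-power construction: with knots
``k_1 < ... < k_K`` (first/last are the boundary knots) the columns are

    N_1(t) = t/s,
    N_{j+1}(t) = d_j(t) - d_{K-1}(t),    j = 1..K-2,

where ``d_k(t) = [ (t-k_k)_+^3 - (t-k_K)_+^3 ] / (k_K - k_k)`` and ``s`` is a
scale constant, all evaluated in scaled time.  Every column is linear outside
the boundary knots (second derivative identically zero there), which keeps
extrapolation well-behaved.  Columns span the same function space as R's
``splines::ns`` for identical knots (modulo the intercept and an affine
reparameterization), which the tests verify against frozen reference values.

Closed forms for the first derivative and the antiderivative from zero are
exposed because the hazard links need the trajectory slope and its running
integral.
"""

from __future__ import annotations

import numpy as np

__all__ = ["NaturalCubicBasis"]


def _tp3(u: np.ndarray, knot: float) -> np.ndarray:
    """Truncated cube (u - knot)_+^3."""
    d = np.maximum(u - knot, 0.0)
    return d * d * d


def _tp3_deriv(u: np.ndarray, knot: float) -> np.ndarray:
    d = np.maximum(u - knot, 0.0)
    return 3.0 * d * d


def _tp3_antideriv(u: np.ndarray, knot: float) -> np.ndarray:
    """Integral of (x - knot)_+^3 from 0 to u (requires knot >= 0)."""
    d = np.maximum(u - knot, 0.0)
    return 0.25 * d * d * d * d


class NaturalCubicBasis:
    """Natural cubic spline design (value, slope, running integral).

    Parameters
    ----------
    interior_knots : sequence of float
        Interior knot locations; ``df = 1 + len(interior_knots)``.
    boundary_knots : (float, float)
        Must satisfy ``0 <= lower < upper`` and bracket the interior knots.
        The lower bound at/above zero keeps the antiderivative-from-zero
        closed form valid.
    """

    def __init__(self, interior_knots, boundary_knots):
        interior = np.atleast_1d(np.asarray(interior_knots, dtype=float))
        lo, hi = float(boundary_knots[0]), float(boundary_knots[1])
        if lo < 0 or hi <= lo:
            raise ValueError("boundary knots must satisfy 0 <= lower < upper")
        if interior.size and not np.all((interior > lo) & (interior < hi)):
            raise ValueError("interior knots must lie strictly inside the boundary")
        self.interior_knots = np.sort(interior)
        self.boundary_knots = (lo, hi)
        self.knots = np.concatenate([[lo], self.interior_knots, [hi]])
        self.scale = hi - lo
        self.df = 1 + self.interior_knots.size

    @classmethod
    def from_times(cls, times, df: int = 2, upper_quantile: float = 0.95):
        """Place knots from observed measurement times.

        Boundary at 0 and the ``upper_quantile`` time; ``df - 1`` interior
        knots at equally spaced interior quantiles (a single interior knot
        lands at the median for the default ``df=2``).
        """
        t = np.asarray(times, dtype=float)
        if df < 2:
            raise ValueError("df must be >= 2")
        hi = float(np.quantile(t, upper_quantile))
        if hi <= 0:
            raise ValueError("upper boundary knot must be positive")
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior = np.quantile(t[(t > 0) & (t < hi)], probs)
        return cls(interior, (0.0, hi))

    # -- internals ---------------------------------------------------------

    def _columns(self, t, fn, linear_col, power_of_scale: int):
        """Assemble basis columns applying `fn` to each truncated-power piece.

        power_of_scale: 0 for value, -1 for d/dt, +1 for the antiderivative;
        undoes the internal time scaling.
        """
        t = np.asarray(t, dtype=float)
        s = self.scale
        u = t / s
        kn = self.knots / s
        K = kn.size
        out = np.empty(t.shape + (self.df,))
        out[..., 0] = linear_col(u)

        def d_k(j):
            return (fn(u, kn[j]) - fn(u, kn[K - 1])) / (kn[K - 1] - kn[j])

        dlast = d_k(K - 2)
        for j in range(K - 2):
            out[..., j + 1] = d_k(j) - dlast
        return out * s ** power_of_scale

    # -- public evaluation -------------------------------------------------

    def design(self, t) -> np.ndarray:
        """Basis values; shape ``t.shape + (df,)``."""
        return self._columns(t, _tp3, lambda u: u, 0)

    def derivative(self, t) -> np.ndarray:
        """First derivative of each column with respect to t."""
        return self._columns(t, _tp3_deriv, lambda u: np.ones_like(u), -1)

    def second_derivative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        s = self.scale
        u = t / s
        kn = self.knots / s
        K = kn.size
        out = np.zeros(t.shape + (self.df,))

        def h2(j):
            return (6.0 * np.maximum(u - kn[j], 0.0)
                    - 6.0 * np.maximum(u - kn[K - 1], 0.0)) / (kn[K - 1] - kn[j])

        dlast = h2(K - 2)
        for j in range(K - 2):
            out[..., j + 1] = h2(j) - dlast
        return out / s ** 2

    def antiderivative(self, t) -> np.ndarray:
        """Integral of each column from 0 to t (t >= 0)."""
        return self._columns(t, _tp3_antideriv, lambda u: 0.5 * u * u, 1)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "interior_knots": self.interior_knots.tolist(),
            "boundary_knots": list(self.boundary_knots),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalCubicBasis":
        return cls(d["interior_knots"], tuple(d["boundary_knots"]))

    def __eq__(self, other):
        return (isinstance(other, NaturalCubicBasis)
                and np.array_equal(self.knots, other.knots))

    def __repr__(self):
        return (f"NaturalCubicBasis(interior={self.interior_knots.tolist()}, "
                f"boundary={self.boundary_knots})")
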