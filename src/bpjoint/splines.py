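"""Natural cubic spline time basis with analytic derivative and integral.

The longitudinal submodels express the time trend of each blood-pressure
outcome through a low-dimensional natural cubic spline in months since
diagnosis.  The association structures of the joint model need not only the
basis values but also exact time derivatives (for slope associations) and
exact integrals from 0 (for area associations), so the basis is built from
truncated power functions where both are available in closed form.

Columns are rescaled to have unit maximum absolute value over the boundary
interval so that coefficients are O(1) regardless of the time unit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["NaturalCubicSplineBasis"]


def _tp3(t: np.ndarray, knot: float) -> np.ndarray:
    """(t - knot)_+^3"""
    return np.clip(t - knot, 0.0, None) ** 3


def _tp2(t: np.ndarray, knot: float) -> np.ndarray:
    return np.clip(t - knot, 0.0, None) ** 2


def _tp4_over4(t: np.ndarray, knot: float) -> np.ndarray:
    """Integral of (s - knot)_+^3 over s in [0, t], valid for knot >= 0."""
    return np.clip(t - knot, 0.0, None) ** 4 / 4.0


class NaturalCubicSplineBasis:
    """Natural cubic spline basis of dimension ``len(knots) - 1``.

    Parameters
    ----------
    internal_knots:
        Strictly increasing interior knots.
    boundary:
        (low, high) boundary knots; the basis is linear outside them.
        ``low`` must be >= 0 (time is months since diagnosis).

    With two interior knots the basis has 3 columns, matching the three
    time coefficients reported per outcome in the fitted model tables.
    """

    def __init__(self, internal_knots, boundary=(0.0, 120.0)):
        lo, hi = float(boundary[0]), float(boundary[1])
        if lo < 0:
            raise ValueError("boundary must start at a non-negative time")
        ks = [lo] + [float(k) for k in internal_knots] + [hi]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError(f"knots must be strictly increasing, got {ks}")
        self.knots = np.asarray(ks)
        self.boundary = (lo, hi)
        self.df = len(ks) - 1
        # column scales: unit max-abs on the boundary interval
        grid = np.linspace(lo, hi, 513)
        raw = self._raw(grid)
        self._scale = np.max(np.abs(raw), axis=0)
        self._scale[self._scale == 0] = 1.0

    # -- raw truncated-power construction ---------------------------------
    def _d(self, t, k):
        """d_k(t) = [(t-xi_k)_+^3 - (t-xi_K)_+^3] / (xi_K - xi_k)"""
        xi = self.knots
        return (_tp3(t, xi[k]) - _tp3(t, xi[-1])) / (xi[-1] - xi[k])

    def _d_deriv(self, t, k):
        xi = self.knots
        return 3.0 * (_tp2(t, xi[k]) - _tp2(t, xi[-1])) / (xi[-1] - xi[k])

    def _d_int(self, t, k):
        xi = self.knots
        return (_tp4_over4(t, xi[k]) - _tp4_over4(t, xi[-1])) / (xi[-1] - xi[k])

    def _raw(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cols = [t]
        last = len(self.knots) - 2  # index K-1 in 0-based knot array
        for k in range(0, last):
            cols.append(self._d(t, k) - self._d(t, last))
        return np.column_stack(cols)

    def _raw_deriv(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cols = [np.ones_like(t)]
        last = len(self.knots) - 2
        for k in range(0, last):
            cols.append(self._d_deriv(t, k) - self._d_deriv(t, last))
        return np.column_stack(cols)

    def _raw_int(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cols = [t**2 / 2.0]
        last = len(self.knots) - 2
        for k in range(0, last):
            cols.append(self._d_int(t, k) - self._d_int(t, last))
        return np.column_stack(cols)

    # -- public API --------------------------------------------------------
    def design(self, t) -> np.ndarray:
        """Basis values B(t); shape (len(t), df)."""
        return self._raw(t) / self._scale

    def deriv(self, t) -> np.ndarray:
        """dB/dt per month; shape (len(t), df)."""
        return self._raw_deriv(t) / self._scale

    def integral(self, t) -> np.ndarray:
        """Columnwise integral of B from 0 to t; shape (len(t), df)."""
        return self._raw_int(t) / self._scale

    @classmethod
    def from_times(cls, times, df: int = 3, boundary=None):
        """Place interior knots at evenly spaced quantiles of observed times.

        With df=3 the interior knots sit at the 33rd/67th percentiles.
        """
        times = np.asarray(times, dtype=float)
        if boundary is None:
            boundary = (0.0, float(np.max(times)))
        probs = np.linspace(0, 1, df + 1)[1:-1]
        inner = np.quantile(times, probs)
        # nudge degenerate quantiles apart
        lo, hi = boundary
        inner = np.clip(inner, lo + 1e-6, hi - 1e-6)
        for i in range(1, len(inner)):
            if inner[i] <= inner[i - 1]:
                inner[i] = inner[i - 1] + 1e-3
        return cls(list(inner), boundary=boundary)
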