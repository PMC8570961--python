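"""Time bases for patient-level MELD-Na trajectories.

A basis maps measurement times (days since listing) to the columns of the
fixed/random-effect design that multiply the time-varying coefficients.  The
intercept is *not* part of the basis; design builders prepend it.  Every basis
exposes an analytic derivative so trajectory slopes are exact, never finite
differences.
"""
from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np


class TimeBasis(ABC):
    """Columns B(t) of the trajectory design and their derivative B'(t)."""

    n_cols: int

    @abstractmethod
    def matrix(self, t: np.ndarray) -> np.ndarray:
        """Basis values, shape ``(len(t), n_cols)``."""

    @abstractmethod
    def deriv(self, t: np.ndarray) -> np.ndarray:
        """d/dt of :meth:`matrix`, same shape."""

    def __call__(self, t):
        return self.matrix(t)


class LinearTimeBasis(TimeBasis):
    """Single column ``t``: straight-line disease trajectories."""

    n_cols = 1

    def matrix(self, t):
        t = np.asarray(t, dtype=float)
        return t.reshape(-1, 1)

    def deriv(self, t):
        t = np.asarray(t, dtype=float)
        return np.ones((t.size, 1))


class NaturalCubicBasis(TimeBasis):
    """Natural cubic spline basis (linear beyond the boundary knots).

    Uses the standard truncated-power construction: with knots
    ``xi_1 < ... < xi_K`` (boundaries included) the columns are ``t`` followed
    by ``d_k(t) - d_{K-1}(t)`` for ``k = 1..K-2`` where
    ``d_k(t) = ((t - xi_k)_+^3 - (t - xi_K)_+^3) / (xi_K - xi_k)``.

    Captures the fast, non-linear deterioration seen in acute-on-chronic
    liver failure while staying linear (hence extrapolation-safe) outside the
    observed time range.
    """

    def __init__(self, interior_knots, boundary_knots):
        interior = np.sort(np.asarray(interior_knots, dtype=float))
        lo, hi = float(boundary_knots[0]), float(boundary_knots[1])
        if interior.size and (interior[0] <= lo or interior[-1] >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        self.knots = np.concatenate([[lo], interior, [hi]])
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.n_cols = len(self.knots) - 1  # t plus K-2 curvature terms

    def _d(self, t, k):
        xi = self.knots
        xK = xi[-1]
        num = np.maximum(t - xi[k], 0.0) ** 3 - np.maximum(t - xK, 0.0) ** 3
        return num / (xK - xi[k])

    def _d_deriv(self, t, k):
        xi = self.knots
        xK = xi[-1]
        num = 3.0 * np.maximum(t - xi[k], 0.0) ** 2 - 3.0 * np.maximum(t - xK, 0.0) ** 2
        return num / (xK - xi[k])

    def matrix(self, t):
        t = np.asarray(t, dtype=float).ravel()
        cols = [t]
        K = len(self.knots)
        dlast = self._d(t, K - 2)
        for k in range(K - 2):
            cols.append(self._d(t, k) - dlast)
        return np.column_stack(cols)

    def deriv(self, t):
        t = np.asarray(t, dtype=float).ravel()
        cols = [np.ones_like(t)]
        K = len(self.knots)
        dlast = self._d_deriv(t, K - 2)
        for k in range(K - 2):
            cols.append(self._d_deriv(t, k) - dlast)
        return np.column_stack(cols)


def make_basis(kind: str, times=None, n_interior: int = 2,
               interior_knots=None, boundary_knots=None) -> TimeBasis:
    """Build a basis from a config string.

    ``kind='linear'`` needs nothing else.  ``kind='ns'`` places interior knots
    at evenly spaced percentiles of ``times`` (33rd/67th for the default two
    knots) unless explicit knots are given.
    """
    if kind == "linear":
        return LinearTimeBasis()
    if kind == "ns":
        if interior_knots is None or boundary_knots is None:
            if times is None:
                raise ValueError("ns basis needs observation times or explicit knots")
            times = np.asarray(times, dtype=float)
            qs = np.linspace(0, 100, n_interior + 2)[1:-1]
            interior_knots = np.percentile(times, qs)
            boundary_knots = (times.min(), times.max())
        return NaturalCubicBasis(interior_knots, boundary_knots)
    raise ValueError(f"unknown time basis kind: {kind!r}")
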