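"""Concave steady-state growth-rate versus nutrient-concentration map.

Steady-state growth rate of *E. coli* increases less than linearly with LB
concentration (a Monod-like, concave dependence).  The map interpolates a
small set of measured anchors with a monotone, *concave*, C1 piecewise-cubic
Hermite interpolant.  Concavity is what makes Jensen's inequality

    rate((c_low + c_high) / 2)  >=  (rate(c_low) + rate(c_high)) / 2

hold by construction, so the interpolant is built to honor it exactly:
node derivatives are chosen between adjacent secant slopes under the
per-interval constraints that keep each cubic piece concave.  (A standard
shape-preserving PCHIP fit is monotone but not concave for these anchors,
and a two-parameter Monod curve cannot pass through all of them.)
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicHermiteSpline

__all__ = ["SteadyStateMap", "steady_rate", "DEFAULT_ANCHORS"]

#: (concentration % LB, steady-state rate in doublings/h) anchors:
#: the origin plus the measured G_low, G_ave and G_high.
DEFAULT_ANCHORS: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.0), (0.1, 1.07), (1.05, 2.31), (2.0, 2.86),
)


def _concave_derivatives(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Node derivatives making the cubic Hermite interpolant concave.

    On interval i with secant slope s_i, a cubic Hermite piece with end
    derivatives (d_i, d_{i+1}) is concave iff

        2 d_i + d_{i+1} >= 3 s_i   and   d_i + 2 d_{i+1} <= 3 s_i,

    (linear second derivative non-positive at both ends).  Choosing d
    backward from the last node keeps every interval feasible when the
    secant slopes are non-increasing and not too unevenly spaced.
    """
    s = np.diff(y) / np.diff(x)
    n = len(x)
    d = np.empty(n)
    d[-1] = s[-1]
    for i in range(n - 2, -1, -1):
        lo = 0.5 * (3.0 * s[i] - d[i + 1])
        hi = 3.0 * s[i] - 2.0 * d[i + 1]
        if i > 0:
            hi = min(hi, s[i - 1])
        if lo > hi + 1e-12:
            raise ValueError(
                "anchors do not admit a concave C1 cubic interpolant")
        d[i] = 0.5 * (lo + hi)
    return d


class SteadyStateMap:
    """Monotone concave map from nutrient concentration to steady-state rate.

    Parameters
    ----------
    anchors : sequence of (concentration, rate)
        Strictly increasing in concentration, non-decreasing in rate, with
        non-increasing secant slopes (concave data).
    interpolation : {"shape_preserving_concave"}
        Only one scheme is provided; the name records the contract.

    Beyond the last anchor the rate saturates at the last anchor's value.
    """

    def __init__(self,
                 anchors: Sequence[Tuple[float, float]] = DEFAULT_ANCHORS,
                 interpolation: str = "shape_preserving_concave"):
        if interpolation != "shape_preserving_concave":
            raise ValueError(f"unknown interpolation {interpolation!r}")
        a = np.asarray(anchors, dtype=float)
        if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
            raise ValueError("anchors must be a sequence of >= 2 (c, rate) pairs")
        c, r = a[:, 0], a[:, 1]
        if np.any(np.diff(c) <= 0):
            raise ValueError("anchor concentrations must be strictly increasing")
        if np.any(np.diff(r) < 0):
            raise ValueError("anchor rates must be non-decreasing")
        slopes = np.diff(r) / np.diff(c)
        if np.any(np.diff(slopes) > 1e-12):
            raise ValueError("anchor secant slopes must be non-increasing "
                             "(concave data required)")
        self.anchors = tuple(map(tuple, a))
        self._c, self._r = c, r
        d = _concave_derivatives(c, r)
        self._spline = CubicHermiteSpline(c, r, d)
        # verify the construction numerically (cheap, one-time)
        grid = np.linspace(c[0], c[-1], 2001)
        if np.any(self._spline.derivative(2)(grid) > 1e-9):
            raise AssertionError("interpolant failed concavity check")
        if np.any(self._spline.derivative(1)(grid) < -1e-9):
            raise AssertionError("interpolant failed monotonicity check")

    @property
    def c_max(self) -> float:
        return float(self._c[-1])

    def rate(self, c):
        """Steady-state growth rate (doublings/h) at concentration(s) ``c``.

        Raises ``ValueError`` for negative concentrations; saturates at the
        last anchor's rate above the anchored range.
        """
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative")
        out = self._spline(np.clip(c, self._c[0], self._c[-1]))
        return out if out.ndim else float(out)

    def __call__(self, c):
        return self.rate(c)


def steady_rate(steady_map: SteadyStateMap, c) -> float:
    """Evaluate ``steady_map`` at concentration ``c`` (doublings/h)."""
    return steady_map.rate(c)
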