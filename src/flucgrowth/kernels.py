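"""Single-shift growth-response kernels.

A shift-response kernel K(tau) is the mean growth rate of a population as a
function of time tau since a single step in nutrient concentration, taken
from steady state in the pre-shift condition.  Two stylized facts define the
default kernels:

* after an upshift (low -> high) the growth rate rises gradually from G_low
  and completes the transition to G_high within 2-3 h;
* after a downshift (high -> low) the growth rate first drops sharply, to a
  small fraction of G_low, then recovers gradually to G_low within ~5 h.

Two shapes are provided: a saturating exponential (normalized to hit the
endpoint exactly at the completion time, constant afterwards) and a linear
ramp.  Both are monotone non-decreasing in tau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["ShiftKernel", "KernelPair", "make_shift_kernels"]

S_PER_H = 3600.0


@dataclass(frozen=True)
class ShiftKernel:
    """Growth-rate trajectory after one nutrient shift.

    ``g_start`` is the value at tau = 0+ (just after the shift), ``g_end``
    the post-shift steady state reached at ``t_complete`` seconds, and
    ``g_pre`` the pre-shift steady state (for a downshift ``g_pre`` differs
    from ``g_start`` because of the initial sharp drop).
    """

    direction: Literal["up", "down"]
    g_pre: float
    g_start: float
    g_end: float
    t_complete: float  # seconds
    shape: Literal["exponential", "linear"] = "exponential"

    # The exponential shape is g_end - (g_end-g_start)*(e^{-tau/tc}-q)/(1-q)
    # with tc chosen so the unnormalized exponential covers 99% of the span
    # at t_complete (q = 0.01); the normalization makes the endpoint exact.

    @property
    def _tc_h(self) -> float:
        return self.t_complete / S_PER_H

    def __call__(self, tau_s):
        """Kernel value at time(s) ``tau_s`` seconds after the shift."""
        tau = np.asarray(tau_s, dtype=float) / S_PER_H
        span = self.g_end - self.g_start
        if self.t_complete <= 0 or span == 0:
            out = np.full_like(tau, self.g_end)
            return out if out.ndim else float(out)
        tc = self._tc_h
        if self.shape == "linear":
            out = self.g_start + span * np.clip(tau / tc, 0.0, 1.0)
        else:
            q = 0.01
            tau_c = tc / np.log(1.0 / q)
            frac = (1.0 - (np.exp(-np.clip(tau, 0, None) / tau_c) - q)
                    / (1.0 - q))
            out = np.where(tau >= tc, self.g_end,
                           self.g_start + span * np.clip(frac, 0.0, 1.0))
        return out if out.ndim else float(out)

    def integral_h(self, a_s: float, b_s: float) -> float:
        """Exact integral of K over [a, b] seconds, in doublings (h^-1 * h)."""
        if b_s < a_s:
            raise ValueError("b < a")
        a, b = a_s / S_PER_H, b_s / S_PER_H
        tc = self._tc_h
        span = self.g_end - self.g_start
        if self.t_complete <= 0 or span == 0:
            return self.g_end * (b - a)
        total = 0.0
        # clamp the part beyond completion
        if b > tc:
            total += self.g_end * (b - min(max(a, tc), b))
            b = min(b, tc)
        if a >= b:
            return total
        if self.shape == "linear":
            prim = lambda t: self.g_start * t + span * t * t / (2 * tc)
        else:
            q = 0.01
            tau_c = tc / np.log(1.0 / q)
            g_inf = self.g_end + span * q / (1.0 - q)
            amp = span / (1.0 - q)
            prim = lambda t: g_inf * t + amp * tau_c * np.exp(-t / tau_c)
        return total + float(prim(b) - prim(a))

    def deficit_area_h(self) -> float:
        """Area (h * h^-1) between g_end and the kernel: integral of g_end - K."""
        return self.g_end * self._tc_h - self.integral_h(0.0, self.t_complete)

    def value_match_tau(self, mu: float) -> float:
        """Smallest tau (s) with K(tau) >= mu, clamped to [0, t_complete]."""
        span = self.g_end - self.g_start
        if self.t_complete <= 0 or span == 0 or mu <= self.g_start:
            return 0.0
        if mu >= self.g_end:
            return float(self.t_complete)
        frac = (mu - self.g_start) / span
        tc = self._tc_h
        if self.shape == "linear":
            tau_h = frac * tc
        else:
            q = 0.01
            tau_c = tc / np.log(1.0 / q)
            tau_h = -tau_c * np.log(q + (1.0 - q) * (1.0 - frac))
        return float(np.clip(tau_h * S_PER_H, 0.0, self.t_complete))


@dataclass(frozen=True)
class KernelPair:
    up: ShiftKernel
    down: ShiftKernel

    @property
    def g_low(self) -> float:
        return self.up.g_start

    @property
    def g_high(self) -> float:
        return self.up.g_end


def make_shift_kernels(g_low: float = 1.07,
                       g_high: float = 2.86,
                       t_up_complete: float = 150 * 60.0,
                       t_down_complete: float = 300 * 60.0,
                       drop_fraction: float = 0.1,
                       shape: Literal["exponential", "linear"] = "exponential",
                       ) -> KernelPair:
    """Build the up/down kernel pair from endpoint rates and completion times.

    Defaults: G_low = 1.07 and G_high = 2.86 doublings/h, upshift complete at
    150 min, downshift complete at 300 min, with the post-downshift rate
    starting at ``drop_fraction`` (10%) of G_low.
    """
    if not (g_low < g_high):
        raise ValueError("g_low must be strictly below g_high")
    if t_up_complete < 0 or t_down_complete < 0:
        raise ValueError("completion times must be non-negative")
    if not (0.0 <= drop_fraction <= 1.0):
        raise ValueError("drop_fraction must lie in [0, 1]")
    up = ShiftKernel("up", g_pre=g_low, g_start=g_low, g_end=g_high,
                     t_complete=t_up_complete, shape=shape)
    down = ShiftKernel("down", g_pre=g_high, g_start=drop_fraction * g_low,
                       g_end=g_low, t_complete=t_down_complete, shape=shape)
    return KernelPair(up=up, down=down)
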