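"""Piecewise-constant nutrient concentration signals.

A nutrient signal describes the concentration (in % LB v/v) delivered to
surface-attached cells over the course of an experiment.  Four kinds are
supported:

``steady``
    A constant concentration: the low, the high, or their arithmetic mean
    (the "average" control, which delivers the same time-averaged nutrient
    as a fluctuating run).
``fluctuating``
    An even square wave between ``c_low`` and ``c_high`` with period
    ``period_T``: exactly half of each period is spent at each level.
``single_shift``
    One step between the two levels at ``shift_time`` (an upshift when the
    signal starts low, a downshift when it starts high).
``onset``
    Steady ``c_low`` until ``shift_time``, then an even square wave whose
    first half-period is at ``c_high`` (cells experience the onset of
    fluctuations after growing steadily in low nutrient).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Optional

import numpy as np

__all__ = ["NutrientSignal", "make_signal"]

SignalKind = Literal["steady", "fluctuating", "single_shift", "onset"]
Phase = Literal["high", "low"]


@dataclass(frozen=True)
class NutrientSignal:
    """A piecewise-constant concentration-versus-time signal.

    Use :func:`make_signal` to construct validated instances.

    Attributes
    ----------
    kind : {"steady", "fluctuating", "single_shift", "onset"}
    c_low, c_high : float
        The two concentration levels (% LB v/v), ``0 <= c_low <= c_high``.
    duration : float
        Total signal duration in seconds.
    period_T : float, optional
        Square-wave period in seconds (fluctuating / onset).
    shift_time : float, optional
        Time of the single shift, or of fluctuation onset, in seconds.
    first_phase : {"high", "low"}
        Level during the first half-period (fluctuating), or the pre-shift
        level (single_shift).
    steady_level : {"low", "average", "high"}
        Which constant level a steady signal delivers.
    """

    kind: SignalKind
    c_low: float
    c_high: float
    duration: float
    period_T: Optional[float] = None
    shift_time: Optional[float] = None
    first_phase: Phase = "high"
    steady_level: Literal["low", "average", "high"] = "average"

    @property
    def c_ave(self) -> float:
        """Arithmetic mean of the two levels, (c_low + c_high) / 2."""
        return 0.5 * (self.c_low + self.c_high)

    # -- evaluation -----------------------------------------------------

    def concentration(self, t):
        """Concentration at time(s) ``t`` (s); vectorized, pure function."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.duration):
            raise ValueError("time outside [0, duration]")
        if self.kind == "steady":
            level = {"low": self.c_low, "average": self.c_ave,
                     "high": self.c_high}[self.steady_level]
            return np.full_like(t, level)
        if self.kind == "fluctuating":
            return self._square(t, t0=0.0)
        if self.kind == "single_shift":
            pre = self.c_high if self.first_phase == "high" else self.c_low
            post = self.c_low if self.first_phase == "high" else self.c_high
            return np.where(t < self.shift_time, pre, post)
        # onset: c_low until shift_time, then square wave starting high
        out = np.where(t < self.shift_time, self.c_low,
                       self._square(t - self.shift_time, t0=0.0,
                                    first="high"))
        return out

    def _square(self, t, t0: float, first: Optional[Phase] = None):
        first = first or self.first_phase
        a, b = ((self.c_high, self.c_low) if first == "high"
                else (self.c_low, self.c_high))
        frac = np.mod(t - t0, self.period_T) / self.period_T
        return np.where(frac < 0.5, a, b)

    def phase(self, t):
        """Phase label ('high'/'low') at time(s) ``t``; 'n/a' for steady."""
        c = self.concentration(t)
        if self.kind == "steady":
            return np.full(c.shape, "n/a", dtype=object)
        mid = self.c_ave
        return np.where(c > mid, "high", "low").astype(object) \
            if self.c_low < self.c_high else np.full(c.shape, "n/a",
                                                     dtype=object)

    # -- shift bookkeeping ----------------------------------------------

    def shift_times(self, direction: Optional[Literal["up", "down"]] = None):
        """Times of concentration steps in (0, duration], optionally by direction.

        For fluctuating signals the wave is taken to start mid-cycle, so the
        first listed shift is the first half-period boundary after t = 0.
        For onset signals the onset itself (an upshift) is included.
        """
        if self.kind == "steady" or self.c_low == self.c_high:
            ups = np.array([])
            downs = np.array([])
        elif self.kind == "single_shift":
            d = "up" if self.first_phase == "low" else "down"
            ups = np.array([self.shift_time]) if d == "up" else np.array([])
            downs = np.array([self.shift_time]) if d == "down" else np.array([])
        elif self.kind == "fluctuating":
            half = 0.5 * self.period_T
            k = np.arange(1, int(np.floor(self.duration / half)) + 1)
            bounds = k * half
            keep = bounds < self.duration   # a step at the end is no shift
            k, bounds = k[keep], bounds[keep]
            # first_phase high: odd boundaries end a high phase -> downshift
            down_mask = (k % 2 == 1) if self.first_phase == "high" \
                else (k % 2 == 0)
            downs = bounds[down_mask]
            ups = bounds[~down_mask]
        else:  # onset
            half = 0.5 * self.period_T
            t_rel_max = self.duration - self.shift_time
            k = np.arange(0, int(np.floor(t_rel_max / self.period_T)) + 1)
            ups = self.shift_time + k * self.period_T
            downs = self.shift_time + half + k * self.period_T
            ups = ups[ups < self.duration]
            downs = downs[downs < self.duration]
        if direction == "up":
            return ups
        if direction == "down":
            return downs
        return np.sort(np.concatenate([ups, downs]))

    def to_dict(self) -> dict:
        return asdict(self)


def make_signal(kind: SignalKind,
                c_low: float,
                c_high: float,
                duration: float,
                period_T: Optional[float] = None,
                shift_time: Optional[float] = None,
                first_phase: Optional[Phase] = None,
                steady_level: Literal["low", "average", "high"] = "average",
                ) -> NutrientSignal:
    """Construct and validate a :class:`NutrientSignal`.

    Raises
    ------
    ValueError
        If concentrations are negative or inverted, the duration is not
        positive, a period is missing for fluctuating/onset kinds, or a
        shift time is missing for single_shift/onset kinds.
    """
    if kind not in ("steady", "fluctuating", "single_shift", "onset"):
        raise ValueError(f"unknown signal kind {kind!r}")
    if c_low < 0 or c_high < 0:
        raise ValueError("concentrations must be non-negative")
    if c_low > c_high:
        raise ValueError("c_low must not exceed c_high")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if kind in ("fluctuating", "onset"):
        if period_T is None or period_T <= 0:
            raise ValueError(f"{kind} signal requires a positive period_T")
    if kind in ("single_shift", "onset"):
        if shift_time is None or shift_time < 0:
            raise ValueError(f"{kind} signal requires a non-negative shift_time")
        if shift_time >= duration:
            raise ValueError("shift_time must fall within the duration")
    if first_phase is None:
        # square waves default to starting in the high phase; a single
        # shift defaults to an upshift (starting low)
        first_phase = "low" if kind == "single_shift" else "high"
    if first_phase not in ("high", "low"):
        raise ValueError(f"unknown first_phase {first_phase!r}")
    return NutrientSignal(kind=kind, c_low=c_low, c_high=c_high,
                          duration=duration, period_T=period_T,
                          shift_time=shift_time, first_phase=first_phase,
                          steady_level=steady_level)
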