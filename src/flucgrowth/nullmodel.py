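"""Steady-state references and the single-shift null model.

The null model asks: what mean growth rate would cells achieve in a
fluctuating nutrient environment if they responded to every shift exactly
as they respond to a *single* shift from steady state?  The growth-rate
trajectory under a square-wave signal is assembled from the measured up-
and down-shift kernels under one of two assumptions:

Variant A (value matching)
    At an upshift the cell continues along the up kernel from the earliest
    time whose kernel value matches (or first exceeds) its current growth
    rate; at a downshift it drops to the start of the down kernel.

Variant B (clock reset)
    At every shift the corresponding kernel restarts from tau = 0,
    regardless of the current growth rate.

Both variants reduce to the single-shift curves when only one shift occurs,
and both approach the Jensen average G_J = (G_low + G_high)/2 as the
fluctuation period grows long relative to the transition times: the
per-period shortfall is bounded by (A_up + A_down)/T, where A_up and A_down
are the kernel deficit areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .kernels import KernelPair, ShiftKernel
from .signals import NutrientSignal

__all__ = [
    "display_round",
    "jensen_rate", "build_null", "predict_gfluc", "NullTrajectory",
    "NullModelPrediction", "biomass_projection", "fold_difference",
    "BiomassProjection", "paired_comparison", "ComparisonSummary",
    "fraction_of_predicted_loss",
]

S_PER_H = 3600.0
Variant = Literal["A_value_matching", "B_clock_reset"]


def display_round(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at a decimal precision (reporting style).

    Plain ``round`` acts on the binary representation, so e.g. the Jensen
    average of 1.07 and 2.86 (exactly 1.965 in decimal) would display as
    1.96; reported rates use the conventional half-up decimal rounding.
    """
    from decimal import Decimal, ROUND_HALF_UP
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(round(float(x), ndigits + 6))).quantize(
        q, rounding=ROUND_HALF_UP))


def jensen_rate(g_low: float, g_high: float) -> float:
    """Jensen average (G_low + G_high)/2: the long-period growth ceiling.

    For a concave rate-versus-concentration curve this is strictly below
    the rate at the average concentration (Jensen's inequality), and it is
    the best a cell alternating between the two steady states can do when
    it spends half its time at each.
    """
    if not (np.isfinite(g_low) and np.isfinite(g_high)):
        raise ValueError("rates must be finite")
    return 0.5 * (g_low + g_high)


@dataclass
class _Segment:
    t_start: float            # s
    t_end: float              # s
    kernel: Optional[ShiftKernel]   # None -> constant at `level`
    tau0: float = 0.0         # kernel time at t_start, s
    level: float = float("nan")

    def mu(self, t):
        if self.kernel is None:
            return np.full_like(np.asarray(t, float), self.level)
        return self.kernel(self.tau0 + np.asarray(t, float) - self.t_start)

    def mu_end(self) -> float:
        if self.kernel is None:
            return self.level
        return float(self.kernel(self.tau0 + self.t_end - self.t_start))

    def integral_h(self) -> float:
        """Integral of mu over the segment, in doublings."""
        if self.kernel is None:
            return self.level * (self.t_end - self.t_start) / S_PER_H
        return self.kernel.integral_h(self.tau0,
                                      self.tau0 + self.t_end - self.t_start)


class NullTrajectory:
    """Deterministic growth-rate trajectory mu(t) under a given signal."""

    def __init__(self, kernels: KernelPair, signal: NutrientSignal,
                 variant: Variant = "A_value_matching"):
        if variant not in ("A_value_matching", "B_clock_reset"):
            raise ValueError(f"unknown null-model variant {variant!r}")
        up, down = kernels.up, kernels.down
        if not np.isclose(up.g_start, down.g_end):
            raise ValueError("kernel endpoint mismatch: U(0) must equal "
                             "the down kernel's steady state")
        self.kernels = kernels
        self.signal = signal
        self.variant = variant
        self.segments: List[_Segment] = self._build()

    def _build(self) -> List[_Segment]:
        sig = self.signal
        up, down = self.kernels.up, self.kernels.down
        ups = set(np.round(sig.shift_times("up"), 9))
        downs = set(np.round(sig.shift_times("down"), 9))
        events = sorted(ups | downs)
        segs: List[_Segment] = []
        # initial state: steady at the level of the first phase
        if sig.kind in ("single_shift", "onset"):
            mu0 = self.kernels.g_low if sig.concentration(0.0) == sig.c_low \
                else self.kernels.g_high
        elif sig.kind == "steady":
            mu0 = {"low": self.kernels.g_low,
                   "average": jensen_rate(self.kernels.g_low,
                                          self.kernels.g_high),
                   "high": self.kernels.g_high}[sig.steady_level]
        else:  # fluctuating: the wave starts mid-cycle at a steady phase rate
            mu0 = self.kernels.g_high if sig.first_phase == "high" \
                else self.kernels.g_low
        t_prev = 0.0
        cur: _Segment = _Segment(0.0, sig.duration, None, level=mu0)
        segs.append(cur)
        for ev in events:
            if ev <= 0.0 or ev >= sig.duration:
                continue
            cur.t_end = ev
            mu_now = cur.mu_end()
            if ev in ups:
                if self.variant == "A_value_matching":
                    tau0 = up.value_match_tau(mu_now)
                else:
                    tau0 = 0.0
                cur = _Segment(ev, sig.duration, up, tau0=tau0)
            else:
                cur = _Segment(ev, sig.duration, down, tau0=0.0)
            segs.append(cur)
        return segs

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        starts = np.array([s.t_start for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
        out = np.empty_like(t, dtype=float)
        for i, seg in enumerate(self.segments):
            m = idx == i
            if m.any():
                out[m] = seg.mu(t[m])
        return out if out.ndim else float(out)

    def time_average(self, t0: float, t1: float,
                     samples_per_segment: int = 400) -> float:
        """Trapezoid time-average of mu over [t0, t1] (doublings/h)."""
        if t1 <= t0:
            raise ValueError("t1 must exceed t0")
        pts = [t0, t1]
        for s in self.segments:
            knots = [s.t_start, s.t_end]
            if s.kernel is not None:
                knots.append(s.t_start + s.kernel.t_complete - s.tau0)
            for b in knots:
                if t0 < b < t1:
                    pts.append(b)
        knots = np.sort(np.unique(pts))
        total = 0.0
        for a, b in zip(knots[:-1], knots[1:]):
            grid = np.linspace(a, b, samples_per_segment)
            total += np.trapezoid(self(grid), grid) / S_PER_H
        return total / ((t1 - t0) / S_PER_H)


def build_null(kernels: KernelPair,
               variant: Variant = "A_value_matching",
               ) -> Callable[[NutrientSignal], NullTrajectory]:
    """Return a factory mapping a nutrient signal to its null trajectory."""
    def factory(signal: NutrientSignal) -> NullTrajectory:
        return NullTrajectory(kernels, signal, variant)
    return factory


@dataclass
class NullModelPrediction:
    variant: Variant
    T_grid_s: np.ndarray
    predicted_G_fluc: np.ndarray     # doublings/h
    G_J: float
    periods_simulated: np.ndarray
    converged: np.ndarray
    kernels: KernelPair = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T_s": self.T_grid_s,
            "variant": self.variant,
            "predicted_G_fluc_per_h": self.predicted_G_fluc,
            "G_J_per_h": self.G_J,
            "periods_simulated": self.periods_simulated,
            "converged": self.converged,
        })


def _kernel_trapz_h(kernel: ShiftKernel, a_s: float, b_s: float,
                    samples: int) -> float:
    """Trapezoid integral of a kernel over [a, b] s, in doublings.

    The grid always resolves the transition: the part of [a, b] before the
    kernel completion time gets the full sample budget; past completion the
    kernel is constant and two samples suffice.
    """
    tc = kernel.t_complete
    total = 0.0
    if a_s < tc:
        hi = min(b_s, tc)
        grid = np.linspace(a_s, hi, samples)
        total += np.trapezoid(kernel(grid), grid) / S_PER_H
        a_s = hi
    if b_s > a_s:
        total += float(kernel(b_s)) * (b_s - a_s) / S_PER_H
    return total


def _period_average(kernels: KernelPair, variant: Variant, T_s: float,
                    mu_in: float, samples: int):
    """One square-wave period (high then low half): average and exit rate."""
    up, down = kernels.up, kernels.down
    half = T_s / 2.0
    tau0 = up.value_match_tau(mu_in) if variant == "A_value_matching" else 0.0
    int_high = _kernel_trapz_h(up, tau0, tau0 + half, samples)
    int_low = _kernel_trapz_h(down, 0.0, half, samples)
    mu_out = float(down(half))
    avg = (int_high + int_low) / (T_s / S_PER_H)
    return avg, mu_out


def predict_gfluc(kernels: KernelPair,
                  variant: Variant = "A_value_matching",
                  T_grid_s: Sequence[float] = (30.0, 300.0, 900.0, 3600.0,
                                               12 * 3600.0, 96 * 3600.0),
                  tol: float = 1e-6,
                  max_periods: int = 200,
                  samples_per_period: int = 401,
                  ) -> NullModelPrediction:
    """Predict G_fluc across fluctuation periods from single-shift kernels.

    For each period T the square-wave trajectory is iterated period by
    period until the per-period time-average changes by less than ``tol``
    doublings/h (at most ``max_periods`` periods, non-convergence recorded,
    not silent); the prediction is the converged per-period average,
    computed by trapezoid quadrature with at least ``samples_per_period``
    samples per period.
    """
    T_grid = np.asarray(T_grid_s, dtype=float)
    if np.any(T_grid <= 0):
        raise ValueError("fluctuation periods must be positive")
    g_j = jensen_rate(kernels.g_low, kernels.g_high)
    preds = np.empty_like(T_grid)
    periods = np.zeros(len(T_grid), dtype=int)
    converged = np.zeros(len(T_grid), dtype=bool)
    samples = max(201, samples_per_period) // 2 + 1
    for i, T in enumerate(T_grid):
        mu = kernels.g_low   # enter the first high phase from steady low
        prev = np.inf
        for p in range(1, max_periods + 1):
            avg, mu = _period_average(kernels, variant, T, mu, samples)
            periods[i] = p
            if abs(avg - prev) < tol:
                converged[i] = True
                break
            prev = avg
        preds[i] = avg
    return NullModelPrediction(variant, T_grid, preds, g_j, periods,
                               converged, kernels)


@dataclass(frozen=True)
class BiomassProjection:
    M0: float      # µm³
    G: float       # doublings/h
    t_h: float     # h
    M: float       # µm³


def biomass_projection(M0: float, G: float, t_h: float) -> BiomassProjection:
    """Exponential biomass projection M(t) = M0 * 2^(G t)."""
    if M0 <= 0:
        raise ValueError("initial biomass must be positive")
    if t_h < 0:
        raise ValueError("time must be non-negative")
    return BiomassProjection(M0, G, t_h, M0 * 2.0 ** (G * t_h))


def fold_difference(G1: float, G2: float, t_h: float) -> float:
    """Biomass ratio 2^((G2 - G1) t) accumulated between two growth rates."""
    if t_h < 0:
        raise ValueError("time must be non-negative")
    return 2.0 ** ((G2 - G1) * t_h)


@dataclass
class ComparisonSummary:
    reference: str
    per_day: pd.DataFrame        # replicate_day, G_fluc, G_ref, pct_diff
    mean_pct_diff: float
    sd_pct_diff: float


def paired_comparison(per_day_rates: pd.DataFrame,
                      reference: Literal["G_ave", "G_J", "G_low"] = "G_ave",
                      ) -> ComparisonSummary:
    """Same-day percent differences of G_fluc against a steady reference.

    ``per_day_rates`` has one row per replicate day with columns
    ``replicate_day``, ``G_fluc`` and the reference columns (``G_ave``,
    ``G_low``, ``G_high`` as applicable).  Percent differences
    (G_fluc - G_ref)/G_ref * 100 are computed within each day *before*
    averaging across days, which removes shared day-to-day variability; for
    the G_J reference the Jensen average is computed from that day's G_low
    and G_high.
    """
    df = per_day_rates.copy()
    if reference == "G_J":
        if not {"G_low", "G_high"}.issubset(df.columns):
            raise ValueError("G_J reference requires per-day G_low and G_high")
        df["G_ref"] = 0.5 * (df["G_low"] + df["G_high"])
    else:
        if reference not in df.columns:
            raise ValueError(f"missing reference column {reference}")
        df["G_ref"] = df[reference]
    df = df.dropna(subset=["G_fluc", "G_ref"])
    if len(df) == 0:
        raise ValueError("no complete day-pairs")
    df["pct_diff"] = (df["G_fluc"] - df["G_ref"]) / df["G_ref"] * 100.0
    keep = [c for c in ("replicate_day", "G_fluc", "G_ref", "pct_diff")
            if c in df.columns]
    pct = df["pct_diff"].to_numpy(float)
    sd = float(pct.std(ddof=1)) if len(pct) > 1 else 0.0
    return ComparisonSummary(reference, df[keep].reset_index(drop=True),
                             float(pct.mean()), sd)


def fraction_of_predicted_loss(G_ave: float, G_fluc_measured: float,
                               G_fluc_predicted: float) -> float:
    """Measured growth loss as a percentage of the null-predicted loss.

    100 * (G_ave - G_fluc_measured) / (G_ave - G_fluc_predicted); below
    100% means cells lose less growth than single-shift responses predict.
    """
    loss_pred = G_ave - G_fluc_predicted
    if loss_pred <= 0:
        raise ValueError("predicted loss must be positive")
    return 100.0 * (G_ave - G_fluc_measured) / loss_pred
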