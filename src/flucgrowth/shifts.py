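"""Shift-aligned growth dynamics and stabilization detection.

Growth points are re-indexed by the time since a nutrient shift (tau = 0 at
the shift), pooled across shifts and cells, and binned.  Stabilization of
the mean growth curve is detected with a shrinking-window statistic: fit a
least-squares line to the bins from a candidate start k to the *end* of the
curve, shrink the window from the left one bin at a time, and declare the
growth rate stabilized at the first start from which the zero-slope
criterion holds for every later start as well.  Two zero-slope rules are
provided: ``tol`` (|slope| below a tolerance) and ``ci`` (the 95% confidence
interval of the slope contains zero; when per-bin SEMs are available the
interval uses them as known measurement errors, which keeps curve shape
misfit from inflating the interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .growth import _binned, _sampling_interval
from .signals import NutrientSignal

__all__ = [
    "ShiftResponseCurve", "StabilizationParams", "StabilizationResult",
    "OnsetResult", "align_to_shifts", "detect_stabilization",
    "initial_response", "onset_analysis",
]

S_PER_H = 3600.0
EQUILIBRATION_WINDOW_S = 3 * 3600.0


@dataclass
class ShiftResponseCurve:
    """Mean growth rate versus time since a nutrient shift."""

    direction: Literal["up", "down"]
    tau_s: np.ndarray         # bin centers, s (first bin may be pre-shift)
    mean_mu: np.ndarray       # doublings/h
    sem: np.ndarray
    n: np.ndarray
    bin_width: float          # s
    source: str = "single_shift"
    pre_shift_mu: float = float("nan")
    n_shifts: int = 1

    def post_shift(self) -> "ShiftResponseCurve":
        m = self.tau_s > 0
        return ShiftResponseCurve(self.direction, self.tau_s[m],
                                  self.mean_mu[m], self.sem[m], self.n[m],
                                  self.bin_width, self.source,
                                  self.pre_shift_mu, self.n_shifts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tau_s": self.tau_s, "mean_mu_per_h": self.mean_mu,
            "sem_per_h": self.sem, "n": self.n,
        })


@dataclass(frozen=True)
class StabilizationParams:
    """Parameters of the shrinking-window zero-slope detector."""

    min_window_points: int = 4
    rule: Literal["tol", "ci"] = "ci"
    slope_tol: float = 0.5        # h^-1 per h, for rule="tol"
    confidence: float = 0.95      # for rule="ci"


@dataclass
class StabilizationResult:
    stabilized: bool
    stabilization_time_min: Optional[float]   # minutes since the shift
    stabilized_value: Optional[float]         # doublings/h
    window_start_index: Optional[int]
    slope_at_stabilization: Optional[float]   # h^-1 per h
    params: StabilizationParams = field(default_factory=StabilizationParams)


def align_to_shifts(points: pd.DataFrame,
                    signal: NutrientSignal,
                    direction: Literal["up", "down"],
                    bin_width: Optional[float] = None,
                    equilibration_window: float = EQUILIBRATION_WINDOW_S,
                    ) -> ShiftResponseCurve:
    """Pool growth points around every qualifying shift of one direction.

    Points are re-indexed by tau = t - t_shift, kept from one pre-shift bin
    up to the next shift (half a period for fluctuating/onset signals, the
    end of the record for a single shift), binned at ``bin_width`` (default:
    the sampling interval) and averaged across all pooled shifts and cells.
    For fluctuating signals only shifts after the equilibration window are
    pooled, mirroring the steady-state averaging window.
    """
    shifts = signal.shift_times(direction)
    if signal.kind == "fluctuating":
        horizon = signal.period_T / 2.0
        shifts = shifts[(shifts >= equilibration_window)
                        & (shifts + horizon <= signal.duration)]
        source = "fluctuation_pooled"
    elif signal.kind == "onset":
        horizon = signal.period_T / 2.0
        shifts = shifts[shifts + horizon <= signal.duration]
        source = "onset_pooled"
    else:
        source = "single_shift"
    if len(shifts) == 0:
        raise ValueError(f"signal has no qualifying '{direction}' shifts")
    pts = points[points["valid"]]
    if bin_width is None:
        bin_width = _sampling_interval(pts)
    t = pts["t_mid_s"].to_numpy(float)
    mu = pts["mu_per_h"].to_numpy(float)
    tau_all, mu_all = [], []
    horizons = []
    for ts in np.atleast_1d(shifts):
        hor = (signal.duration - ts) if signal.kind == "single_shift" \
            else horizon
        horizons.append(hor)
        tau = t - ts
        m = (tau >= -bin_width) & (tau < hor)
        tau_all.append(tau[m])
        mu_all.append(mu[m])
    tau = np.concatenate(tau_all)
    muv = np.concatenate(mu_all)
    if len(tau) == 0:
        raise ValueError("no growth points near the requested shifts")
    # the curve ends at the last *complete* bin before the next shift (or
    # record end); a trailing partial bin would mix across the shift
    hi = np.floor(min(horizons) / bin_width) * bin_width
    edges = np.arange(-bin_width, hi + bin_width / 2, bin_width)
    centers, mean, sem, n = _binned(muv, tau, edges)
    pre_mask = (tau >= -bin_width) & (tau < 0)
    pre = float(muv[pre_mask].mean()) if pre_mask.any() else float("nan")
    return ShiftResponseCurve(direction, centers, mean, sem, n,
                              float(bin_width), source, pre,
                              n_shifts=len(np.atleast_1d(shifts)))


def _suffix_slopes(x: np.ndarray, y: np.ndarray):
    """OLS slope and residual-based stderr for every suffix window y[k:]."""
    n = len(x)
    # suffix sums via reversed cumulative sums
    rs = lambda a: np.cumsum(a[::-1])[::-1]
    S1 = rs(np.ones(n))
    Sx, Sy = rs(x), rs(y)
    Sxx, Sxy, Syy = rs(x * x), rs(x * y), rs(y * y)
    vx = Sxx - Sx * Sx / S1
    cov = Sxy - Sx * Sy / S1
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cov / vx
        sse = Syy - Sy * Sy / S1 - slope * cov
        sse = np.clip(sse, 0.0, None)
        sigma2 = sse / np.clip(S1 - 2, 1, None)
        stderr = np.sqrt(sigma2 / vx)
    return slope, stderr, S1


def _suffix_weighted_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted slope and known-error stderr for every suffix window."""
    rs = lambda a: np.cumsum(a[::-1])[::-1]
    Sw = rs(w)
    Swx, Swy = rs(w * x), rs(w * y)
    Swxx, Swxy = rs(w * x * x), rs(w * x * y)
    vx = Swxx - Swx * Swx / Sw
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (Swxy - Swx * Swy / Sw) / vx
        stderr = np.sqrt(1.0 / vx)
    return slope, stderr


def detect_stabilization(curve: ShiftResponseCurve,
                         params: Optional[StabilizationParams] = None,
                         ) -> StabilizationResult:
    """Shrinking-window zero-slope stabilization detection.

    Windows always end at the last available bin and shrink from the left.
    The stabilization index is the smallest start k whose zero-slope
    criterion holds and keeps holding for every later start; the
    stabilization time is the bin center at k (minutes after the shift) and
    the stabilized value is the point-weighted mean over bins k..end.
    """
    params = params or StabilizationParams()
    post = curve.post_shift()
    m = len(post.tau_s)
    if m < params.min_window_points:
        raise ValueError(
            f"need at least {params.min_window_points} post-shift bins, "
            f"got {m}")
    x = post.tau_s / S_PER_H
    y = post.mean_mu
    n_starts = m - params.min_window_points + 1
    slope_ols, stderr_ols, _ = _suffix_slopes(x, y)
    if params.rule == "tol":
        ok = np.abs(slope_ols[:n_starts]) <= params.slope_tol
        slopes = slope_ols
    elif params.rule == "ci":
        sem = post.sem
        use_w = np.all(np.isfinite(sem)) and np.all(sem > 0)
        # the persistence requirement makes this a joint test over all
        # scanned windows: Bonferroni-correct the per-window level so the
        # family-wise confidence stays at `confidence`
        alpha_w = (1.0 - params.confidence) / n_starts
        if use_w:
            slope, stderr = _suffix_weighted_slopes(x, y, 1.0 / sem ** 2)
            crit = stats.norm.ppf(1.0 - alpha_w / 2.0)
        else:
            slope, stderr = slope_ols, stderr_ols
            dof = np.clip(np.arange(m, 0, -1) - 2, 1, None)
            crit = stats.t.ppf(1.0 - alpha_w / 2.0, dof)
        # numerical floor: a perfect fit must not reject a ~0 slope
        half = np.maximum(crit * stderr, 1e-9)
        ok = np.abs(slope[:n_starts]) <= np.atleast_1d(half)[:n_starts]
        slopes = slope
    else:
        raise ValueError(f"unknown rule {params.rule!r}")
    # persistence: criterion must hold for this start and every later one
    holds_from = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.argmax(holds_from) if holds_from.any() else None
    if idx is None or not holds_from[idx]:
        return StabilizationResult(False, None, None, None, None, params)
    value = float(np.sum(post.mean_mu[idx:] * post.n[idx:])
                  / np.sum(post.n[idx:]))
    return StabilizationResult(
        stabilized=True,
        stabilization_time_min=float(post.tau_s[idx] / 60.0),
        stabilized_value=value,
        window_start_index=int(idx),
        slope_at_stabilization=float(slopes[idx]),
        params=params,
    )


def initial_response(curve: ShiftResponseCurve,
                     window_s: float = 7.5 * 60.0) -> float:
    """Signed percent change of growth rate over the first minutes post-shift.

    100 * (mean mu over (0, window] - pre-shift mu) / pre-shift mu, with the
    pre-shift reference taken from the single bin just before the shift.
    """
    pre = curve.pre_shift_mu
    if not np.isfinite(pre) or pre == 0:
        raise ValueError("pre-shift growth rate unavailable or zero")
    m = (curve.tau_s > 0) & (curve.tau_s <= window_s)
    if not m.any():
        raise ValueError("no bins within the post-shift window")
    post = float(np.sum(curve.mean_mu[m] * curve.n[m]) / np.sum(curve.n[m]))
    return 100.0 * (post - pre) / pre


@dataclass
class OnsetResult:
    period_curves: List[ShiftResponseCurve]
    period_stats: pd.DataFrame
    convergence_period: Optional[int]


def onset_analysis(points: pd.DataFrame,
                   signal: NutrientSignal,
                   bin_width: Optional[float] = None,
                   convergence_tol: float = 0.05,
                   ) -> OnsetResult:
    """Per-period overlays and stabilization of the onset-of-fluctuations run.

    Periods are counted from the first upshift (period 1); period 0 is the
    one period of steady low nutrient preceding it.  The convergence period
    is the first period p >= 1 from which the whole-period mean growth rate
    changes by at most ``convergence_tol`` (relative) between every later
    pair of consecutive periods; ``None`` if the means keep drifting.
    """
    from .growth import phase_period_stats
    if signal.kind != "onset":
        raise ValueError("onset analysis requires an onset signal")
    T = float(signal.period_T)
    origin = float(signal.shift_time)
    n_periods = int(np.floor((signal.duration - origin) / T))
    if n_periods < 3:
        raise ValueError("need at least 3 full periods after the onset")
    pts = points[points["valid"]]
    if bin_width is None:
        bin_width = _sampling_interval(pts)
    t = pts["t_mid_s"].to_numpy(float)
    mu = pts["mu_per_h"].to_numpy(float)
    curves: List[ShiftResponseCurve] = []
    edges = np.arange(0.0, T + bin_width / 2, bin_width)
    for p in range(0, n_periods + 1):
        start = origin + (p - 1) * T
        m = (t >= start) & (t < start + T)
        if not m.any():
            continue
        centers, mean, sem, n = _binned(mu[m], t[m] - start, edges)
        curves.append(ShiftResponseCurve(
            "up", centers, mean, sem, n, float(bin_width),
            source=f"onset_period_{p}", n_shifts=1))
    stats_df = phase_period_stats(points, signal)
    per = stats_df[stats_df["period_index"] >= 1].sort_values("period_index")
    mt = per["mean_T"].to_numpy(float)
    pidx = per["period_index"].to_numpy(int)
    conv: Optional[int] = None
    diffs_ok = np.abs(np.diff(mt)) <= convergence_tol * np.abs(mt[1:])
    for i in range(len(mt) - 1):
        if diffs_ok[i:].all():
            conv = int(pidx[i])
            break
    return OnsetResult(curves, stats_df, conv)
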