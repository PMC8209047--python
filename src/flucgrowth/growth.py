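"""Instantaneous single-cell growth rates and binned growth statistics.

Growth rate is defined as the exponential rate at which cell volume doubles:
from V(t + dt) = V(t) * 2^(mu * dt),

    mu = (ln V(t+dt) - ln V(t)) / (dt * ln 2)      [doublings / h]

computed between every consecutive pair of frames of a track.  Intervals in
which the volume drops by more than the division threshold are division
events: the retained daughter is roughly half the mother's volume, so the
interval does not measure growth and is excluded from valid points.  Each
estimate is assigned to the interval midpoint.

Binned statistics pool *all* valid single-cell estimates (per-point pooling,
every valid interval weighted equally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .qc import volume_from_dims
from .signals import NutrientSignal

__all__ = [
    "growth_points", "instantaneous_mu", "bin_mean", "steady_state_rate",
    "phase_fold", "phase_period_stats", "assign_phase", "GrowthCurve",
    "SteadyStateRate", "DIVISION_DROP", "DEFAULT_WINDOW_START_S",
]

LN2 = np.log(2.0)
S_PER_H = 3600.0
#: relative volume drop between frames classified as a division event
DIVISION_DROP = 0.25
#: steady-state averaging window start (growth stabilizes within 3 h)
DEFAULT_WINDOW_START_S = 3 * 3600.0


@dataclass
class GrowthCurve:
    """Mean growth rate per time (or phase-time) bin."""

    bin_centers: np.ndarray   # s
    mean_mu: np.ndarray       # doublings/h
    sem: np.ndarray           # doublings/h
    n: np.ndarray             # points per bin
    bin_width: float          # s
    kind: str = "time"        # "time" | "phase"
    under_resolved: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_s": self.bin_centers,
            "mean_mu_per_h": self.mean_mu,
            "sem_per_h": self.sem,
            "n": self.n,
        })

    @property
    def overall_mean(self) -> float:
        """Point-weighted mean across bins (equals the pooled mean)."""
        return float(np.sum(self.mean_mu * self.n) / np.sum(self.n))


@dataclass(frozen=True)
class SteadyStateRate:
    condition: str
    G: float                 # doublings/h
    sem: float
    n_points: int
    n_cells: int
    window_start: float      # s
    replicate_day: str = ""


def instantaneous_mu(times_s: np.ndarray, volumes: np.ndarray,
                     division_drop: float = DIVISION_DROP):
    """Per-interval growth rates for one track.

    Returns ``(t_mid_s, mu_per_h, is_division)`` arrays of length n-1.
    Raises on non-positive volumes or fewer than two frames.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if len(t) < 2:
        raise ValueError("a track needs at least two frames")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    dlnv = np.diff(np.log(v))
    dt_h = np.diff(t) / S_PER_H
    mu = dlnv / (LN2 * dt_h)
    is_division = np.expm1(dlnv) <= -division_drop
    t_mid = t[:-1] + np.diff(t) / 2.0
    return t_mid, mu, is_division


def growth_points(table: pd.DataFrame,
                  division_drop: float = DIVISION_DROP) -> pd.DataFrame:
    """Instantaneous growth rates for every track of a track table.

    Returns a points table with columns ``track_id, t_mid_s, dt_s,
    mu_per_h, division, valid`` (plus ``condition``/``replicate_day`` labels
    when present).  ``valid`` excludes division intervals.
    """
    t = table.sort_values(["track_id", "time_s"]).reset_index(drop=True)
    v = volume_from_dims(t["length_um"].to_numpy(float),
                         t["width_um"].to_numpy(float))
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    tid = t["track_id"].to_numpy()
    time = t["time_s"].to_numpy(float)
    lnv = np.log(v)
    same = tid[1:] == tid[:-1]
    dln = (lnv[1:] - lnv[:-1])[same]
    dt = (time[1:] - time[:-1])[same]
    mid = (time[1:] + time[:-1])[same] / 2.0
    mu = dln / (LN2 * dt / S_PER_H)
    division = np.expm1(dln) <= -division_drop
    out = pd.DataFrame({
        "track_id": tid[:-1][same],
        "t_mid_s": mid,
        "dt_s": dt,
        "mu_per_h": mu,
        "division": division,
        "valid": ~division,
    })
    for col in ("condition", "replicate_day"):
        if col in t.columns:
            out[col] = t[col].to_numpy()[:-1][same]
    return out


def assign_phase(points: pd.DataFrame, signal: NutrientSignal) -> pd.DataFrame:
    """Attach the nutrient phase at each point's interval midpoint."""
    points = points.copy()
    points["phase"] = signal.phase(points["t_mid_s"].to_numpy(float))
    return points


def _binned(values: np.ndarray, t: np.ndarray, edges: np.ndarray):
    idx = np.digitize(t, edges) - 1
    ok = (idx >= 0) & (idx < len(edges) - 1)
    idx, values = idx[ok], values[ok]
    n = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=values, minlength=len(edges) - 1)
    sq = np.bincount(idx, weights=values ** 2, minlength=len(edges) - 1)
    present = n > 0
    mean = np.full(len(n), np.nan)
    mean[present] = sums[present] / n[present]
    var = np.full(len(n), np.nan)
    m2 = n > 1
    var[m2] = (sq[m2] - n[m2] * mean[m2] ** 2) / (n[m2] - 1)
    with np.errstate(invalid="ignore"):
        sem = np.sqrt(np.where(m2, var, np.nan) / np.where(m2, n, 1))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers[present], mean[present], sem[present], n[present]


def bin_mean(points: pd.DataFrame, bin_width: float) -> GrowthCurve:
    """Arithmetic mean of all valid points per time bin of ``bin_width`` s.

    Empty bins are absent from the result, not reported as zero.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pts = points[points["valid"]]
    if len(pts) == 0:
        raise ValueError("no valid growth points")
    t = pts["t_mid_s"].to_numpy(float)
    mu = pts["mu_per_h"].to_numpy(float)
    lo = np.floor(t.min() / bin_width) * bin_width
    hi = np.ceil((t.max() + 1e-9) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers, mean, sem, n = _binned(mu, t, edges)
    return GrowthCurve(centers, mean, sem, n, bin_width, kind="time")


def steady_state_rate(points: pd.DataFrame,
                      window_start: float = DEFAULT_WINDOW_START_S,
                      condition: str = "",
                      replicate_day: str = "") -> SteadyStateRate:
    """Pooled mean of all valid growth rates measured at t >= window_start.

    The steady-state rate G averages every valid single-cell estimate after
    the equilibration window (3 h by default).
    """
    if window_start < 0:
        raise ValueError("window_start must be non-negative")
    pts = points[points["valid"] & (points["t_mid_s"] >= window_start)]
    if len(pts) == 0:
        raise ValueError("no valid growth points after window_start")
    mu = pts["mu_per_h"].to_numpy(float)
    n = len(mu)
    sem = float(mu.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return SteadyStateRate(
        condition=condition or (str(pts["condition"].iloc[0])
                                if "condition" in pts else ""),
        G=float(mu.mean()), sem=sem, n_points=n,
        n_cells=int(pts["track_id"].nunique()),
        window_start=float(window_start),
        replicate_day=replicate_day or (str(pts["replicate_day"].iloc[0])
                                        if "replicate_day" in pts else ""),
    )


def _sampling_interval(points: pd.DataFrame) -> float:
    return float(np.nanmedian(points["dt_s"].to_numpy(float)))


def phase_fold(points: pd.DataFrame, signal: NutrientSignal,
               bin_width: Optional[float] = None,
               t_min: float = 0.0) -> GrowthCurve:
    """Fold valid points onto one nutrient period and bin the means.

    Each point is assigned phase-time ``(t_mid - fold_origin) mod T``; for
    onset signals the fold origin is the onset time, otherwise t = 0.  The
    curve is flagged ``under_resolved`` when the sampling interval exceeds
    half the period (fluctuations faster than the imaging cadence cannot be
    resolved).
    """
    if signal.kind not in ("fluctuating", "onset"):
        raise ValueError("phase folding requires a fluctuating or onset signal")
    if signal.period_T is None:
        raise ValueError("signal period missing")
    T = float(signal.period_T)
    origin = float(signal.shift_time) if signal.kind == "onset" else 0.0
    pts = points[points["valid"] & (points["t_mid_s"] >= max(origin, t_min))]
    if len(pts) == 0:
        raise ValueError("no valid points to fold")
    if bin_width is None:
        bin_width = min(_sampling_interval(pts), T / 2.0)
    n_bins = max(1, int(round(T / bin_width)))
    edges = np.linspace(0.0, T, n_bins + 1)
    tau = np.mod(pts["t_mid_s"].to_numpy(float) - origin, T)
    centers, mean, sem, n = _binned(pts["mu_per_h"].to_numpy(float),
                                    tau, edges)
    under = _sampling_interval(pts) > T / 2.0
    return GrowthCurve(centers, mean, sem, n, T / n_bins, kind="phase",
                       under_resolved=under)


def phase_period_stats(points: pd.DataFrame, signal: NutrientSignal
                       ) -> pd.DataFrame:
    """Per-period half-period mean growth rates.

    For each full nutrient period p the mean over the high half (t_high),
    the low half (t_low) and the whole period (T) is reported.  For onset
    signals period 0 is the one period of steady low nutrient preceding the
    first upshift, and period 1 starts at the onset.
    """
    if signal.kind not in ("fluctuating", "onset"):
        raise ValueError("per-period statistics require fluctuating or onset")
    if signal.period_T is None:
        raise ValueError("signal period missing")
    T = float(signal.period_T)
    origin = float(signal.shift_time) if signal.kind == "onset" else 0.0
    pts = points[points["valid"]].copy()
    if len(pts) == 0:
        raise ValueError("no valid points")
    t = pts["t_mid_s"].to_numpy(float)
    mu = pts["mu_per_h"].to_numpy(float)
    rows = []
    if signal.kind == "onset":
        m0 = (t >= origin - T) & (t < origin)
        if m0.any():
            rows.append({"period_index": 0, "mean_t_high": np.nan,
                         "n_high": 0, "mean_t_low": float(mu[m0].mean()),
                         "n_low": int(m0.sum()),
                         "mean_T": float(mu[m0].mean()),
                         "n": int(m0.sum())})
        first = 1
    else:
        first = 1
    n_periods = int(np.floor((signal.duration - origin) / T))
    high_first = (signal.first_phase == "high") or signal.kind == "onset"
    for p in range(first, n_periods + 1):
        lo_t = origin + (p - 1) * T
        m = (t >= lo_t) & (t < lo_t + T)
        if not m.any():
            continue
        tau = t[m] - lo_t
        in_first = tau < T / 2.0
        m_high = in_first if high_first else ~in_first
        mu_p = mu[m]
        rows.append({
            "period_index": p,
            "mean_t_high": float(mu_p[m_high].mean()) if m_high.any()
            else np.nan,
            "n_high": int(m_high.sum()),
            "mean_t_low": float(mu_p[~m_high].mean()) if (~m_high).any()
            else np.nan,
            "n_low": int((~m_high).sum()),
            "mean_T": float(mu_p.mean()),
            "n": int(m.sum()),
        })
    if not rows:
        raise ValueError("no complete periods covered by the points")
    return pd.DataFrame(rows)
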