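"""Synthetic single-cell track generation.

The generator emulates the measurement process of a nutrient-control
microfluidic experiment: surface-attached cells grow their volume
exponentially at an instantaneous rate mu(t) set by the nutrient signal and
the chosen growth physiology, divide by an adder rule (divide after adding
a roughly constant volume since birth, one daughter retained), and are
imaged every 117 s, with length and width emitted under multiplicative
measurement noise.  Tracks have finite lifetimes and a per-day multiplicative
rate effect shared by all conditions run on the same day.

Three physiologies are selectable:

``instantaneous``
    mu(t) follows the steady-state map of the momentary concentration
    (growth responds to nutrient level with no memory).
``single_shift_kernel``
    mu(t) follows the single-shift null-model trajectory assembled from the
    up/down response kernels (cells re-run a steady-state transition at
    every shift).
``fluctuation_adapted``
    mu(t) jumps within a short lag to stabilized phase rates below the
    corresponding steady states; in onset signals the behavior blends from
    the single-shift trajectory to the stabilized one over a configurable
    number of periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .kernels import KernelPair
from .nullmodel import NullTrajectory
from .qc import length_from_volume
from .signals import NutrientSignal
from .steadymap import SteadyStateMap

__all__ = ["SimConfig", "SimResult", "simulate_tracks",
           "simulate_experiment", "draw_day_factors"]

S_PER_H = 3600.0


@dataclass
class SimConfig:
    """Parameters of the synthetic acquisition and growth process.

    Field-name suffixes carry the units.  Defaults reflect the emulated
    acquisition (117 s imaging cadence, ~40-frame track lifetimes) and
    modest measurement/heterogeneity noise: 2% multiplicative size noise,
    10% cell-to-cell rate variation, 8% day-to-day rate variation.
    """

    seed: int = 0
    physiology: str = "instantaneous"
    n_cells: int = 200
    frame_interval_s: float = 117.0
    size_noise_sd: float = 0.02
    cell_rate_sd: float = 0.10
    mean_track_frames: float = 40.0
    day_effect_sd: float = 0.08
    # adder division rule
    added_volume_mean_um3: float = 2.0
    division_asymmetry_sd: float = 0.1
    initial_volume_um3: Optional[float] = None
    # cell geometry for emitting (length, width) pairs
    width_um: float = 0.9
    width_cell_sd: float = 0.05
    # equilibration transient after loading into the device
    equilibration_enabled: bool = True
    equilibration_initial_fraction: float = 0.5
    equilibration_timescale_s: float = 3600.0
    # fluctuation-adapted physiology
    stabilized_up_rate: float = 1.86     # doublings/h after each upshift
    stabilized_down_rate: float = 0.60   # doublings/h after each downshift
    adaptation_lag_s: float = 120.0
    adaptation_periods: int = 3
    null_variant: str = "A_value_matching"
    integration_dt_s: float = 1.0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        for name in ("size_noise_sd", "cell_rate_sd", "day_effect_sd",
                     "division_asymmetry_sd", "width_cell_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.initial_volume_um3 is not None \
                and self.initial_volume_um3 <= 0:
            raise ValueError("initial volume must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimResult:
    """A simulated track table plus its generating ground truth."""

    table: pd.DataFrame
    truth: pd.DataFrame
    mu_base: Callable[[np.ndarray], np.ndarray]  # population rate, no noise
    signal: NutrientSignal
    config: SimConfig


def _lognormal_factor(rng: np.random.Generator, sd: float, size=None):
    """Multiplicative factor with mean exactly 1 and relative spread ~sd."""
    if sd == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(sd ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=size)


def draw_day_factors(n_days: int, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-day multiplicative rate effects, shared across same-day conditions."""
    return np.atleast_1d(_lognormal_factor(rng, sd, size=n_days))


class _AdaptedMu:
    """Stabilized phase rates with a short linear ramp after each shift."""

    def __init__(self, signal: NutrientSignal, config: SimConfig,
                 g_pre: float):
        T = float(signal.period_T)
        half = T / 2.0
        origin = float(signal.shift_time) if signal.kind == "onset" else 0.0
        r_hi, r_lo = config.stabilized_up_rate, config.stabilized_down_rate
        self.lag = float(config.adaptation_lag_s)
        self.g_pre = g_pre
        self.origin = origin
        times: List[float] = []
        targets: List[float] = []
        if signal.kind == "onset":
            k = 0
            t = origin
            while t < signal.duration:
                times.append(t)
                targets.append(r_hi if k % 2 == 0 else r_lo)
                k += 1
                t = origin + k * half
            self.value0 = g_pre
        else:
            first_hi = signal.first_phase == "high"
            self.value0 = r_hi if first_hi else r_lo
            k = 1
            t = half
            while t < signal.duration:
                times.append(t)
                hi_phase = (k % 2 == 0) if first_hi else (k % 2 == 1)
                targets.append(r_hi if hi_phase else r_lo)
                k += 1
                t = k * half
        self.times = np.asarray(times)
        self.targets = np.asarray(targets)
        self.prevs = np.concatenate([[self.value0], self.targets[:-1]]) \
            if len(self.targets) else np.array([])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.value0)
        if len(self.times):
            idx = np.searchsorted(self.times, t, side="right") - 1
            has = idx >= 0
            i = np.clip(idx, 0, None)
            dt = t - self.times[i]
            ramp = np.clip(dt / self.lag, 0.0, 1.0) if self.lag > 0 else 1.0
            v = self.prevs[i] + (self.targets[i] - self.prevs[i]) * ramp
            out = np.where(has, v, out)
        if self.origin > 0:
            out = np.where(t < self.origin, self.g_pre, out)
        return out

    def breakpoints(self) -> np.ndarray:
        b = [self.origin] if self.origin > 0 else []
        for ts in self.times:
            b.extend([ts, ts + self.lag])
        return np.asarray(b)


def _build_mu_base(signal: NutrientSignal, config: SimConfig,
                   steady_map: Optional[SteadyStateMap],
                   kernels: Optional[KernelPair],
                   ) -> Tuple[Callable, np.ndarray, bool]:
    """Population-level mu(t) (doublings/h), its breakpoints, and whether
    the equilibration transient applies to this physiology."""
    phys = config.physiology
    if phys == "instantaneous":
        if steady_map is None:
            raise ValueError("instantaneous physiology requires a steady map")
        mu = lambda t: steady_map.rate(signal.concentration(t))
        return mu, signal.shift_times(), True
    if phys == "single_shift_kernel":
        if kernels is None:
            raise ValueError("single_shift_kernel physiology requires kernels")
        traj = NullTrajectory(kernels, signal, config.null_variant)
        bp = []
        for s in traj.segments:
            bp.append(s.t_start)
            if s.kernel is not None:
                bp.append(s.t_start + s.kernel.t_complete - s.tau0)
        # the kernels already encode the transition; no extra equilibration
        return traj, np.asarray(bp), False
    if phys == "fluctuation_adapted":
        if signal.kind not in ("fluctuating", "onset"):
            raise ValueError("fluctuation_adapted physiology requires a "
                             "fluctuating or onset signal")
        g_pre = kernels.g_low if kernels is not None else 1.07
        adapted = _AdaptedMu(signal, config, g_pre)
        if signal.kind == "onset":
            if kernels is None:
                raise ValueError("onset simulation requires kernels for the "
                                 "pre-adaptation response")
            traj = NullTrajectory(kernels, signal, config.null_variant)
            T = float(signal.period_T)
            origin = float(signal.shift_time)
            n_adapt = max(1, int(config.adaptation_periods))

            def mu(t, _traj=traj, _ad=adapted):
                t = np.asarray(t, dtype=float)
                period = np.floor((t - origin) / T) + 1
                w = np.clip((period - 1) / max(n_adapt - 1, 1), 0.0, 1.0) \
                    if n_adapt > 1 else np.ones_like(t)
                out = (1 - w) * np.asarray(_traj(t)) \
                    + w * np.asarray(_ad(t))
                return np.where(t < origin, g_pre, out)

            bp = np.concatenate([
                adapted.breakpoints(),
                [s.t_start for s in traj.segments],
                origin + T * np.arange(0, int((signal.duration - origin) / T)
                                       + 1),
            ])
            return mu, bp, True
        return adapted, adapted.breakpoints(), True
    raise ValueError(f"unknown physiology {phys!r}")


def _equilibration(t: np.ndarray, config: SimConfig) -> np.ndarray:
    f0 = config.equilibration_initial_fraction
    tau = config.equilibration_timescale_s
    return 1.0 - (1.0 - f0) * np.exp(-np.asarray(t, float) / tau)


def _cumulative_doublings(mu: Callable, breakpoints: np.ndarray,
                          duration: float, config: SimConfig,
                          equilibrate: bool):
    """Grid times and cumulative base doublings I(t) = int mu dt (midpoint).

    Breakpoints are grid knots, so the midpoint rule is exact for
    piecewise-constant mu and the cumulative integral is piecewise-linear,
    making linear interpolation of I(t) exact in that case.
    """
    dt = config.integration_dt_s
    grid = np.arange(0.0, duration + dt / 2, dt)
    bp = np.asarray(breakpoints, dtype=float)
    bp = bp[(bp > 0) & (bp < duration)]
    edges = np.unique(np.concatenate([grid, bp, [duration]]))
    mids = (edges[:-1] + edges[1:]) / 2.0
    mu_mid = np.asarray(mu(mids), dtype=float)
    if equilibrate and config.equilibration_enabled:
        mu_mid = mu_mid * _equilibration(mids, config)
    steps = np.diff(edges) / S_PER_H * mu_mid
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    return edges, cum


def simulate_tracks(signal: NutrientSignal,
                    config: SimConfig,
                    steady_map: Optional[SteadyStateMap] = None,
                    kernels: Optional[KernelPair] = None,
                    condition: str = "",
                    replicate_day: str = "day1",
                    day_factor: float = 1.0,
                    rng: Optional[np.random.Generator] = None,
                    ) -> SimResult:
    """Simulate a track table under one signal and physiology.

    Volume integrates dV/dt = mu(t) ln2 V, with per-cell multiplicative
    rate factors and the shared ``day_factor`` scaling mu.  Division follows
    the adder rule; exactly one daughter is retained.  Lengths and widths
    carry multiplicative noise constructed so that the cylinder-with-caps
    volume computed from them is an unbiased estimate of the true volume.

    Returns a :class:`SimResult`; with the same config, signal and seed the
    output table is bit-for-bit reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu_base, bps, equilibrate = _build_mu_base(signal, config, steady_map,
                                               kernels)
    edges, cum = _cumulative_doublings(mu_base, bps, signal.duration,
                                       config, equilibrate)
    n_frames_total = int(np.floor(signal.duration
                                  / config.frame_interval_s)) + 1
    add_mean = config.added_volume_mean_um3
    rows_time, rows_len, rows_wid, rows_tid = [], [], [], []
    truth_rows = []
    sphere_coef = np.pi / 6.0
    for cell in range(config.n_cells):
        start = int(rng.integers(0, max(1, n_frames_total - 1)))
        life = max(2, int(rng.geometric(1.0 / config.mean_track_frames)))
        n_fr = min(life, n_frames_total - start)
        if n_fr < 2:
            n_fr = 2
            start = n_frames_total - 2
        ft = (start + np.arange(n_fr)) * config.frame_interval_s
        f = float(day_factor * _lognormal_factor(rng, config.cell_rate_sd))
        if config.initial_volume_um3 is not None:
            vb0 = config.initial_volume_um3
            v0 = vb0
        else:
            vb0 = add_mean
            v0 = vb0 * 2.0 ** rng.uniform(0.0, 1.0)
        t_end = ft[-1]
        # adder division times by inverting the cumulative integral
        birth_t = [ft[0]]
        birth_v = [v0]
        birth_I = [np.interp(ft[0], edges, cum)]
        div_times: List[float] = []
        while True:
            thr = rng.normal(add_mean, config.division_asymmetry_sd
                             * add_mean)
            thr = max(thr, 0.05 * add_mean)
            v_div = birth_v[-1] + thr
            dI = np.log2(v_div / birth_v[-1]) / f if f > 0 else np.inf
            I_div = birth_I[-1] + dI
            if I_div >= np.interp(t_end, edges, cum) or not np.isfinite(I_div):
                break
            t_div = float(np.interp(I_div, cum, edges))
            if t_div >= t_end:
                break
            div_times.append(t_div)
            birth_t.append(t_div)
            birth_v.append(v_div / 2.0)
            birth_I.append(I_div)
        bt = np.asarray(birth_t)
        bI = np.asarray(birth_I)
        bV = np.asarray(birth_v)
        seg = np.clip(np.searchsorted(bt, ft, side="right") - 1, 0, None)
        I_f = np.interp(ft, edges, cum)
        v_true = bV[seg] * 2.0 ** (f * (I_f - bI[seg]))
        v_meas = v_true * _lognormal_factor(rng, config.size_noise_sd,
                                            size=n_fr)
        w = config.width_um * float(_lognormal_factor(rng,
                                                      config.width_cell_sd))
        v_meas = np.maximum(v_meas, sphere_coef * w ** 3 * (1 + 1e-9))
        lengths = length_from_volume(v_meas, w)
        tid = f"{condition or 'c'}-{replicate_day}-{cell:05d}"
        rows_tid.append(np.full(n_fr, tid, dtype=object))
        rows_time.append(ft)
        rows_len.append(np.atleast_1d(lengths))
        rows_wid.append(np.full(n_fr, w))
        truth_rows.append({
            "track_id": tid, "cell_factor": f, "day_factor": day_factor,
            "t_start_s": float(ft[0]), "n_frames": n_fr,
            "division_times_s": div_times,
            "width_um": w, "v0_um3": v0,
        })
    table = pd.DataFrame({
        "track_id": np.concatenate(rows_tid),
        "time_s": np.concatenate(rows_time),
        "length_um": np.concatenate(rows_len),
        "width_um": np.concatenate(rows_wid),
        "condition": condition,
        "replicate_day": replicate_day,
    })
    truth = pd.DataFrame(truth_rows)
    return SimResult(table=table, truth=truth, mu_base=mu_base,
                     signal=signal, config=config)


def simulate_experiment(conditions: Dict[str, Tuple[NutrientSignal, str]],
                        config: SimConfig,
                        steady_map: Optional[SteadyStateMap] = None,
                        kernels: Optional[KernelPair] = None,
                        n_days: int = 1,
                        ) -> Dict[str, List[SimResult]]:
    """Simulate parallel conditions over one or more replicate days.

    ``conditions`` maps a condition name to (signal, physiology).  One
    multiplicative day effect is drawn per day and applied identically to
    every condition run that day (same-day runs share a seed culture).
    Child seeds are spawned deterministically from ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    day_rng = np.random.default_rng(root.spawn(1)[0])
    day_factors = draw_day_factors(n_days, config.day_effect_sd, day_rng)
    out: Dict[str, List[SimResult]] = {name: [] for name in conditions}
    children = root.spawn(n_days * len(conditions) + 1)[1:]
    i = 0
    for d in range(n_days):
        day = f"day{d + 1}"
        for name, (sig, phys) in conditions.items():
            cfg = SimConfig(**{**config.to_dict(), "physiology": phys})
            rng = np.random.default_rng(children[i])
            i += 1
            out[name].append(simulate_tracks(
                sig, cfg, steady_map=steady_map, kernels=kernels,
                condition=name, replicate_day=day,
                day_factor=float(day_factors[d]), rng=rng))
    return out
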