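# flucgrowth

Single-cell analysis of bacterial growth under rapid nutrient fluctuations.

Many microbial habitats change on second-to-minute timescales, yet growth
physiology is usually characterized at steady state or across a single
nutrient shift. This package implements, as a tested and reusable pipeline,
the analysis of single-cell *E. coli* volume trajectories under square-wave
nutrient signals: instantaneous growth-rate estimation, shift-aligned
stabilization statistics, Jensen's-inequality reference rates, and a null
model that predicts growth in fluctuating environments from single-shift
response kernels. A synthetic track generator stands in for the microscopy
measurements, so every stage is testable end to end without any download.

It is written for quantitative microbiologists working with image-derived
single-cell measurements (track tables of cell length and width over time).

## The quantities at the core

* **Instantaneous growth rate.** Cell volume V is a cylinder with
  hemispherical caps, V = π(w/2)²(l − w) + (4/3)π(w/2)³. From
  V(t + Δt) = V(t)·2^(µΔt), the per-interval rate is
  µ = (ln V(t+Δt) − ln V(t)) / (Δt ln 2) in doublings/h. Intervals whose
  volume drops by more than 25% are division events and are excluded.
* **Steady-state rates.** G = pooled mean of all single-cell µ after a 3-h
  equilibration window; G_low, G_ave, G_high for the steady controls and
  G_fluc for fluctuating runs.
* **Jensen reference.** For a concave rate-versus-concentration curve,
  G_J = (G_low + G_high)/2 < G_ave: the ceiling for cells alternating
  between the two steady states with equal time in each.
* **Stabilization.** The mean post-shift growth curve is "stabilized" from
  the first window start (windows always end at the last bin, shrinking
  from the left) whose least-squares slope is indistinguishable from zero
  and stays so for every later start.
* **Null model.** Growth under a square wave is assembled from measured
  up/down single-shift kernels (value-matching or clock-reset variants) and
  time-averaged per period to predict G_fluc across periods T = 30 s–96 h;
  predictions rise with T toward G_J, with shortfall at most
  (A_up + A_down)/T given the kernel deficit areas A.

## Worked example

```python
import flucgrowth as fg

sig = fg.make_signal("fluctuating", c_low=0.1, c_high=2.0,
                     duration=12 * 3600, period_T=3600.0)
cfg = fg.SimConfig(seed=7, physiology="fluctuation_adapted", n_cells=800,
                   size_noise_sd=0.05, day_effect_sd=0.0,
                   mean_track_frames=60)
res = fg.simulate_tracks(sig, cfg, kernels=fg.make_shift_kernels())
kept, report = fg.apply_qc(res.table)
pts = fg.growth_points(kept)
for direction in ("up", "down"):
    curve = fg.align_to_shifts(pts, sig, direction)
    stab = fg.detect_stabilization(curve)
    print(direction, f"t = {stab.stabilization_time_min:.1f} min,",
          f"value = {stab.stabilized_value:.3f} /h")
```

prints

```
up t = 2.9 min, value = 1.858 /h
down t = 1.0 min, value = 0.652 /h
```

— cells grown in a 60-min fluctuation stabilize their growth rate within
~1–3 min of each shift, at ~1.86 doublings/h after upshifts (66% of
G_high = 2.86) and ~0.6–0.65 after downshifts, far below the steady rates. Running
the same detector on tracks that replay a full steady-state transition at
each shift (`physiology="single_shift_kernel"`) yields upshift
stabilization only around 126 min, near kernel completion — the
qualitative signature separating the fluctuation-adapted physiology from
single-shift behavior.

The numbered drivers under `analysis/` run the full study: simulate the
four parallel channels over replicate days (`01`), growth-rate and
steady-state analysis (`02`), the stabilization contrast (`03`), and the
null-model sweep with biomass projections and paired per-day comparisons
(`04`). A `flucgrowth` command-line interface exposes the same stages
(`simulate`, `analyze`, `nullmodel`, `report`) over a YAML config.

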