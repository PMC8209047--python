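# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not show
about real measurements.

## Measurement model and growth-rate estimator

A track table carries one row per cell per imaging frame: `track_id,
time_s, length_um, width_um` plus condition and replicate-day labels.
Cell volume is the cylinder-with-hemispherical-caps approximation
V = π(w/2)²(l − w) + (4/3)π(w/2)³ (µm³), the standard geometry for
rod-shaped bacteria segmented as 2-D particles.

The instantaneous growth rate between consecutive frames solves
V(t + Δt) = V(t)·2^(µΔt):

    µ = (ln V(t+Δt) − ln V(t)) / (Δt ln 2)   [doublings/h]

Each estimate is assigned to the interval midpoint; with the 117-s default
cadence a point therefore averages the true µ(t) over ±58.5 s, which
smears responses across a shift by up to one frame. Intervals whose volume
drops by more than `division_drop` (default 25%, far beyond plausible
shrinkage and far below the ~50% halving) are division events and excluded
from valid points; whether the original analysis excluded such intervals
or terminated lineages at division is not stated in the text, so the rule
is explicit and configurable here. All binned statistics pool valid points
with equal weight ("per-point pooling"), matching a definition of G as the
average of all single-cell rates; steady-state rates use points after a
3-h window (`window_start`), when the loading transient has decayed.

Relative size noise σ propagates to per-interval rate noise
√2·σ/(Δt·ln 2) ≈ 63·σ doublings/h at Δt = 117 s — 2% noise gives ±1.3/h
per interval. Single-interval estimates are therefore never interpreted
alone; every downstream statistic averages hundreds of points per bin.

## Quality control

Frames outside the size bounds (length 1–12 µm, width 0.4–4 µm,
length ≥ width) or showing a non-division volume step above
`max_rel_step` = 0.5 are dropped; tracks left with fewer than
`min_frames` = 5 clean frames are discarded. The original thresholds live
in released analysis scripts rather than the text, so these values are
documented surrogates: they pass clean synthetic tracks untouched (the
suite asserts 100% retention) and reject gross tracking errors. QC is
idempotent on tracks whose defects are isolated glitches; pathological
inputs where removing a frame creates a new >50% step could require a
second pass.

## Steady-state map

Steady-state growth rate versus nutrient concentration is anchored at
(0% LB, 0), (0.1, 1.07), (1.05, 2.31) and (2.0, 2.86 doublings/h) — the
origin plus the three measured control rates — and interpolated with a
monotone, concave, C1 piecewise-cubic Hermite. Concavity is a contract,
not an accident: Jensen's inequality (rate at the mean concentration
exceeding the mean of the endpoint rates) must hold for any sub-interval,
and the suite asserts it property-based. Node derivatives are chosen by a
backward recursion that keeps each cubic piece concave (2d_i + d_{i+1} ≥
3s_i and d_i + 2d_{i+1} ≤ 3s_i per interval with secant slope s_i); a
standard shape-preserving PCHIP fit is monotone but convex over part of
this anchor set, and a two-parameter Monod curve cannot pass through all
three measured rates. Above the last anchor the rate saturates.

## Shift-response kernels

Single-shift growth responses are parameterized by endpoint rates and
completion times: the up kernel rises from G_low = 1.07 to G_high = 2.86
completing at 150 min (the middle of the reported 2–3 h), the down kernel
drops at the shift to 10% of G_low and recovers to G_low by 300 min. Two
shapes are available. The default is a saturating exponential normalized
to hit the endpoint exactly at completion (time constant t_c/ln 100, i.e.
99% of the span covered); the alternative is a linear ramp. The
end-to-end stabilization-contrast experiment uses the linear shape: the
measured single-shift curves keep rising at a roughly steady pace until
the transition completes, whereas an exponential's slope becomes
negligible long before its nominal completion time, which would let any
zero-slope detector fire early for reasons that are artifacts of the
parameterization, not of the physiology.

## Stabilization detection

The growth signal is "stabilized once the slope within a shrinking window
reaches zero"; the window scheme, tolerance and persistence requirement
are design choices fixed here as: windows always end at the last available
bin, shrink from the left one bin at a time, and the criterion must hold
from the stabilization start and every later start (persistence). Aligned
curves end at the last complete bin before the next shift — a trailing
partial bin would mix data across the shift. Two zero-slope rules are
exposed, neither asserted to be the original:

* `tol` — |OLS slope| ≤ `slope_tol` (0.5 h⁻¹ per hour);
* `ci` (default) — the confidence interval of the slope contains zero.
  When per-bin SEMs are available the interval treats them as known
  measurement errors (so curve-shape misfit cannot inflate it); otherwise
  a residual-based t interval is used. Because persistence makes this a
  joint test over every scanned window, the per-window level is
  Bonferroni-corrected to keep the family-wise confidence at 95%: without
  the correction a genuinely flat noisy curve fails persistence roughly
  half the time through a single noisy late window.

The stabilized value is the point-weighted mean over the stabilized
window. The detector is validated against an exhaustive window-scan
oracle (independent loop over `scipy.stats.linregress` / explicit weighted
sums) on randomized relaxation curves, and stabilization time is
non-increasing in `slope_tol` by construction.

The initial post-shift response is the percent change of the mean rate
over the first 7.5 min relative to the single pre-shift bin.

## Null model

Growth under a square wave is assembled from the kernel pair under two
variants. Variant A (value matching): at an upshift, continue the up
kernel from the earliest time whose value reaches the current rate
(clamped to the kernel's domain); at a downshift, drop to the start of the
down kernel. Variant B (clock reset): restart the appropriate kernel from
zero at every shift. Both reduce to the single-shift curves when only one
shift occurs. With the default monotone kernels the down kernel never
ends a half-period above G_low, so the up-kernel value matching always
clamps to zero and the two variants coincide numerically; they are kept as
separate first-class options because they formalize different assumptions
and diverge for other kernel families. Both are surrogates for the
original pair of modeling assumptions, whose exact constructions are not
in the available text.

Predicted G_fluc at period T iterates the trajectory period by period
until the per-period time-average changes by < 1e-6 doublings/h (cap 200
periods; non-convergence is reported, not silent) and averages one
converged period by trapezoid quadrature with ≥ 200 samples per period,
the sample budget concentrated on the pre-completion part of each kernel
(a uniform grid under-resolves a 2.5-h transition inside a 48-h
half-period). The prediction rises with T toward G_J = (G_low + G_high)/2
with shortfall at most (A_up + A_down)/T, A being the kernel deficit
areas; the bound is an equality once T/2 exceeds both completion times,
so tests allow ~1e-4 of quadrature slack on it.

Paired comparisons mirror the day-structure of real experiments: percent
differences (G_fluc − G_ref)/G_ref·100 are formed within a replicate day
(G_J from that day's G_low and G_high) before averaging across days,
which removes the shared day effect; the suite checks that pairing
shrinks the spread relative to all-pairs comparisons. Reported rates are
rounded half-up at two decimals (`display_round`), the convention used
for printed values; biomass projections M = M₀·2^(Gt) are reported at one
significant figure.

## Synthetic-data generator

The generator emulates tracker output from a nutrient-control microfluidic
experiment, not images: exponential volume growth dV/dt = µ(t)·ln 2·V
integrated exactly per cell, adder division (divide after adding
`added_volume_mean` = 2 µm³ ± 10%, truncated positive; the retained
daughter takes half), global frames every 117 s, geometric track lifetimes
(mean 40 frames), multiplicative size noise (2% default) constructed so
the cylinder-with-caps volume computed from the emitted length and width
is an unbiased estimate of the true volume, per-cell lognormal rate
factors (10%), and a per-day lognormal factor (8%) shared by all
conditions simulated for the same day. An equilibration transient (start
at 50% of the target rate, 1-h relaxation) is on by default so the 3-h
steady-state window is meaningful. Square waves start in the high phase
by default (configurable; the original text does not state the starting
phase). All times are seconds internally; rates are doublings/h;
conversion happens at one boundary.

Three physiologies set µ(t):

* `instantaneous` — µ follows the steady-state map of the momentary
  concentration (no memory);
* `single_shift_kernel` — µ follows the null-model trajectory (the
  kernels define the transient, so the equilibration factor is skipped);
* `fluctuation_adapted` — µ moves to stabilized phase rates (defaults
  1.86/h post-upshift, 0.60/h post-downshift, the 60-min-period values)
  within a 2-min linear lag after each shift, consistent with the
  minute-scale stabilization times this physiology exhibits; in onset
  signals the behavior blends linearly from the single-shift trajectory
  to the stabilized one over 3 periods, so per-period means converge at
  the third period.

Numerics: µ(t) is integrated midpoint-exactly on a 1-s grid whose knots
include every signal and kernel breakpoint, making log-volume exactly
piecewise-linear for piecewise-constant rates (the suite asserts 1e-9
agreement and exact adder doubling times). Division times invert the
cumulative integral by linear interpolation. Identical config and seed
give byte-identical tables.

What the generator does not emulate: segmentation artifacts beyond
multiplicative size noise, cell-to-cell interactions, width dynamics over
the cell cycle, non-stationary day effects, or any mechanistic basis for
the adapted state. Passing tests therefore demonstrate that the pipeline
recovers known ground truth under the stated statistical structure — not
that real data satisfy that structure.

## Problem sizes

The stabilization-contrast experiment uses 3,600 fluctuation-adapted
tracks over 12 h (nine pooled shifts per direction) and 2,000 single-shift
tracks over 6 h, with 5% size noise. These sizes pin the recovered
downshift rate (0.60 doublings/h) to ~1–2%: per-interval noise is ~3/h,
so ~50,000 valid points per stabilized window are needed for a
sub-percent standard error. Unit and property tests run on tens of tracks
and finish in seconds.

## Known limitations

* The measured fluctuating-environment rates (1.93/1.53/1.15/1.15
  doublings/h) and the measured fractions of predicted growth loss
  (70.8%/38.9%) require the real dataset and the original prediction
  table; they are carried as documented reference constants
  (`flucgrowth.reference`), never recomputed.
* The QC thresholds and both stabilization rules are explicit surrogates
  for under-specified steps of the original processing.
* The null-model variants bracket plausible readings of the original
  assumptions but are not verbatim reconstructions.
* Phase-resolved analysis flags, but cannot overcome, under-resolution
  when the sampling interval exceeds half the fluctuation period
  (T = 30 s at 117-s cadence).
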