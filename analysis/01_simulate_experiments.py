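#!/usr/bin/env python
"""Simulate the core experiment suite.

One 'experiment' mirrors a four-channel device run: a fluctuating channel
(T = 60 min, fluctuation-adapted physiology) plus three steady controls at
the low, average and high concentrations (instantaneous physiology), over
three replicate days sharing per-day rate effects.  A single-shift pair
(up and down) and an onset-of-fluctuations run are simulated alongside.

Writes track tables under results/tracks/.
"""

from pathlib import Path

from flucgrowth.pipeline import RunConfig, run_simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "tracks"

CONFIG = RunConfig(
    seed=2021,
    n_days=3,
    signals={
        "fluctuating": {"kind": "fluctuating", "duration_s": 6 * 3600.0,
                        "period_T_s": 3600.0},
        "steady_low": {"kind": "steady", "duration_s": 6 * 3600.0,
                       "steady_level": "low"},
        "steady_ave": {"kind": "steady", "duration_s": 6 * 3600.0,
                       "steady_level": "average"},
        "steady_high": {"kind": "steady", "duration_s": 6 * 3600.0,
                        "steady_level": "high"},
        "single_upshift": {"kind": "single_shift", "duration_s": 6 * 3600.0,
                           "shift_time_s": 3 * 3600.0,
                           "first_phase": "low"},
        "single_downshift": {"kind": "single_shift",
                             "duration_s": 8 * 3600.0,
                             "shift_time_s": 3 * 3600.0,
                             "first_phase": "high"},
        "onset": {"kind": "onset", "duration_s": 9 * 3600.0,
                  "period_T_s": 3600.0, "shift_time_s": 4 * 3600.0},
    },
    physiologies={
        "fluctuating": "fluctuation_adapted",
        "single_upshift": "single_shift_kernel",
        "single_downshift": "single_shift_kernel",
        "onset": "fluctuation_adapted",
    },
    sim={"n_cells": 150, "size_noise_sd": 0.02, "mean_track_frames": 50},
)

if __name__ == "__main__":
    paths = run_simulate(CONFIG, OUT)
    for name, path in sorted(paths.items()):
        print(f"wrote {path}")
    print(f"config + per-condition signal sidecars in {OUT}")
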