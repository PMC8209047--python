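#!/usr/bin/env python
"""The stabilization contrast between growth physiologies.

Fluctuation-grown cells stabilize their growth rate within minutes of each
shift, at rates below the corresponding steady states; cells that re-run a
steady-state transition at every shift (single-shift-kernel physiology)
stabilize only when the transition kernel completes, hours later.  This
driver runs both synthetic experiments with the same detector and writes
the side-by-side summary.

Writes results/shift_response_contrast.csv.
"""

from pathlib import Path

import pandas as pd

from flucgrowth.experiments import (fluctuation_recovery_experiment,
                                    single_shift_stabilization_experiment)

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    rows = []
    rec = fluctuation_recovery_experiment(seed=2021)
    for direction in ("up", "down"):
        r = rec[direction]
        rows.append({
            "condition": "fluctuating_T60min", "direction": direction,
            "stabilization_time_min": r["stabilization_time_min"],
            "stabilized_value_per_h": r["stabilized_value"],
            "target_per_h": rec["targets"][direction],
            "initial_response_pct": r["initial_response_pct"],
        })
    for direction in ("up", "down"):
        s = single_shift_stabilization_experiment(seed=2022,
                                                  direction=direction,
                                                  duration=(6 if direction
                                                            == "up" else 9)
                                                  * 3600.0)
        rows.append({
            "condition": "single_shift", "direction": direction,
            "stabilization_time_min": s["stabilization_time_min"],
            "stabilized_value_per_h": s["stabilized_value"],
            "target_per_h": None,
            "initial_response_pct": None,
        })
    table = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "shift_response_contrast.csv", index=False)
    print(table.to_string(index=False))
    print("\nfluctuation-grown cells stabilize within minutes at rates "
          "below steady state;\nsingle-shift responders stabilize only "
          "near kernel completion.")
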