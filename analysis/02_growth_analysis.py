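#!/usr/bin/env python
"""Growth-rate analysis of the simulated experiment suite.

QC, instantaneous growth rates, 2-min and 30-min binned curves, per-day
steady-state rates after the 3-h equilibration window, phase-folded curves
for the fluctuating channel, and per-period statistics for the onset run.

Reads results/tracks/ (from 01), writes results/analysis/.
"""

import json
from pathlib import Path

base = Path(__file__).resolve().parent.parent
import importlib.util
spec = importlib.util.spec_from_file_location(
    "sim_config", base / "analysis" / "01_simulate_experiments.py")
mod = importlib.util.module_from_spec(spec)
spec.loader.exec_module(mod)

from flucgrowth.pipeline import run_analyze

if __name__ == "__main__":
    summary = run_analyze(mod.CONFIG, base / "results" / "tracks",
                          base / "results" / "analysis")
    print("per-day steady-state rates (doublings/h):")
    for name, cond in sorted(summary["conditions"].items()):
        days = ", ".join(f"{r['replicate_day']}: {r['G_per_h']:.2f}"
                         for r in cond["steady_state"])
        print(f"  {name:16s} {days}")
    fluc = summary["conditions"]["fluctuating"]
    if "shift_response" in fluc:
        print("fluctuating-channel shift response:")
        print(json.dumps(fluc["shift_response"], indent=2))
    print(f"tables in {base / 'results' / 'analysis'}")
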