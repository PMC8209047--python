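#!/usr/bin/env python
"""Null-model predictions versus measured fluctuating growth.

Sweeps the single-shift null model over fluctuation periods from 30 s to
96 h (both variants), tabulates predicted G_fluc against the Jensen
ceiling G_J, and contrasts with the published measured G_fluc values:
measured growth under rapid fluctuations sits well above the single-shift
prediction, the signature of the fluctuation-adapted physiology.

Writes results/null_predictions.csv and results/null_vs_measured.csv.
"""

from pathlib import Path

import pandas as pd

from flucgrowth import (biomass_projection, display_round,
                        fraction_of_predicted_loss, fold_difference,
                        jensen_rate, make_shift_kernels, predict_gfluc,
                        reference)

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    kernels = make_shift_kernels()
    T_grid = [30.0, 300.0, 900.0, 3600.0, 12 * 3600.0, 96 * 3600.0]
    frames = []
    for variant in ("A_value_matching", "B_clock_reset"):
        frames.append(predict_gfluc(kernels, variant,
                                    T_grid_s=T_grid).to_frame())
    preds = pd.concat(frames, ignore_index=True)
    OUT.mkdir(parents=True, exist_ok=True)
    preds.to_csv(OUT / "null_predictions.csv", index=False)

    g_j = jensen_rate(reference.G_LOW, reference.G_HIGH)
    a = preds[preds["variant"] == "A_value_matching"].set_index("T_s")
    rows = []
    for T, g_meas in reference.G_FLUC_MEASURED.items():
        g_pred = float(a.loc[T, "predicted_G_fluc_per_h"])
        rows.append({
            "T_s": T,
            "measured_G_fluc_per_h": g_meas,
            "predicted_G_fluc_per_h": g_pred,
            "pct_below_G_ave": display_round(
                100.0 * (reference.G_AVE - g_meas) / reference.G_AVE, 1),
            "measured_loss_pct_of_predicted": display_round(
                fraction_of_predicted_loss(reference.G_AVE, g_meas, g_pred),
                1),
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "null_vs_measured.csv", index=False)

    print(f"G_J = {display_round(g_j, 2)} /h "
          f"(Jensen ceiling; G_ave = {reference.G_AVE} /h)")
    print(table.to_string(index=False))
    m30 = biomass_projection(1.0, reference.G_FLUC_MEASURED[30.0], 24.0).M
    mave = biomass_projection(1.0, reference.G_AVE, 24.0).M
    fold = fold_difference(reference.G_FLUC_MEASURED[30.0],
                           reference.G_AVE, 24.0)
    print(f"\ndaily biomass from 1 um^3: {m30:.1e} (G_fluc, T=30 s) vs "
          f"{mave:.1e} um^3 (G_ave): {fold:.0f}-fold difference")
    print("measured growth under rapid fluctuations exceeds the "
          "single-shift prediction:\nthe faster the fluctuation, the "
          "larger the advantage of the adapted physiology.")
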