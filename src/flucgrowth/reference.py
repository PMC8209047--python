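"""Published reference values for the fluctuating-nutrient growth study.

These are *measured* quantities from the original experiments (mean ± sd
across replicate days).  They are reference constants for contextualizing
synthetic-data results — re-deriving them requires the real single-cell
dataset, so nothing in this package computes them; they parameterize
defaults (steady-state anchors, kernel endpoints, stabilized rates) and
appear in reports for comparison only.

Rates are in doublings per hour; concentrations in % LB v/v.
"""

from __future__ import annotations

from types import MappingProxyType

#: nutrient levels switched between in all fluctuating runs
C_LOW_PCT_LB = 0.1
C_HIGH_PCT_LB = 2.0
C_AVE_PCT_LB = 1.05

#: steady-state growth rates in the three control conditions
G_LOW = 1.07       # ± 0.23
G_HIGH = 2.86      # ± 0.14
G_AVE = 2.31       # ± 0.18
G_J_PRINTED = 1.97  # ± 0.16, Jensen average of G_low and G_high

#: measured mean growth rate under fluctuations, by period (seconds)
G_FLUC_MEASURED = MappingProxyType({
    30.0: 1.93,      # ± 0.16
    300.0: 1.53,     # ± 0.20
    900.0: 1.15,     # ± 0.28
    3600.0: 1.15,    # ± 0.13
})

#: stabilized post-shift rates of fluctuation-grown cells, by period (s)
STABILIZED_UPSHIFT_RATE = MappingProxyType({900.0: 1.86, 3600.0: 1.86})
STABILIZED_DOWNSHIFT_RATE = MappingProxyType({900.0: 0.65, 3600.0: 0.60})

#: stabilization times (minutes after each shift) of fluctuation-grown cells
STABILIZATION_MIN_UPSHIFT = MappingProxyType({900.0: 3.8, 3600.0: 3.3})
STABILIZATION_MIN_DOWNSHIFT = MappingProxyType({900.0: 2.2, 3600.0: 15.0})

#: single-shift stabilization: ~116.3 min after an upshift; after a
#: downshift at least 297.5 min (one of two replicates within 5 h)
SINGLE_SHIFT_UPSHIFT_STABILIZATION_MIN = 116.3
SINGLE_SHIFT_DOWNSHIFT_STABILIZATION_MIN = 297.5

#: measured growth loss as a fraction (%) of the null-model predicted loss
FRACTION_OF_PREDICTED_LOSS_PCT = MappingProxyType({300.0: 70.8, 30.0: 38.9})
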