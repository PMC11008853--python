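"""Device sampling arithmetic and exclusion-window filtering.

First converts a series of sampled perfusate concentrations to the
cumulative mass-per-area observable using the chamber constants
(4 uL/min perfusion, 0.5 cm^2 diffusion window), then applies the
published animal-weight and endpoint-mass exclusion windows to a small
record table.
"""

import numpy as np
import pandas as pd

from dermakin import (
    apply_exclusion_criteria,
    concentration_to_cumulative_mass,
    default_exclusion_criteria,
)

concentrations = np.array([0.8, 1.6, 2.1, 2.4, 2.6, 2.7])  # ug/mL per sample
obs = concentration_to_cumulative_mass(concentrations, interval_min=30)
print("30-min samples at 4 uL/min collect 0.12 mL each:")
for t, v in zip(obs.times, obs.values):
    print(f"  t={t:4.1f} h  cumulative {v:6.3f} ug/cm^2")

records = pd.DataFrame(
    {
        "animal": ["m1", "m2", "m3"],
        "mouse_body_weight_g": [19.0, 25.0, 33.0],
    }
).set_index("animal")
criteria = default_exclusion_criteria().subset(["mouse_body_weight_g"])
kept, report = apply_exclusion_criteria(records, criteria)

print("\nExclusion filtering (window 20-32 g, bounds inclusive):")
print(report.to_string(index=False))
print(f"kept animals: {list(kept.index)}")
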