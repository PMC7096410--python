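"""Force-ablation comparison on a wall-collision-rich scenario.

Seeds small microbubbles within two micrometres of the wall -- where
Brownian drift actually produces collisions -- and reruns with individual
forces switched off, printing the percent change of the adhered count.
The percentages characterize this synthetic domain, not any patient.
"""

import json

import numpy as np

from mbtrack import RunConfig, ablate

r0 = float(np.sqrt(377.4e-6 / np.pi))
cfg = RunConfig.model_validate({
    "microbubble": {"name": "definity", "diameter_um": "min"},
    "injection": {"count_per_injection": 600, "times_s": [0.0],
                  "r_min_frac": 1 - 2e-6 / r0,
                  "r_max_frac": 1 - 0.2e-6 / r0},
    "numerics": {"t_end_s": 2.0},
    "seed": 2,
})

table = ablate(cfg, toggles=("brownian", "gravity", "interaction", "lift"))
print(f"baseline adhered count: {table['baseline']['adhered_count']}")
for key, entry in table.items():
    if key == "baseline":
        continue
    print(f"{key:<16} adhered {entry['adhered_count']:4d}   "
          f"change {entry['pct_change_adhered']:+7.1f} %")

print()
print("Near the wall, deposition is diffusion-limited: removing Brownian")
print("motion nearly eliminates adhesion. The other toggles shift the count")
print("by tens of percent (buoyancy lifts bubbles off the lower wall, for")
print("instance), with visible small-sample noise at these event counts.")
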