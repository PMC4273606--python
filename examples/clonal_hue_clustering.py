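"""Group cells into clones by their colour hue.

Plants five clones with distinct vector copy-number combinations, adds
per-cell expression variability and small channel noise, and recovers
the clonal partition by circular single-linkage clustering of hues.
Hue is the clonal watermark: it depends on copy ratios, not on how
strongly an individual cell expresses.
"""

import numpy as np
import pandas as pd
from scipy import stats

import rgbtrace as rt

clones = [(2, 0, 0), (2, 2, 0), (0, 2, 0), (0, 2, 2), (0, 0, 2)]
noise = rt.NoiseModel(expr_cv=0.2, channel_cv=0.02, autofluor_mean=0.0)
population = rt.generate_clones(clones, cells_per_clone=40, noise=noise,
                                expr=(60, 60, 60), rng=17)

hues = np.array([rt.hue_saturation(*r.intensity)[0] for r in population])
truth = np.array([r.clone_id for r in population])
within_sd = np.mean([stats.circstd(hues[truth == k], high=360.0)
                     for k in range(len(clones))])
print(f"within-clone hue spread: {within_sd:.2f} deg "
      f"(tolerance = 3x = {3 * within_sd:.2f} deg)")

calls = pd.DataFrame({"cell_id": [r.cell_id for r in population],
                      "brightness": 100.0, "hue_deg": hues})
groups = rt.cluster_by_hue(calls, hue_tolerance_deg=3 * within_sd,
                           min_brightness=0.0)
print(f"clones planted: {len(clones)}, clusters found: "
      f"{groups.clone_id.nunique()}")
print(pd.crosstab(groups.clone_id, truth,
                  rownames=["found"], colnames=["planted"]))
print("\nA diagonal cross-table means the hue clustering reassembled the "
      "planted clones exactly.")
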