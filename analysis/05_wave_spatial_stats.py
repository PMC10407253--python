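"""Two-wave adhesion coupling vs the random-dot null.

With hotspot attraction the second wave adheres nearer the first wave
than random dots do (negative median difference); without attraction
the two distance distributions are statistically indistinguishable.
Writes results/wave_metrics.json and the pooled distance table.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from temsig import spatial, synthetic

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(parents=True, exist_ok=True)

metrics = {}
frames = []
for attraction in (0.0, 0.8):
    meds, ks_ps = [], []
    for seed in range(10):
        w1, w2 = synthetic.gen_wave_points(150, 150,
                                           hotspot_attraction=attraction,
                                           seed=seed)
        rep = spatial.wave_comparison(w1, w2, (1330, 1330), seed=seed + 1000)
        meds.append(rep["median_difference"])
        ks_ps.append(rep["ks_pvalue"])
        if seed == 0:
            d = rep["distances"]
            d["attraction"] = attraction
            frames.append(d)
    metrics[f"attraction_{attraction}"] = {
        "median_difference_um_mean": float(np.mean(meds)),
        "ks_p_gt_0.01_fraction": float(np.mean(np.array(ks_ps) > 0.01)),
        "n_seeds": len(meds),
    }
pd.concat(frames).to_csv(RESULTS / "wave_distances.csv", index=False)
with open(RESULTS / "wave_metrics.json", "w") as fh:
    json.dump(metrics, fh, indent=2)
for k, v in metrics.items():
    print(f"{k}: median difference {v['median_difference_um_mean']:+.1f} um, "
          f"KS p>0.01 in {v['ks_p_gt_0.01_fraction']:.0%} of seeds")
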