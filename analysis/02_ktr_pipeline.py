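"""Run the KTR quantification pipeline on a rendered movie and validate it.

A noise-free 20-cell movie goes through background subtraction, nucleus
segmentation, cytoplasm rings, C/N measurement and overlap tracking;
recovered traces are matched to the generator's ground truth by
centroid.  Writes results/ktr_traces.csv and a recovery summary.
"""

import json
from pathlib import Path

import numpy as np

from temsig import ktr, synthetic

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(parents=True, exist_ok=True)

spec = synthetic.SceneSpec(n_cells=20, seed=1)
nuc, kstack, truth = synthetic.gen_ktr_movie(spec, "neutrophil",
                                             noise_sd=0.0, background_amp=0.0)
traces = ktr.run_ktr_pipeline(nuc, kstack)
traces.to_csv(RESULTS / "ktr_traces.csv", index=False)

first = traces.groupby("track_id").first()
errors, spans = [], []
for tid, row in first.iterrows():
    d = np.hypot(truth.centroids[:, 0] - row.y_px, truth.centroids[:, 1] - row.x_px)
    i = int(d.argmin())
    if d[i] >= 5:
        continue
    sub = traces[traces.track_id == tid].set_index("frame")
    spans.append(len(sub) / spec.n_frames)
    rel = np.abs(sub["cn_ratio"].to_numpy()
                 - truth.cn[i, sub.index.to_numpy()]) / truth.cn[i, sub.index]
    errors.append(float(np.nanmax(rel)))

summary = {
    "n_cells_planted": int(truth.n_cells),
    "n_tracks": int(traces["track_id"].nunique()),
    "n_matched": len(errors),
    "median_track_span": float(np.median(spans)),
    "max_relative_cn_error": float(np.max(errors)),
}
with open(RESULTS / "ktr_recovery.json", "w") as fh:
    json.dump(summary, fh, indent=2)
print(f"matched {summary['n_matched']}/{summary['n_cells_planted']} cells; "
      f"max relative C/N error {summary['max_relative_cn_error']:.2e}; "
      f"median span {summary['median_track_span']:.0%} of frames")
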