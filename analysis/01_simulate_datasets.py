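"""Generate the synthetic study datasets used by the downstream analyses.

Writes ground-truth tables under results/data/ and (heavier) image
stacks under scratch/data/.  Every later script regenerates what it
needs from seeds, so this driver mainly documents the study conditions:
200 cells per condition, 30 frames at 30 s, stimulus at frame 5
(t = 2.5 min), control preset 5% responders vs neutrophil preset 50%.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from temsig import io, synthetic

RESULTS = Path(__file__).resolve().parents[1] / "results" / "data"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "data"
RESULTS.mkdir(parents=True, exist_ok=True)
SCRATCH.mkdir(parents=True, exist_ok=True)

# --- KTR trace tables (fast path, both presets) --------------------------
for preset in ("control", "neutrophil"):
    cn, truth = synthetic.gen_traces(200, preset, seed=1)
    df = pd.DataFrame(cn)
    df.insert(0, "cell", np.arange(len(df)))
    df.insert(1, "responder", truth.responder)
    df.to_csv(RESULTS / f"ktr_traces_{preset}.csv", index=False)
    print(f"{preset}: {truth.responder.sum()}/{len(df)} responders "
          f"({100 * truth.responder.mean():.0f}%)")

# --- one rendered two-channel movie (neutrophil preset) ------------------
spec = synthetic.SceneSpec(n_cells=20, seed=1)
nuc, ktr_stack, truth = synthetic.gen_ktr_movie(spec, "neutrophil")
cfg = {"preset": "neutrophil", "n_cells": spec.n_cells, "seed": spec.seed,
       "pixel_size_um": spec.pixel_size_um,
       "frame_interval_s": spec.frame_interval_s,
       "stimulus_frame": spec.stimulus_frame}
io.write_ktr_dataset(SCRATCH / "ktr_movie", nuc, ktr_stack, truth, cfg)
print(f"rendered movie: {spec.n_cells} cells, {spec.n_frames} frames "
      f"at {spec.field_size_px} px -> {SCRATCH / 'ktr_movie'}")

# --- two-wave point sets -------------------------------------------------
rows = []
for attraction in (0.0, 0.8):
    w1, w2 = synthetic.gen_wave_points(150, 150, hotspot_attraction=attraction,
                                       seed=1)
    for wave, pts in ((1, w1), (2, w2)):
        for x, y in pts:
            rows.append({"x_um": x, "y_um": y, "wave": wave,
                         "attraction": attraction})
pd.DataFrame(rows).to_csv(RESULTS / "wave_points.csv", index=False)
print(f"wave points written ({len(rows)} rows, attraction 0.0 and 0.8)")

# --- filopodia field -----------------------------------------------------
img, spot_truth, jmask = synthetic.gen_filopodia_field(
    field_um=(200, 200), density_per_um2=0.005, seed=1)
io.write_stack(SCRATCH / "filopodia_icam.tif", img.astype("float32"))
io.write_stack(SCRATCH / "filopodia_junction_mask.tif", jmask.astype("uint8"))
spot_truth.to_csv(RESULTS / "filopodia_truth.csv", index=False)
print(f"filopodia field: {len(spot_truth)} planted spots on 200x200 um")
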