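# Methods

## Scope and shape

`temsig` reimplements, as a tested library plus thin analysis drivers,
the quantification chain for endothelial signaling during neutrophil
transendothelial migration: KTR activity extraction and responder
clustering, filopodia density, two-wave adhesion spatial statistics,
and FRET/FRAP/crosstalk ratiometrics. Raw microscopy is replaced by
synthetic generators with known ground truth; everything downstream is
validated against that truth.

## The KTR generative model (`temsig.synthetic`)

A scene is a set of non-overlapping concentric disk cells (nucleus
inside cytoplasm) on a 512×512 px field at 0.33 µm/px, imaged for 30
frames at 30 s with the stimulus at frame 5 (2.5 min into a 15-min
movie). Latent kinase activity per cell is

    a(t) = A · 1{responder} · (1 − exp(−(t − t_stim − d)/τ))   for t > t_stim + d,

with amplitude A = 0.4 C/N units, rise constant τ = 2 frames and a
1-frame translocation delay; non-responders hold a(t) = 0. The observed
ratio is CN(t) = baseline + a(t), with per-cell resting baselines drawn
from N(1.0, 0.1) (clipped at 0.3) and i.i.d. Gaussian trace noise of
SD 0.05. Amplitude and noise are stand-ins — the source experiments
report no effect sizes — chosen once so that clustering is non-trivial
but solvable, and they remain configurable.

Condition presets differ only in the responder rate: `control` 0.05,
`neutrophil` 0.50. Responder counts are **exact** (`round(rate·n)`,
shuffled positions), never binomial draws, so downstream fraction
estimates are not confounded by sampling noise in the truth itself.

Movie rendering conserves each cell's total KTR fluorescence: with
nucleus area A_n, cytoplasm area A_c and target ratio CN(t), the
nuclear concentration is N(t) = T/(A_n + CN(t)·A_c) and the cytoplasmic
concentration CN(t)·N(t), so compartment means reproduce the analytic
C/N trace exactly. Stacks are float32 in [0, 1]; 16-bit quantization
would already exceed the 1e-6 noise-free identity the generator
guarantees, so integer output is only an option of the TIFF writer.
Optional Gaussian read noise and a smooth background gradient emulate
camera and illumination imperfections. Cells are static; mitosis,
death, and neutrophil rendering are out of scope.

What the generator does **not** emulate: realistic optics (PSF, shot
noise), irregular cell shapes, cell crowding with touching cytoplasms,
drift, or photobleaching. Passing tests therefore demonstrate
correctness of the measurement chain, not robustness to every
real-data pathology.

## KTR quantification (`temsig.ktr`)

Per frame: (1) rolling-ball background subtraction (radius 50 px) on
the nuclear channel; (2) nuclei by global threshold 0.1 on
[0, 1]-rescaled intensity, declumped by a watershed on the distance
transform with peaks ≥ d_min/2 apart, gated to equivalent diameters
30–100 px, border-touching objects dropped; (3) cytoplasm as the ≤10 px
ring around each nucleus on the KTR channel, gated at threshold 0.08,
collisions resolved to the nearest nucleus; (4) compartment means and
C/N = C/N̄, with compartments under 20 px marked missing (never zero).
Nuclei are then linked frame-to-frame by mask overlap with a 3-px
centroid-displacement gate; the largest overlap wins, ties break by
smaller displacement then lower label; tracks never merge. A
pure-distance fallback (no overlap required) is available for sparse
scenes.

Numerical choices:

- Thresholds follow the convention of dividing integer images by their
  dtype maximum; float inputs are assumed already on [0, 1].
- The rolling ball is a true sphere in (x, y, intensity). For float
  inputs the intensity axis is scaled by 65535 internally so the ball's
  sagitta is small relative to object amplitudes, as it is on 16-bit
  counts; without this, a 0.5-amplitude plateau wider than twice the
  ball sagitta would be swallowed into the background.
- By default the background is estimated on a 4× downscaled copy
  (radius scaled accordingly) and resized back — the same acceleration
  ImageJ applies for large radii — with `downscale=1` giving the exact
  ball. On the noise-free oracle movies both variants agree to well
  below the 1e-3 validation tolerance.
- Coordinates are 0-based (row, col) with origin top-left; outputs
  carry physical units via `pixel_size_um` and `frame_interval_s`.

On noise-free synthetic movies the full pipeline reproduces the
analytic C/N to ~1e-7 relative error; the validated bound is 1e-3.

## Activity analysis (`temsig.activity`)

Relative kinase activity subtracts each cell's mean over all
pre-stimulus frames (not the last baseline frame). Cells first detected
after the stimulus have no baseline and are dropped with a count.
Post-stimulus frames are binned in pairs (missing-aware means; a
trailing odd frame is dropped), residual missing values are imputed by
row interpolation, and cells are clustered with Manhattan pairwise
distances under Ward.D2 linkage, cut at two clusters.

Ward.D2 on L1 distances is mathematically unconventional — Ward's
criterion assumes squared Euclidean input — but is applied deliberately,
matching the behavior of the clustering app this mirrors: the
Lance–Williams recursion squares whatever dissimilarities it is given.
`scipy.cluster.hierarchy.linkage(method="ward")` on a precomputed
condensed L1 matrix implements exactly that recursion; the test suite
checks merge orders and heights against an independent brute-force
Lance–Williams implementation.

The activated cluster is identified as the one with the higher mean
post-stimulus value (the original analysis assigned labels by
inspection). A degenerate all-identical matrix returns every cell
non-activated with a warning rather than an arbitrary split. Condition
summaries use the normal approximation mean ± 1.96·SEM for the 95%
ribbon (bootstrap was the alternative; the normal approximation was
chosen for determinism and because per-frame n is large).

Replicate-level hypothesis tests (t tests, ANOVA) are deliberately not
reimplemented; the module exports the per-condition tables that feed
stock routines.

## Filopodia and morphometry (`temsig.filopodia`)

Spots are maxima of the scale-normalized Laplacian-of-Gaussian response
at the single scale σ = diameter/(2√2)/pixel_size for 0.6 µm spots,
with parabolic sub-pixel refinement. Quality is the response amplitude,
reported both raw and in robust-sigma units (1.4826·MAD of the response
image); the filtering threshold is expressed in sigma units (default 8)
so density estimates are invariant to intensity rescaling. The original
workflow filtered spots manually on a proprietary quality metric;
equivalence to that metric is not claimed — planted-truth recovery is
the validation. Junction exclusion thresholds the VE-cadherin channel
(Otsu by default), dilates by 0.5 µm, and removes spots whose centers
fall in the mask. Z-stacks are maximum-projected before detection.
Density is kept spots over imaged area; the mosaic-overexpression split
partitions spots by GFP intensity at the spot center and divides each
count by its corresponding area partition.

Morphometry seeds nuclei at the ~5 µm scale (Gaussian smoothing +
Otsu), removes seeds under 173 px, grows cells by a watershed on the
junction channel, and filters cells under 10.62 µm equivalent diameter
or touching the border. Circularity is 2D 4πA/P² with the Crofton
perimeter estimator (the default pixel-count perimeter biases digital
disks to ~0.9); users should note this is a 2D stand-in for the 3D
sphericity of volumetric pipelines. Whether the 173-object-size filter
was 2D or 3D in the original analysis is ambiguous; it is applied in 2D
here.

## Two-wave spatial statistics (`temsig.spatial`)

First-wave neutrophils are modeled as disks of 7.5 µm (≈ one neutrophil
radius) around their centroids; the signed nearest-neighbor distance of
a query point is (distance to nearest centroid − radius), negative
inside a disk. The null is an equal-count uniform point set over the
full field (no monolayer mask, mirroring the original random-dot
generation); comparisons report medians, quartiles, per-replicate
medians, the median difference and a two-sample KS test. Adhesion
metrics consume manual above/below-monolayer annotations; diapedesis
efficacy is transmigrated/(adherent + transmigrated). Track statistics
are path length (Σ segment lengths), duration, and speed =
length/duration, with sub-2-point tracks excluded and counted.

The wave generator places first-wave points around k = 5 hotspot
centers (Gaussian spread 40 µm) in a 1330×1330 µm field; a fraction
`hotspot_attraction` of second-wave points lands within 5 µm of a
random first-wave point, the rest uniformly. Attraction 0 is the
calibration condition: second-wave and random-dot distance
distributions must be statistically indistinguishable.

## Ratiometrics (`temsig.ratiometrics`)

FRET traces are per-frame acceptor/donor mean ratios within a mask,
pairing whole-cell and sub-ROI values at the same timepoint. FRAP uses
the two-point normalization 100·(I(t) − I(t_b))/(I(t_0) − I(t_b)) with
anchors at the nearest sampled frames to 0 s and 15 s; the
single-anchor variant (percent of the first frame, which the protocol
text describes) is available via `t_bleach_s=None`, but the two-point
form is the default because it is the one the reported curves obey.
Crosstalk uses the brightest cell — the connected component with the
highest mean intensity above Otsu — on each fluorophore's native
channel as the shared ROI, giving a matrix with unit diagonal by
construction. Background subtraction before ratios is off by default.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng(seed)`; a given
(spec, preset, seed) triple yields bit-identical outputs. Study-scale
runs use 200 cells per condition over 20 seeds for responder fractions,
a 20-cell 512² movie for the end-to-end oracle, 200×200 µm fields at
0.08 µm/px over 10 seeds per density for filopodia recovery, and
150-point waves over 20 seeds for the spatial calibration — sizes
chosen to keep full reproduction runs in the minutes range on a single
core while leaving estimator variance well below the validation bands.

## Known limitations

- Disk-shaped cells make segmentation easier than real monolayers; the
  pipeline's thresholds are validated for recovery, not tuned for
  robustness to confluent irregular shapes.
- Overlap tracking has no gap closing or mitosis handling; a
  disappearing-and-reappearing cell starts a new track.
- The spot-quality scale is detector-specific; only planted-truth
  recovery, not commercial-software equivalence, is claimed.
- 2D circularity is not 3D sphericity; absolute values differ even for
  identical cells.
- The FRAP model is single-exponential with an instantaneous bleach; no
  diffusion-model fitting is provided.
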