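"""Exactly specified ratiometric normalizations: FRET, FRAP, crosstalk.

FRET: per-frame ratio of mean acceptor to mean donor intensity within a
mask (Venus/Cerulean3 convention: higher ratio = higher GTPase
activity).  FRAP: two-point normalization anchoring the pre-bleach frame
to 100% and the bleach frame to 0%.  Crosstalk: per-fluorophore
bleed-through into non-native channels measured in the brightest cell's
ROI and normalized to the native channel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

__all__ = ["fret_ratio_trace", "frap_normalize", "crosstalk_matrix"]


def fret_ratio_trace(acceptor_stack: np.ndarray, donor_stack: np.ndarray,
                     masks: dict[str, np.ndarray],
                     frame_interval_s: float | None = None) -> pd.DataFrame:
    """Acceptor/donor mean-intensity ratio per frame within each mask.

    ``masks`` maps ROI names (e.g. "whole_cell", "under_neutrophil") to
    a 2-D mask or a per-frame mask stack.  Rows for different ROIs at
    the same frame are paired by the ``frame`` column.
    """
    acc = np.asarray(acceptor_stack, dtype=np.float64)
    don = np.asarray(donor_stack, dtype=np.float64)
    if acc.ndim == 2:
        acc, don = acc[None], don[None]
    if acc.shape != don.shape:
        raise ValueError("acceptor and donor stacks must have identical shape")
    rows = []
    for roi, mask in masks.items():
        m = np.asarray(mask, dtype=bool)
        for t in range(acc.shape[0]):
            mt = m if m.ndim == 2 else m[t]
            if not mt.any():
                raise ValueError(f"mask {roi!r} empty at frame {t}")
            d = don[t][mt].mean()
            if d == 0:
                raise ZeroDivisionError(f"donor mean is 0 in ROI {roi!r} at frame {t}")
            rec = {"frame": t, "roi": roi, "ratio": acc[t][mt].mean() / d}
            if frame_interval_s is not None:
                rec["time_s"] = t * frame_interval_s
            rows.append(rec)
    return pd.DataFrame(rows)


def frap_normalize(times_s: np.ndarray, values: np.ndarray,
                   t_prebleach_s: float = 0.0, t_bleach_s: float = 15.0) -> np.ndarray:
    """Two-point FRAP normalization: 100% at pre-bleach, 0% at bleach.

    out(t) = 100 * (I(t) - I(t_bleach)) / (I(t_prebleach) - I(t_bleach)),
    anchors taken at the nearest sampled frame.  The single-anchor
    variant (percent of the pre-bleach frame only) is available via
    ``t_bleach_s=None``.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be matching 1-D arrays")
    i_pre = int(np.argmin(np.abs(t - t_prebleach_s)))
    if t_bleach_s is None:
        if v[i_pre] == 0:
            raise ValueError("pre-bleach intensity is 0")
        return 100.0 * v / v[i_pre]
    i_bleach = int(np.argmin(np.abs(t - t_bleach_s)))
    denom = v[i_pre] - v[i_bleach]
    if denom == 0:
        raise ValueError("pre-bleach and bleach intensities are equal")
    return 100.0 * (v - v[i_bleach]) / denom


def _brightest_cell_roi(image: np.ndarray) -> np.ndarray:
    """Connected component with the highest mean intensity above Otsu."""
    img = np.asarray(image, dtype=np.float64)
    if img.max() == img.min():
        raise ValueError("flat image: cannot pick a brightest cell")
    mask = img >= threshold_otsu(img)
    labels, n = ndi.label(mask)
    if n == 0:
        raise ValueError("no object above threshold")
    means = ndi.mean(img, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(means)) + 1
    return labels == best


def crosstalk_matrix(stacks: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Bleed-through matrix from single-fluorophore multi-channel stacks.

    ``stacks[i, j]`` is the image of fluorophore i recorded in channel
    j (identical imaging settings).  For each fluorophore the ROI is the
    brightest cell on its own channel (i == j) and is reused across
    channels; entry (i, j) is the mean in channel j divided by the mean
    in channel i, so the diagonal is exactly 1.

    Returns ``(matrix, rois)``.
    """
    arr = np.asarray(stacks, dtype=np.float64)
    if arr.ndim != 4 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected stacks of shape (n_fp, n_channels=n_fp, H, W)")
    n = arr.shape[0]
    mat = np.zeros((n, n))
    rois = []
    for i in range(n):
        roi = _brightest_cell_roi(arr[i, i])
        rois.append(roi)
        own = arr[i, i][roi].mean()
        if own == 0:
            raise ValueError(f"fluorophore {i} has zero signal in its own channel")
        for j in range(n):
            mat[i, j] = 1.0 if j == i else arr[i, j][roi].mean() / own
    return mat, rois
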