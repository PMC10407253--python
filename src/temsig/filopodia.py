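"""Apical filopodia as diffraction-limited spots, plus monolayer morphometry.

ICAM-1-rich apical filopodia appear as ~0.6 um puncta on the endothelial
apical membrane.  They are detected as local maxima of the
scale-normalized Laplacian-of-Gaussian response at the single scale
sigma = diameter / (2*sqrt(2)) and filtered on a quality score before the
count is divided by the imaged area to give filopodia per um^2.
Junctional ICAM-1 (bright VE-cadherin-adjacent ridges) is excluded via a
dilated junction mask.

Spot quality is reported both raw (LoG response amplitude) and in
robust-sigma units of the response image (1.4826 * MAD), so that the
filtering threshold — and hence the density — is invariant to rescaling
the image intensity.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import clear_border, watershed

logger = logging.getLogger(__name__)

__all__ = [
    "detect_spots",
    "filter_spots",
    "junction_mask_from_channel",
    "density",
    "cell_morphometry",
]


def _robust_sigma(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def _subpixel_offset(resp: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Quadratic (parabolic) sub-pixel refinement of a response maximum."""
    out = [0.0, 0.0]
    h, w = resp.shape
    if 0 < r < h - 1:
        a, b, cc = resp[r - 1, c], resp[r, c], resp[r + 1, c]
        denom = a - 2 * b + cc
        if denom != 0:
            out[0] = float(np.clip(0.5 * (a - cc) / denom, -0.5, 0.5))
    if 0 < c < w - 1:
        a, b, cc = resp[r, c - 1], resp[r, c], resp[r, c + 1]
        denom = a - 2 * b + cc
        if denom != 0:
            out[1] = float(np.clip(0.5 * (a - cc) / denom, -0.5, 0.5))
    return out[0], out[1]


def detect_spots(image: np.ndarray, pixel_size_um: float,
                 diameter_um: float = 0.6) -> pd.DataFrame:
    """Single-scale LoG spot detection with sub-pixel centers.

    Returns the *unfiltered* candidate table with columns row_px,
    col_px, x_um, y_um, scale_um, quality (response amplitude) and
    quality_snr (amplitude in robust-sigma units of the response).
    """
    if pixel_size_um > diameter_um / 2:
        raise ValueError(
            f"pixel size {pixel_size_um} um too coarse for {diameter_um} um "
            "spots (need pixel_size <= diameter/2)"
        )
    img = np.asarray(image, dtype=np.float64)
    sigma_px = diameter_um / (2 * math.sqrt(2)) / pixel_size_um
    # scale-normalized LoG; negated so bright blobs give positive response
    resp = -(sigma_px ** 2) * ndi.gaussian_laplace(img, sigma_px)
    sig = _robust_sigma(resp)
    peaks = peak_local_max(resp, min_distance=max(1, int(round(sigma_px))),
                           threshold_abs=0.0, exclude_border=False)
    rows = []
    for r, c in peaks:
        q = float(resp[r, c])
        if q <= 0:
            continue
        dr, dc = _subpixel_offset(resp, r, c)
        rr, cc = r + dr, c + dc
        rows.append({
            "row_px": rr,
            "col_px": cc,
            "x_um": cc * pixel_size_um,
            "y_um": rr * pixel_size_um,
            "scale_um": diameter_um / 2,
            "quality": q,
            "quality_snr": q / sig if sig > 0 else np.inf,
        })
    out = pd.DataFrame(rows, columns=["row_px", "col_px", "x_um", "y_um",
                                      "scale_um", "quality", "quality_snr"])
    out.attrs["pixel_size_um"] = pixel_size_um
    return out


def junction_mask_from_channel(junction_image: np.ndarray,
                               threshold: float | None = None,
                               dilation_um: float = 0.5,
                               pixel_size_um: float = 1.0) -> np.ndarray:
    """Binary junction mask: threshold + morphological dilation.

    ``threshold`` defaults to Otsu on the channel.  The mask is dilated
    by ``dilation_um`` so spots merely adjacent to a junction are also
    excluded.  Warns when the mask is (near-)degenerate.
    """
    img = np.asarray(junction_image, dtype=np.float64)
    if threshold is None:
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=bool) if img.max() == 0 else \
                _warn_full(np.ones(img.shape, dtype=bool))
        threshold = threshold_otsu(img)
    mask = img >= threshold
    r = int(round(dilation_um / pixel_size_um))
    if r > 0 and mask.any():
        mask = ndi.binary_dilation(mask, structure=disk(r))
    frac = mask.mean()
    logger.info("junction mask covers %.1f%% of the frame", 100 * frac)
    if frac >= 0.999:
        _warn_full(mask)
    return mask


def _warn_full(mask: np.ndarray) -> np.ndarray:
    warnings.warn("junction mask covers the whole frame (degenerate)")
    return mask


def filter_spots(spots: pd.DataFrame, quality_threshold: float = 8.0,
                 junction_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Keep spots with quality_snr >= threshold and centers off the junction mask.

    Idempotent; removal counts are logged.
    """
    n0 = len(spots)
    out = spots[spots["quality_snr"] >= quality_threshold]
    n_quality = n0 - len(out)
    n_junction = 0
    if junction_mask is not None and len(out):
        h, w = junction_mask.shape
        rr = np.clip(out["row_px"].round().astype(int), 0, h - 1)
        cc = np.clip(out["col_px"].round().astype(int), 0, w - 1)
        on = junction_mask[rr, cc]
        n_junction = int(on.sum())
        out = out[~on.to_numpy() if isinstance(on, pd.Series) else ~on]
    logger.info("filter_spots: removed %d by quality, %d on junctions (of %d)",
                n_quality, n_junction, n0)
    out = out.reset_index(drop=True)
    out.attrs.update(spots.attrs)
    out.attrs["n_removed_quality"] = n_quality
    out.attrs["n_removed_junction"] = n_junction
    return out


def density(spots: pd.DataFrame, area_um2: float,
            gfp_image: np.ndarray | None = None,
            gfp_threshold: float | None = None,
            pixel_size_um: float | None = None) -> dict:
    """Filopodia per um^2, optionally split by transduction (GFP) status.

    With ``gfp_image`` given, spots are partitioned by the GFP intensity
    at the spot center (>= ``gfp_threshold``, default Otsu) and each
    partition's density is computed over the corresponding cell-area
    fraction (GFP-positive vs -negative area of the frame).
    """
    if area_um2 <= 0:
        raise ValueError("area_um2 must be positive")
    report = {"n_spots": int(len(spots)), "area_um2": float(area_um2),
              "density_per_um2": len(spots) / area_um2}
    if gfp_image is not None:
        if pixel_size_um is None:
            pixel_size_um = spots.attrs.get("pixel_size_um")
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required for the GFP split")
        gfp = np.asarray(gfp_image, dtype=np.float64)
        if gfp_threshold is None:
            gfp_threshold = threshold_otsu(gfp)
        pos_mask = gfp >= gfp_threshold
        px_area = pixel_size_um ** 2
        pos_area = float(pos_mask.sum() * px_area)
        neg_area = float((~pos_mask).sum() * px_area)
        if len(spots):
            h, w = gfp.shape
            rr = np.clip(spots["row_px"].round().astype(int), 0, h - 1)
            cc = np.clip(spots["col_px"].round().astype(int), 0, w - 1)
            is_pos = pos_mask[rr, cc]
        else:
            is_pos = np.zeros(0, dtype=bool)
        n_pos = int(np.sum(is_pos))
        n_neg = int(len(spots) - n_pos)
        report["transduced"] = {
            "n_spots": n_pos, "area_um2": pos_area,
            "density_per_um2": n_pos / pos_area if pos_area > 0 else np.nan,
        }
        report["untransduced"] = {
            "n_spots": n_neg, "area_um2": neg_area,
            "density_per_um2": n_neg / neg_area if neg_area > 0 else np.nan,
        }
    return report


def cell_morphometry(nuclear_image: np.ndarray, junction_image: np.ndarray,
                     icam_image: np.ndarray, pixel_size_um: float,
                     nucleus_diameter_um: float = 5.0,
                     min_nucleus_px: int = 173,
                     min_cell_diameter_um: float = 10.62) -> pd.DataFrame:
    """Per-cell area, circularity and mean ICAM-1 intensity of a monolayer.

    Nuclei are seeded at the ~``nucleus_diameter_um`` scale (Gaussian
    smoothing + Otsu), size-filtered at ``min_nucleus_px``; cells are
    grown from the nuclear seeds by a watershed on the junction channel;
    cells with equivalent diameter below ``min_cell_diameter_um`` or
    touching the border are removed.  Circularity is 2D 4*pi*A/P^2
    (clipped at 1), standing in for the 3D sphericity of volumetric
    pipelines — close but not identical.
    """
    nuc = np.asarray(nuclear_image, dtype=np.float64)
    jct = np.asarray(junction_image, dtype=np.float64)
    icam = np.asarray(icam_image, dtype=np.float64)
    if not (nuc.shape == jct.shape == icam.shape):
        raise ValueError("channels must be registered (same shape)")

    sigma = nucleus_diameter_um / 4.0 / pixel_size_um
    smooth = ndi.gaussian_filter(nuc, sigma)
    if smooth.max() == smooth.min():
        return pd.DataFrame(columns=["label", "area_um2", "circularity", "icam_mean", "row_px", "col_px"])
    nmask = smooth >= threshold_otsu(smooth)
    nlab, _ = ndi.label(nmask)
    sizes = ndi.sum_labels(np.ones_like(nlab), nlab, index=np.arange(1, nlab.max() + 1))
    seeds = np.zeros_like(nlab)
    k = 1
    for lab, sz in enumerate(sizes, start=1):
        if sz >= min_nucleus_px:
            seeds[nlab == lab] = k
            k += 1
    if k == 1:
        return pd.DataFrame(columns=["label", "area_um2", "circularity", "icam_mean", "row_px", "col_px"])

    cells = watershed(jct, seeds)
    cells = clear_border(cells)
    rows = []
    px_area = pixel_size_um ** 2
    for prop in regionprops(cells, intensity_image=icam):
        if prop.equivalent_diameter_area * pixel_size_um < min_cell_diameter_um:
            continue
        perim = prop.perimeter_crofton  # less biased than 4-neighbor estimate
        circ = 4 * np.pi * prop.area / perim ** 2 if perim > 0 else np.nan
        rows.append({
            "label": prop.label,
            "area_um2": prop.area * px_area,
            "circularity": min(float(circ), 1.0),
            "icam_mean": float(prop.intensity_mean),
            "row_px": prop.centroid[0],
            "col_px": prop.centroid[1],
        })
    return pd.DataFrame(rows, columns=["label", "area_um2", "circularity",
                                       "icam_mean", "row_px", "col_px"])
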