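"""Two-wave adhesion spatial statistics and crawling-track metrics.

When two sequential waves of neutrophils are perfused over an
endothelial monolayer, hotspot priming shows up as second-wave cells
adhering closer to first-wave cells than random dots would.  The core
statistic is the signed nearest-neighbor distance of each second-wave
point (or random dot) to the nearest first-wave "surface", modeled here
as a disk of roughly one neutrophil radius around each first-wave
centroid; negative distances mean the point falls inside a surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

__all__ = [
    "signed_nn_distance",
    "random_dot_null",
    "wave_comparison",
    "adhesion_metrics",
    "track_statistics",
]

DEFAULT_SURFACE_RADIUS_UM = 7.5  # ~ neutrophil radius


def signed_nn_distance(query_xy: np.ndarray, target_xy: np.ndarray,
                       target_radius_um: float = 0.0) -> np.ndarray:
    """Distance of each query point to the nearest target surface (um).

    Targets are disks of ``target_radius_um`` around the target points;
    the signed distance is (center distance - radius), negative when the
    query lies inside a disk.  With radius 0 this is the plain (never
    negative) nearest-point distance.
    """
    query = np.atleast_2d(np.asarray(query_xy, dtype=float))
    targets = np.atleast_2d(np.asarray(target_xy, dtype=float))
    if targets.size == 0:
        raise ValueError("empty target set")
    if query.size == 0:
        return np.empty(0)
    tree = cKDTree(targets)
    d, _ = tree.query(query)
    return d - target_radius_um


def random_dot_null(n: int, field_bounds: tuple[float, float], seed: int = 0) -> np.ndarray:
    """n i.i.d. uniform points over a (width, height) field, in um."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    fw, fh = field_bounds
    return rng.uniform([0, 0], [fw, fh], size=(n, 2))


def wave_comparison(wave1_xy: np.ndarray, wave2_xy: np.ndarray,
                    field_bounds: tuple[float, float], seed: int = 0,
                    surface_radius_um: float = DEFAULT_SURFACE_RADIUS_UM,
                    replicates=None) -> dict:
    """Second-wave vs random-dot distances to the nearest first-wave surface.

    Generates exactly ``len(wave2)`` random dots, computes both signed
    distance distributions, and reports medians, quartiles (overall and
    per replicate when labels are given), the median difference and a
    two-sample KS test.
    """
    wave1 = np.atleast_2d(np.asarray(wave1_xy, dtype=float))
    wave2 = np.atleast_2d(np.asarray(wave2_xy, dtype=float))
    if wave1.size == 0 or wave2.size == 0:
        raise ValueError("both waves must be non-empty")
    random_xy = random_dot_null(len(wave2), field_bounds, seed)
    d_wave2 = signed_nn_distance(wave2, wave1, surface_radius_um)
    d_random = signed_nn_distance(random_xy, wave1, surface_radius_um)

    def _summary(d: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3),
                "n": int(d.size)}

    ks = ks_2samp(d_wave2, d_random)
    report = {
        "wave2": _summary(d_wave2),
        "random": _summary(d_random),
        "median_difference": float(np.median(d_wave2) - np.median(d_random)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "distances": pd.DataFrame({
            "distance_um": np.concatenate([d_wave2, d_random]),
            "kind": ["wave2"] * len(d_wave2) + ["random"] * len(d_random),
        }),
    }
    if replicates is not None:
        rep = pd.Series(np.asarray(replicates))
        med = (pd.DataFrame({"rep": rep, "d": d_wave2})
               .groupby("rep")["d"].median())
        report["wave2_replicate_medians"] = med.to_dict()
    return report


def adhesion_metrics(points: pd.DataFrame) -> dict:
    """Adhesion counts, second/first ratio and diapedesis efficacy per wave.

    ``points`` needs columns ``wave`` (1 or 2) and ``state``
    ({"adherent", "transmigrated", "unknown"} — annotations consumed,
    not computed).  Efficacy = transmigrated / (adherent + transmigrated).
    """
    out: dict = {"waves": {}}
    for wave, grp in points.groupby("wave"):
        n_adh = int((grp["state"] == "adherent").sum())
        n_tem = int((grp["state"] == "transmigrated").sum())
        denom = n_adh + n_tem
        out["waves"][int(wave)] = {
            "n_total": int(len(grp)),
            "n_adherent": n_adh,
            "n_transmigrated": n_tem,
            "diapedesis_efficacy": n_tem / denom if denom else 0.0,
        }
    w = out["waves"]
    if 1 in w and 2 in w and w[1]["n_total"] > 0:
        out["second_to_first_ratio"] = w[2]["n_total"] / w[1]["n_total"]
    return out


def track_statistics(tracks: pd.DataFrame, pixel_size_um: float = 1.0,
                     frame_interval_s: float | None = None) -> pd.DataFrame:
    """Per-track path length (um), duration (s) and speed (um/s).

    ``tracks`` is long-format with columns ``track_id``, ``x``, ``y``
    (px unless ``pixel_size_um`` is 1 and data already in um) and either
    ``t_s`` or ``frame`` (+ ``frame_interval_s``).  Tracks with fewer
    than 2 points are excluded; the count is in ``result.attrs``.
    """
    if "t_s" in tracks.columns:
        tcol = "t_s"
        df = tracks.copy()
    elif "frame" in tracks.columns:
        if frame_interval_s is None:
            raise ValueError("frame_interval_s required when only frames are given")
        df = tracks.copy()
        df["t_s"] = df["frame"] * frame_interval_s
        tcol = "t_s"
    else:
        raise ValueError("tracks need a t_s or frame column")
    rows = []
    n_excluded = 0
    for tid, grp in df.sort_values(tcol).groupby("track_id"):
        if len(grp) < 2:
            n_excluded += 1
            continue
        xy = grp[["x", "y"]].to_numpy(dtype=float) * pixel_size_um
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        length = float(seg.sum())
        duration = float(grp[tcol].iloc[-1] - grp[tcol].iloc[0])
        rows.append({
            "track_id": tid,
            "path_length_um": length,
            "duration_s": duration,
            "speed_um_per_s": length / duration if duration > 0 else np.nan,
            "n_points": int(len(grp)),
        })
    out = pd.DataFrame(rows, columns=["track_id", "path_length_um", "duration_s",
                                      "speed_um_per_s", "n_points"])
    out.attrs["n_excluded_short"] = n_excluded
    return out
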