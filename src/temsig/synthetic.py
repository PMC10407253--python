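"""Ground-truth-annotated synthetic microscopy inputs.

Every downstream stage of the toolkit (KTR quantification, responder
clustering, filopodia density, two-wave spatial statistics, ratiometrics)
is exercised against data produced here, so each generator carries its
ground truth alongside the rendered arrays.

The kinase-translocation-reporter (KTR) generator emulates an endothelial
monolayer imaged in two channels: a nuclear marker and a KTR whose
fluorescence redistributes from nucleus to cytoplasm when the kinase is
active.  Kinase activity is a latent per-cell trace ``a(t)`` in [0, 1];
the observable is the cytoplasm/nucleus (C/N) mean-intensity ratio.
Responding cells step up after a known stimulus frame with first-order
rise kinetics; non-responders stay at baseline.  Total KTR fluorescence
per cell is conserved over time (translocation moves signal, it does not
create it).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "SceneSpec",
    "Preset",
    "KtrGroundTruth",
    "CONTROL",
    "NEUTROPHIL",
    "get_preset",
    "gen_traces",
    "gen_ktr_movie",
    "gen_wave_points",
    "gen_filopodia_field",
    "gen_monolayer",
    "gen_ratiometric_traces",
]


# --------------------------------------------------------------------------
# specifications

@dataclass(frozen=True)
class SceneSpec:
    """Geometry and timing of a synthetic KTR time-lapse.

    Defaults mirror the confocal acquisition the pipeline targets:
    512x512 px at 0.33 um/px, 30 frames every 30 s (15 min total) with
    the stimulus at frame 5 (t = 2.5 min).
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.33
    n_cells: int = 20
    nucleus_diameter_px: tuple[float, float] = (32.0, 42.0)
    cell_diameter_px: float = 70.0
    frame_interval_s: float = 30.0
    n_frames: int = 30
    stimulus_frame: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not (0 <= self.stimulus_frame < self.n_frames):
            raise ValueError("stimulus_frame must lie within the movie")
        if max(self.nucleus_diameter_px) >= self.cell_diameter_px:
            raise ValueError("nucleus diameter must be smaller than cell diameter")

    @property
    def stimulus_time_s(self) -> float:
        return self.stimulus_frame * self.frame_interval_s


@dataclass(frozen=True)
class Preset:
    """Condition-level parameters of the KTR generative model.

    ``responder_rate`` is applied exactly: ``round(rate * n)`` cells are
    flagged responders, never a binomial draw, so downstream fraction
    estimates are not confounded by sampling noise in the truth itself.
    """

    name: str
    responder_rate: float
    amplitude: float = 0.4          # C/N units added at full activation
    rise_tau_frames: float = 2.0    # first-order rise time constant
    rise_delay_frames: float = 1.0  # translocation lag after the stimulus
    noise_sd: float = 0.05          # i.i.d. noise on observed C/N traces
    baseline_cn: float = 1.0        # population-mean resting C/N
    baseline_sd: float = 0.1        # cell-to-cell spread of resting C/N


CONTROL = Preset(name="control", responder_rate=0.05)
NEUTROPHIL = Preset(name="neutrophil", responder_rate=0.50)

_PRESETS = {p.name: p for p in (CONTROL, NEUTROPHIL)}


def get_preset(name: str) -> Preset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None


@dataclass
class KtrGroundTruth:
    """Latent truth behind a synthetic KTR dataset (one row per cell)."""

    responder: np.ndarray          # (n,) bool
    activity: np.ndarray           # (n, T) latent a(t) in [0, 1]
    cn: np.ndarray                 # (n, T) noise-free expected C/N
    centroids: np.ndarray          # (n, 2) (row, col) px; static scenes
    nucleus_radius_px: np.ndarray  # (n,)
    cell_radius_px: np.ndarray     # (n,)
    stimulus_frame: int = 5
    frame_interval_s: float = 30.0

    @property
    def n_cells(self) -> int:
        return self.responder.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell": np.arange(self.n_cells),
                "responder": self.responder,
                "row_px": self.centroids[:, 0],
                "col_px": self.centroids[:, 1],
                "nucleus_radius_px": self.nucleus_radius_px,
                "cell_radius_px": self.cell_radius_px,
            }
        )
        return df


# --------------------------------------------------------------------------
# KTR activity model

def _activity_traces(
    responder: np.ndarray,
    n_frames: int,
    stimulus_frame: int,
    amplitude: float,
    tau: float,
    delay: float,
) -> np.ndarray:
    """Latent activity a(t): 0 at rest, first-order rise for responders.

    a(t) = amplitude * (1 - exp(-dt / tau)) with dt measured from
    stimulus_frame + delay; identically 0 for non-responders.
    """
    t = np.arange(n_frames, dtype=float)
    dt = t - (stimulus_frame + delay)
    rise = np.where(dt > 0, 1.0 - np.exp(-np.clip(dt, 0, None) / tau), 0.0)
    return amplitude * responder[:, None].astype(float) * rise[None, :]


def _responder_flags(n_cells: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Exactly round(rate*n) responders, positions shuffled."""
    k = int(round(rate * n_cells))
    flags = np.zeros(n_cells, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def gen_traces(
    n_cells: int,
    preset: Preset | str,
    n_frames: int = 30,
    stimulus_frame: int = 5,
    seed: int = 0,
    frame_interval_s: float = 30.0,
) -> tuple[np.ndarray, KtrGroundTruth]:
    """Draw C/N traces directly from the generative model (no rendering).

    Returns ``(cn_observed, truth)`` where ``cn_observed`` is an
    (n_cells, n_frames) array of baseline + activity + i.i.d. Gaussian
    noise, and ``truth`` carries the noise-free expectation.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    rng = np.random.default_rng(seed)
    responder = _responder_flags(n_cells, preset.responder_rate, rng)
    activity = _activity_traces(
        responder, n_frames, stimulus_frame,
        preset.amplitude, preset.rise_tau_frames, preset.rise_delay_frames,
    )
    baseline = rng.normal(preset.baseline_cn, preset.baseline_sd, size=n_cells)
    baseline = np.clip(baseline, 0.3, None)
    cn = baseline[:, None] + activity
    observed = cn + rng.normal(0.0, preset.noise_sd, size=cn.shape)
    truth = KtrGroundTruth(
        responder=responder,
        activity=activity,
        cn=cn,
        centroids=np.full((n_cells, 2), np.nan),
        nucleus_radius_px=np.full(n_cells, np.nan),
        cell_radius_px=np.full(n_cells, np.nan),
        stimulus_frame=stimulus_frame,
        frame_interval_s=frame_interval_s,
    )
    return observed, truth


# --------------------------------------------------------------------------
# KTR movie rendering

class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails: density too high."""


def _place_cells(spec: SceneSpec, rng: np.random.Generator,
                 margin_px: float = 4.0, max_tries: int = 20000
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping cell disks fully inside the frame."""
    h, w = spec.field_size_px
    r_cell = spec.cell_diameter_px / 2.0
    lo, hi = spec.nucleus_diameter_px
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {spec.n_cells} non-overlapping cells of "
                f"diameter {spec.cell_diameter_px} px in a {h}x{w} px field "
                f"after {max_tries} tries; reduce n_cells or cell size"
            )
        r0 = rng.uniform(r_cell + margin_px, h - r_cell - margin_px)
        c0 = rng.uniform(r_cell + margin_px, w - r_cell - margin_px)
        ok = all((r0 - rr) ** 2 + (c0 - cc) ** 2 >= (2 * r_cell + margin_px) ** 2
                 for rr, cc in centers)
        if ok:
            centers.append((r0, c0))
    centers_arr = np.asarray(centers, dtype=float)
    nuc_r = rng.uniform(lo, hi, size=spec.n_cells) / 2.0
    cell_r = np.full(spec.n_cells, r_cell)
    return centers_arr, nuc_r, cell_r


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    r0, c0 = center
    rr = np.arange(shape[0])[:, None] - r0
    cc = np.arange(shape[1])[None, :] - c0
    return rr * rr + cc * cc <= radius * radius


def gen_ktr_movie(
    spec: SceneSpec,
    preset: Preset | str,
    noise_sd: float = 0.005,
    background_amp: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, KtrGroundTruth]:
    """Render a two-channel KTR time-lapse with known per-cell truth.

    Cells are concentric disks (nucleus inside cytoplasm).  The KTR
    channel distributes a fixed per-cell total fluorescence between the
    two compartments so that the mean-intensity ratio equals the
    ground-truth C/N trace at every frame; the nuclear channel shows
    only nuclei.  ``noise_sd`` (Gaussian read noise) and
    ``background_amp`` (smooth gradient) are in [0, 1] intensity units;
    set both to 0 for a noise-free oracle movie.

    Returns ``(nuclear_stack, ktr_stack, truth)`` as float32 stacks in
    [0, 1], frame-major.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    rng = np.random.default_rng(spec.seed)
    centers, nuc_r, cell_r = _place_cells(spec, rng)
    responder = _responder_flags(spec.n_cells, preset.responder_rate, rng)
    activity = _activity_traces(
        responder, spec.n_frames, spec.stimulus_frame,
        preset.amplitude, preset.rise_tau_frames, preset.rise_delay_frames,
    )
    baseline = np.clip(
        rng.normal(preset.baseline_cn, preset.baseline_sd, size=spec.n_cells), 0.3, None
    )
    cn = baseline[:, None] + activity  # (n, T)

    h, w = spec.field_size_px
    nuc_level = 0.5
    n0_conc = 0.35  # nuclear KTR concentration at frame 0 sets each cell's total

    nuc_masks = [_disk_mask((h, w), tuple(centers[i]), nuc_r[i]) for i in range(spec.n_cells)]
    cell_masks = [_disk_mask((h, w), tuple(centers[i]), cell_r[i]) for i in range(spec.n_cells)]
    a_nuc = np.array([m.sum() for m in nuc_masks], dtype=float)
    a_cyt = np.array([(cm & ~nm).sum() for cm, nm in zip(cell_masks, nuc_masks)], dtype=float)
    total = n0_conc * (a_nuc + cn[:, 0] * a_cyt)  # conserved per cell

    nuclear = np.zeros((spec.n_frames, h, w), dtype=np.float64)
    ktr = np.zeros_like(nuclear)

    nuc_frame = np.zeros((h, w))
    for i in range(spec.n_cells):
        nuc_frame[nuc_masks[i]] = nuc_level
    for t in range(spec.n_frames):
        frame = np.zeros((h, w))
        for i in range(spec.n_cells):
            n_conc = total[i] / (a_nuc[i] + cn[i, t] * a_cyt[i])
            c_conc = cn[i, t] * n_conc
            frame[cell_masks[i] & ~nuc_masks[i]] = c_conc
            frame[nuc_masks[i]] = n_conc
        ktr[t] = frame
        nuclear[t] = nuc_frame

    if background_amp > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        grad = background_amp * (0.5 * yy / max(h - 1, 1) + 0.5 * xx / max(w - 1, 1))
        nuclear += grad
        ktr += grad
    if noise_sd > 0:
        nuclear += rng.normal(0.0, noise_sd, nuclear.shape)
        ktr += rng.normal(0.0, noise_sd, ktr.shape)

    np.clip(nuclear, 0.0, 1.0, out=nuclear)
    np.clip(ktr, 0.0, 1.0, out=ktr)

    truth = KtrGroundTruth(
        responder=responder,
        activity=activity,
        cn=cn,
        centroids=centers,
        nucleus_radius_px=nuc_r,
        cell_radius_px=cell_r,
        stimulus_frame=spec.stimulus_frame,
        frame_interval_s=spec.frame_interval_s,
    )
    return nuclear.astype(np.float32), ktr.astype(np.float32), truth


# --------------------------------------------------------------------------
# two-wave adhesion point sets

def gen_wave_points(
    n_first: int,
    n_second: int,
    field_um: tuple[float, float] = (1330.0, 1330.0),
    hotspot_attraction: float = 0.5,
    n_hotspots: int = 5,
    hotspot_sd_um: float = 40.0,
    attract_radius_um: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two sequential waves of adherent-cell positions.

    First-wave points cluster around ``n_hotspots`` centers (Gaussian
    spread ``hotspot_sd_um``).  Exactly ``round(hotspot_attraction *
    n_second)`` second-wave points are placed within ``attract_radius_um``
    of a random first-wave point; the remainder are uniform over the
    field.  Returns ``(wave1_xy_um, wave2_xy_um)``.
    """
    if not (0.0 <= hotspot_attraction <= 1.0):
        raise ValueError("hotspot_attraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fw, fh = field_um

    def _uniform(n: int) -> np.ndarray:
        return rng.uniform([0, 0], [fw, fh], size=(n, 2))

    hotspots = rng.uniform([0.1 * fw, 0.1 * fh], [0.9 * fw, 0.9 * fh], size=(n_hotspots, 2))
    which = rng.integers(0, n_hotspots, size=n_first)
    wave1 = hotspots[which] + rng.normal(0.0, hotspot_sd_um, size=(n_first, 2))
    wave1 = np.clip(wave1, [0, 0], [fw, fh])

    n_attracted = int(round(hotspot_attraction * n_second))
    parts = []
    if n_attracted > 0:
        if n_first == 0:
            raise ValueError("cannot attract second-wave points without a first wave")
        anchors = wave1[rng.integers(0, n_first, size=n_attracted)]
        theta = rng.uniform(0, 2 * np.pi, size=n_attracted)
        rad = attract_radius_um * np.sqrt(rng.uniform(0, 1, size=n_attracted))
        pts = anchors + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
        parts.append(np.clip(pts, [0, 0], [fw, fh]))
    if n_second - n_attracted > 0:
        parts.append(_uniform(n_second - n_attracted))
    wave2 = np.vstack(parts) if parts else np.empty((0, 2))
    return wave1, wave2


# --------------------------------------------------------------------------
# filopodia fields

def gen_filopodia_field(
    field_um: tuple[float, float] = (200.0, 200.0),
    density_per_um2: float = 0.005,
    pixel_size_um: float = 0.08,
    spot_diameter_um: float = 0.6,
    spot_amplitude: float = 1.0,
    texture_amp: float = 0.06,
    junction_lines: bool = True,
    n_junctions: int = 6,
    junction_width_um: float = 1.0,
    junction_amp: float = 0.5,
    junction_spot_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Apical-membrane field with planted diffraction-limited spots.

    The image is a smooth membrane texture plus Gaussian spots of FWHM
    ``spot_diameter_um`` and, optionally, bright junction ridges.
    Exactly ``round(density * area)`` spots are planted, pairwise
    separated by at least two spot diameters; a fraction
    ``junction_spot_fraction`` of them is placed on the junction ridges,
    the rest away from them.  Returns ``(image, truth, junction_mask)``
    where ``truth`` has columns x_um, y_um, row_px, col_px, on_junction.
    """
    rng = np.random.default_rng(seed)
    fw, fh = field_um
    area = fw * fh
    n_spots = int(round(density_per_um2 * area))
    h = int(round(fh / pixel_size_um))
    w = int(round(fw / pixel_size_um))

    # junction ridges: random chords across the field
    junction_mask = np.zeros((h, w), dtype=bool)
    if junction_lines:
        yy, xx = np.mgrid[0:h, 0:w]
        half_w = junction_width_um / 2.0 / pixel_size_um
        for _ in range(n_junctions):
            p = rng.uniform([0, 0], [h, w])
            ang = rng.uniform(0, np.pi)
            nvec = np.array([np.sin(ang), np.cos(ang)])
            dist = np.abs((yy - p[0]) * nvec[0] + (xx - p[1]) * nvec[1])
            junction_mask |= dist <= half_w

    min_sep_px = 2.0 * spot_diameter_um / pixel_size_um
    margin = 3.0 * spot_diameter_um / pixel_size_um
    n_on = int(round(junction_spot_fraction * n_spots))
    on_flags = np.zeros(n_spots, dtype=bool)
    on_flags[:n_on] = True
    centers: list[tuple[float, float]] = []
    tries, max_tries = 0, 200000
    jm_idx = np.argwhere(junction_mask)
    # off-junction spots keep a clear margin from the ridges so that
    # junction exclusion and spot detection stay unambiguous
    free_margin_px = spot_diameter_um / pixel_size_um
    if junction_lines and junction_mask.any():
        dist_to_junction = ndi.distance_transform_edt(~junction_mask)
    else:
        dist_to_junction = None
    for i in range(n_spots):
        while True:
            tries += 1
            if tries > max_tries:
                raise PlacementError(
                    f"could not plant {n_spots} spots separated by "
                    f"{2 * spot_diameter_um} um; density {density_per_um2}/um2 too high"
                )
            if on_flags[i]:
                if jm_idx.size == 0:
                    raise ValueError("junction_spot_fraction > 0 requires junction_lines")
                r0, c0 = jm_idx[rng.integers(0, len(jm_idx))].astype(float)
                r0 += rng.uniform(-0.5, 0.5)
                c0 += rng.uniform(-0.5, 0.5)
                if not (margin <= r0 < h - margin and margin <= c0 < w - margin):
                    continue
            else:
                r0 = rng.uniform(margin, h - margin)
                c0 = rng.uniform(margin, w - margin)
                ir, ic = int(round(r0)), int(round(c0))
                if dist_to_junction is not None and \
                        dist_to_junction[ir, ic] <= free_margin_px:
                    continue
            if all((r0 - rr) ** 2 + (c0 - cc) ** 2 >= min_sep_px ** 2 for rr, cc in centers):
                centers.append((r0, c0))
                break

    # membrane texture: heavily smoothed noise, amplitude well below spots
    texture_sigma_px = 2.0 / pixel_size_um
    texture = ndi.gaussian_filter(rng.normal(0, 1, (h, w)), texture_sigma_px)
    sd = texture.std()
    if sd > 0:
        texture = texture / sd * texture_amp
    image = 0.2 + texture
    if junction_lines:
        ridge = ndi.gaussian_filter(junction_mask.astype(float), 1.0)
        image = image + junction_amp * ridge

    sigma_px = spot_diameter_um / 2.3548 / pixel_size_um  # FWHM -> sigma
    spots_img = np.zeros((h, w))
    for r0, c0 in centers:
        ir, ic = int(round(r0)), int(round(c0))
        ext = int(math.ceil(4 * sigma_px))
        rs, re = max(0, ir - ext), min(h, ir + ext + 1)
        cs, ce = max(0, ic - ext), min(w, ic + ext + 1)
        ry = np.arange(rs, re)[:, None] - r0
        cx = np.arange(cs, ce)[None, :] - c0
        spots_img[rs:re, cs:ce] += spot_amplitude * np.exp(
            -(ry * ry + cx * cx) / (2 * sigma_px * sigma_px)
        )
    image = image + spots_img

    if centers:
        arr = np.asarray(centers)
        truth = pd.DataFrame(
            {
                "row_px": arr[:, 0],
                "col_px": arr[:, 1],
                "x_um": arr[:, 1] * pixel_size_um,
                "y_um": arr[:, 0] * pixel_size_um,
                "on_junction": on_flags,
            }
        )
    else:
        truth = pd.DataFrame(
            columns=["row_px", "col_px", "x_um", "y_um", "on_junction"]
        )
    return image, truth, junction_mask


# --------------------------------------------------------------------------
# Voronoi monolayer for morphometry

def gen_monolayer(
    field_um: tuple[float, float] = (300.0, 300.0),
    n_cells: int = 25,
    pixel_size_um: float = 0.5,
    nucleus_diameter_um: float = 10.0,
    icam_base: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Confluent monolayer as a Voronoi tessellation with drawn junctions.

    Returns ``(nuclear, junction, icam, labels, truth)``: three
    registered single-frame channels, the ground-truth label image and a
    per-cell table (area_um2, icam_mean, seed position).
    """
    rng = np.random.default_rng(seed)
    fw, fh = field_um
    h = int(round(fh / pixel_size_um))
    w = int(round(fw / pixel_size_um))
    # jittered grid seeds keep cells convex-ish and comparably sized
    grid = int(math.ceil(math.sqrt(n_cells)))
    gy = (np.arange(grid) + 0.5) * h / grid
    gx = (np.arange(grid) + 0.5) * w / grid
    pts = np.array([(y, x) for y in gy for x in gx])[:n_cells]
    pts = pts + rng.uniform(-0.25, 0.25, pts.shape) * np.array([h / grid, w / grid])

    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy[None] - pts[:, 0, None, None]) ** 2 + (xx[None] - pts[:, 1, None, None]) ** 2
    labels = np.argmin(d2, axis=0).astype(np.int32) + 1

    from skimage.segmentation import find_boundaries

    boundaries = find_boundaries(labels, mode="thick")
    junction = ndi.gaussian_filter(boundaries.astype(float), 1.0)
    junction = 0.8 * junction / max(junction.max(), 1e-12)

    nuclear = np.zeros((h, w))
    nuc_r_px = nucleus_diameter_um / 2.0 / pixel_size_um
    for i in range(n_cells):
        nuclear += 0.6 * np.exp(-((yy - pts[i, 0]) ** 2 + (xx - pts[i, 1]) ** 2)
                                / (2 * (nuc_r_px / 1.5) ** 2))

    icam_levels = icam_base + rng.uniform(0.0, 0.4, n_cells)
    icam = icam_levels[labels - 1]
    icam = icam + 0.02 * rng.normal(0, 1, (h, w))

    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_cells + 1))
    truth = pd.DataFrame(
        {
            "label": np.arange(1, n_cells + 1),
            "area_um2": areas * pixel_size_um ** 2,
            "icam_mean": icam_levels,
            "row_px": pts[:, 0],
            "col_px": pts[:, 1],
        }
    )
    return nuclear, junction, icam, labels, truth


# --------------------------------------------------------------------------
# ratiometric traces

def gen_ratiometric_traces(kind: str, params: dict | None = None, seed: int = 0):
    """Synthetic FRAP / FRET / crosstalk inputs.

    kind="frap"      -> DataFrame(time_s, intensity): pre-bleach plateau,
                        instantaneous drop at the bleach time, exponential
                        recovery to ``recovery_fraction`` of the bleached depth.
    kind="fret"      -> DataFrame(time_s, acceptor, donor): the acceptor/donor
                        ratio steps by ``step_factor`` at ``step_frame``.
    kind="crosstalk" -> (stacks, bleed): ``stacks[i][j]`` is the image of
                        fluorophore i in channel j; planted bleed fractions
                        returned as the ground-truth matrix.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "frap":
        n_frames = params.pop("n_frames", 120)
        dt = params.pop("frame_interval_s", 5.0)
        t_bleach = params.pop("t_bleach_s", 15.0)
        depth = params.pop("bleach_depth", 0.8)
        rec = params.pop("recovery_fraction", 0.7)
        tau = params.pop("recovery_tau_s", 30.0)
        noise = params.pop("noise_sd", 0.0)
        t = np.arange(n_frames) * dt
        i0 = 1.0
        trace = np.full(n_frames, i0)
        post = t >= t_bleach
        trace[post] = (i0 - depth) + depth * rec * (1 - np.exp(-(t[post] - t_bleach) / tau))
        trace = trace + rng.normal(0, noise, n_frames)
        return pd.DataFrame({"time_s": t, "intensity": trace})
    if kind == "fret":
        n_frames = params.pop("n_frames", 60)
        dt = params.pop("frame_interval_s", 5.0)
        step_frame = params.pop("step_frame", 10)
        step = params.pop("step_factor", 1.5)
        base_ratio = params.pop("base_ratio", 1.0)
        donor_level = params.pop("donor_level", 1.0)
        noise = params.pop("noise_sd", 0.0)
        t = np.arange(n_frames) * dt
        ratio = np.where(np.arange(n_frames) >= step_frame, base_ratio * step, base_ratio)
        donor = donor_level + rng.normal(0, noise, n_frames)
        acceptor = ratio * donor_level + rng.normal(0, noise, n_frames)
        return pd.DataFrame({"time_s": t, "acceptor": acceptor, "donor": donor})
    if kind == "crosstalk":
        n_fp = params.pop("n_fluorophores", 3)
        bleed = params.pop("bleed", None)
        shape = params.pop("shape", (64, 64))
        amp = params.pop("amplitude", 0.8)
        noise = params.pop("noise_sd", 0.0)
        if bleed is None:
            bleed = np.full((n_fp, n_fp), 0.02)
            np.fill_diagonal(bleed, 1.0)
        bleed = np.asarray(bleed, dtype=float)
        n_fp = bleed.shape[0]
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        stacks = []
        for i in range(n_fp):
            cy = rng.uniform(0.3 * h, 0.7 * h)
            cx = rng.uniform(0.3 * w, 0.7 * w)
            blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (h / 8) ** 2))
            chans = []
            for j in range(n_fp):
                img = amp * bleed[i, j] * blob
                if noise > 0:
                    img = img + rng.normal(0, noise, (h, w))
                chans.append(img)
            stacks.append(np.stack(chans))
        return np.stack(stacks), bleed
    raise ValueError(f"unknown kind {kind!r}; choose frap, fret or crosstalk")
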