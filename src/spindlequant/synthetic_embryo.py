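"""Synthetic time-lapse movies of a mitotic syncytial-embryo field.

Generates multi-channel 16-bit movies of a cortical field of nuclei, each
flanked by two spindle poles, with fully known ("ground truth") kinetics and
geometry so that every downstream stage — ROI rasterization, intensity
extraction, tracking, fold-change normalization and the statistical layer —
can be tested by parameter recovery.

Scene model
-----------
The marker channel is a uniform cytoplasmic background ``b * g(t)`` (with
``g`` declining linearly by ``cytoplasm_depletion_frac`` over the movie),
nuclei rendered as dimmer disks, and one isotropic 2-D Gaussian spot per
spindle pole.  The spot amplitude at each frame is calibrated so that the
mean intensity inside a pole-centred measurement disk (2 um diameter by
default) equals ``b * r(t)``, where the relative pole intensity

    r(t) = pole_t0_rel + slope1 * t                      for t <= break
    r(t) = pole_t0_rel + slope1 * break + slope2 * (t - break)   after,

capped so the pole fold change ``r(t)/r(0)`` never exceeds
``1 + peak_enrichment``.  A measurement ROI centred on the pole therefore
reads back the programmed piecewise-linear kinetics exactly (up to 16-bit
rounding) in the noise-free case.

Pole motion: the pole-pair axis rocks about the nucleus centre by
``rocking_amplitude_deg * sin(2*pi*t/rocking_period_s)``; before NEB each
pole additionally jitters with per-axis s.d. ``pre_neb_jitter_sd_um``; after
NEB the pair translates along its axis on a linear ramp whose endpoint is
solved so that the maximum pole displacement from its time-0 position equals
exactly ``post_neb_drift_max_um`` at the last frame (the rocking
contribution is accounted for, so the cap is reached but never exceeded).

Additive Gaussian camera noise is applied after scene composition; Poisson
shot noise and photobleaching are deliberately omitted.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging_io import MAX_UINT16, Movie
from .roi_model import DEFAULT_ROI_DIAMETER_UM, disk_pixel_coords

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "GeometryError",
    "generate_movie",
    "builtin_preset",
    "preset_names",
    "write_ground_truth",
    "read_ground_truth",
    "roi_table_from_ground_truth",
]

MARKER = "marker"
NUCLEI = "nuclei"


class GeometryError(ValueError):
    """Simulation geometry would place a pole (or its ROI) outside the field."""


@dataclass(frozen=True)
class SimulationParams:
    """Complete parameterization of one synthetic movie.

    Physical defaults follow common acquisition settings for cortical
    syncytial-division imaging: 0.1 um/px on a 512 x 512 field, 35 s frame
    interval, 10 frames, 20 nuclei (matching a 20-spindle-ROI analysis),
    nuclear envelope breakdown at 105 s (spindles not yet morphologically
    visible at 0, 35 and 70 s).
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.1
    n_frames: int = 10
    frame_interval_s: float = 35.0
    n_nuclei: int = 20
    nucleus_radius_um: float = 2.5
    pole_offset_um: float = 3.5
    pole_sigma_um: float = 0.75
    enrichment_slope1_per_s: float = 0.0
    enrichment_slope2_per_s: float = 0.0
    phase_break_s: float = 105.0
    peak_enrichment: float = math.inf
    cytoplasm_depletion_frac: float = 0.0
    rocking_amplitude_deg: float = 0.0
    rocking_period_s: float = 140.0
    pre_neb_jitter_sd_um: float = 0.0
    post_neb_drift_max_um: float = 0.0
    neb_time_s: float = 105.0
    noise_sd: float = 0.0
    seed: int = 0
    # instrument / rendering details
    background_intensity: float = 1000.0
    pole_t0_rel: float = 1.0
    nucleus_dim_factor: float = 0.6
    calib_roi_diameter_um: float = DEFAULT_ROI_DIAMETER_UM
    n_cytoplasm_sites: int = 20

    def __post_init__(self) -> None:
        positive = {
            "pixel_size_um": self.pixel_size_um,
            "n_frames": self.n_frames,
            "frame_interval_s": self.frame_interval_s,
            "n_nuclei": self.n_nuclei,
            "nucleus_radius_um": self.nucleus_radius_um,
            "pole_offset_um": self.pole_offset_um,
            "pole_sigma_um": self.pole_sigma_um,
            "rocking_period_s": self.rocking_period_s,
            "background_intensity": self.background_intensity,
            "pole_t0_rel": self.pole_t0_rel,
            "calib_roi_diameter_um": self.calib_roi_diameter_um,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ValueError(f"{name} must be > 0")
        nonneg = {
            "phase_break_s": self.phase_break_s,
            "peak_enrichment": self.peak_enrichment,
            "rocking_amplitude_deg": self.rocking_amplitude_deg,
            "pre_neb_jitter_sd_um": self.pre_neb_jitter_sd_um,
            "post_neb_drift_max_um": self.post_neb_drift_max_um,
            "neb_time_s": self.neb_time_s,
            "noise_sd": self.noise_sd,
        }
        for name, val in nonneg.items():
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.cytoplasm_depletion_frac <= 1.0):
            raise ValueError("cytoplasm_depletion_frac must be in [0, 1]")
        if self.phase_break_s > self.duration_s + self.frame_interval_s:
            raise ValueError("phase_break_s must lie within the movie duration")

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s

    @property
    def field_size_um(self) -> tuple[float, float]:
        ny, nx = self.field_size_px
        return ((ny - 1) * self.pixel_size_um, (nx - 1) * self.pixel_size_um)

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class GroundTruth:
    """The simulator's programmed kinetics and geometry, for recovery tests."""

    params: SimulationParams
    #: one row per pole per frame: nucleus, pole, frame, time_s, x_um, y_um, fold
    pole_table: pd.DataFrame
    cytoplasm_fold: np.ndarray
    rocking_deg: np.ndarray
    max_displacement_um: float
    cytoplasm_centers_um: np.ndarray

    def pole_trajectory(self, nucleus: int, pole: str) -> np.ndarray:
        """(n_frames, 2) array of true (x, y) positions of one pole, in um."""
        sub = self.pole_table[
            (self.pole_table["nucleus"] == nucleus)
            & (self.pole_table["pole"] == pole)
        ].sort_values("frame")
        return sub[["x_um", "y_um"]].to_numpy()

    def pole_fold(self) -> np.ndarray:
        """The programmed pole fold-change series (identical for all poles)."""
        sub = self.pole_table[
            (self.pole_table["nucleus"] == 0) & (self.pole_table["pole"] == "a")
        ].sort_values("frame")
        return sub["fold"].to_numpy()


# ---------------------------------------------------------------------------
# kinetic curves


def _cytoplasm_fold(p: SimulationParams) -> np.ndarray:
    t = p.times_s()
    span = p.duration_s if p.duration_s > 0 else 1.0
    return 1.0 - p.cytoplasm_depletion_frac * t / span


def _pole_rel_intensity(p: SimulationParams) -> np.ndarray:
    t = p.times_s()
    ramp = np.where(
        t <= p.phase_break_s,
        p.enrichment_slope1_per_s * t,
        p.enrichment_slope1_per_s * p.phase_break_s
        + p.enrichment_slope2_per_s * (t - p.phase_break_s),
    )
    r = p.pole_t0_rel + ramp
    if math.isfinite(p.peak_enrichment):
        r = np.minimum(r, p.pole_t0_rel * (1.0 + p.peak_enrichment))
    return r


# ---------------------------------------------------------------------------
# geometry


def _nucleus_grid(p: SimulationParams) -> np.ndarray:
    """Deterministic nucleus centres (um) on an even grid with edge margin."""
    h_um, w_um = self_sizes = p.field_size_um
    margin = _edge_margin(p)
    if 2 * margin >= min(self_sizes):
        raise GeometryError(
            f"field of {w_um:.1f} x {h_um:.1f} um cannot hold nuclei with "
            f"pole excursions needing a {margin:.1f} um edge margin"
        )
    n = p.n_nuclei
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    xs = (
        np.linspace(margin, w_um - margin, ncols)
        if ncols > 1
        else np.array([w_um / 2.0])
    )
    ys = (
        np.linspace(margin, h_um - margin, nrows)
        if nrows > 1
        else np.array([h_um / 2.0])
    )
    centers = [(x, y) for y in ys for x in xs][:n]
    if ncols > 1:
        min_gap = (xs[1] - xs[0]) - 2 * p.pole_offset_um
        if min_gap < DEFAULT_ROI_DIAMETER_UM:
            raise GeometryError(
                f"nucleus spacing leaves only {min_gap:.2f} um between "
                "neighbouring pole ROIs; reduce n_nuclei or pole_offset_um"
            )
    return np.asarray(centers, dtype=float)


def _edge_margin(p: SimulationParams) -> float:
    roi_r = p.calib_roi_diameter_um / 2.0
    return (
        p.pole_offset_um
        + p.post_neb_drift_max_um
        + 3.0 * p.pre_neb_jitter_sd_um
        + roi_r
        + 0.5
    )


def _post_neb_ramp_end(p: SimulationParams, theta_final_rad: float) -> float:
    """Translation magnitude at the last frame so that the maximum pole
    displacement from time 0 equals exactly post_neb_drift_max_um.

    For the pole on the adverse side, the displacement satisfies
    ``d^2 = u^2 + 2*u*offset*(1-cos(theta)) + 2*offset^2*(1-cos(theta))``;
    solve for u at d = cap.
    """
    cap = p.post_neb_drift_max_um
    if cap == 0:
        return 0.0
    off = p.pole_offset_um
    beta = off * (1.0 - math.cos(theta_final_rad))
    q = 2.0 * off**2 * (1.0 - math.cos(theta_final_rad))
    disc = beta**2 - q + cap**2
    if disc <= 0:
        return 0.0  # rocking alone already consumes the displacement budget
    return -beta + math.sqrt(disc)


def _pole_positions(
    p: SimulationParams,
    centers: np.ndarray,
    axis_angles: np.ndarray,
    rocking_rad: np.ndarray,
    jitter: np.ndarray,
) -> np.ndarray:
    """(n_frames, n_nuclei, 2 poles, 2 xy) true pole positions in um."""
    t = p.times_s()
    n_f, n_n = p.n_frames, p.n_nuclei
    pos = np.zeros((n_f, n_n, 2, 2))
    theta_final = rocking_rad[-1]
    u_end = _post_neb_ramp_end(p, theta_final)
    post_span = max(p.duration_s - p.neb_time_s, 0.0)
    for k in range(n_f):
        theta = rocking_rad[k]
        pre_neb = t[k] < p.neb_time_s
        if pre_neb or post_span == 0:
            u = 0.0
        else:
            u = u_end * (t[k] - p.neb_time_s) / post_span
        for i in range(n_n):
            phi = axis_angles[i]
            e_r = np.array([math.cos(phi), math.sin(phi)])
            rot = phi + theta
            e_rot = np.array([math.cos(rot), math.sin(rot)])
            for s_idx, s in enumerate((+1.0, -1.0)):
                xy = centers[i] + s * p.pole_offset_um * e_rot + u * e_r
                if pre_neb:
                    xy = xy + jitter[k, i, s_idx]
                pos[k, i, s_idx] = xy
    return pos


def _cytoplasm_sites(
    p: SimulationParams,
    centers: np.ndarray,
    pole_pos: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rejection-sample cytoplasm ROI centres clear of nuclei and pole spots."""
    h_um, w_um = p.field_size_um
    roi_r = p.calib_roi_diameter_um / 2.0
    margin = roi_r + 0.1
    nuc_excl = p.nucleus_radius_um + roi_r
    n_sites = p.n_cytoplasm_sites
    pole_excl = roi_r + 2.0 * p.pole_sigma_um + 0.5
    flat_poles = pole_pos.reshape(-1, 2)
    sites: list[np.ndarray] = []
    for _ in range(20000):
        if len(sites) == n_sites:
            break
        cand = rng.uniform([margin, margin], [w_um - margin, h_um - margin])
        if np.min(np.linalg.norm(centers - cand, axis=1)) < nuc_excl:
            continue
        if np.min(np.linalg.norm(flat_poles - cand, axis=1)) < pole_excl:
            continue
        if sites and np.min(np.linalg.norm(np.array(sites) - cand, axis=1)) < (
            2 * roi_r + 0.2
        ):
            continue
        sites.append(cand)
    if len(sites) < n_sites:
        raise GeometryError(
            f"could not place {n_sites} cytoplasm ROIs clear of nuclei/poles"
        )
    return np.array(sites)


# ---------------------------------------------------------------------------
# rendering


def _render_marker_frame(
    p: SimulationParams,
    centers: np.ndarray,
    pole_xy: np.ndarray,
    g: float,
    r: float,
) -> np.ndarray:
    """Noise-free marker-channel frame as float64."""
    shape = p.field_size_px
    px = p.pixel_size_um
    b = p.background_intensity
    img = np.full(shape, b * g, dtype=np.float64)
    for cx, cy in centers:
        rr, cc = disk_pixel_coords((cx, cy), p.nucleus_radius_um, shape, px)
        img[rr, cc] = b * g * p.nucleus_dim_factor
    sigma = p.pole_sigma_um
    patch_r = 4.0 * sigma
    calib_r = p.calib_roi_diameter_um / 2.0
    for xy in pole_xy.reshape(-1, 2):
        cx, cy = float(xy[0]), float(xy[1])
        # calibrate the spot amplitude against the pole-centred measurement disk
        rr, cc = disk_pixel_coords((cx, cy), calib_r, shape, px)
        if rr.size == 0:
            raise GeometryError(f"pole at ({cx:.2f}, {cy:.2f}) um leaves the field")
        d2 = (cc * px - cx) ** 2 + (rr * px - cy) ** 2
        gbar = float(np.mean(np.exp(-d2 / (2.0 * sigma**2))))
        amp = b * (r - g) / gbar
        if amp != 0.0:
            pr, pc = disk_pixel_coords((cx, cy), patch_r, shape, px)
            pd2 = (pc * px - cx) ** 2 + (pr * px - cy) ** 2
            img[pr, pc] += amp * np.exp(-pd2 / (2.0 * sigma**2))
    return img


def _render_nuclei_frame(p: SimulationParams, centers: np.ndarray) -> np.ndarray:
    shape = p.field_size_px
    img = np.full(shape, 100.0, dtype=np.float64)
    for cx, cy in centers:
        rr, cc = disk_pixel_coords(
            (cx, cy), p.nucleus_radius_um, shape, p.pixel_size_um
        )
        img[rr, cc] = 3000.0
    return img


def generate_movie(params: SimulationParams) -> tuple[Movie, GroundTruth]:
    """Render a synthetic movie and return it with its ground truth.

    Identical ``params`` (including the seed) give bit-identical output.
    Geometry that would place any pole or its measurement disk outside the
    field raises :class:`GeometryError`.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    centers = _nucleus_grid(p)
    axis_angles = rng.uniform(0.0, 2.0 * math.pi, size=p.n_nuclei)
    jitter = np.zeros((p.n_frames, p.n_nuclei, 2, 2))
    if p.pre_neb_jitter_sd_um > 0:
        jitter = rng.normal(
            0.0, p.pre_neb_jitter_sd_um, size=(p.n_frames, p.n_nuclei, 2, 2)
        )
        jitter[0] = 0.0  # frame 0 is the displacement reference
    t = p.times_s()
    rocking_rad = np.deg2rad(p.rocking_amplitude_deg) * np.sin(
        2.0 * math.pi * t / p.rocking_period_s
    )
    pole_pos = _pole_positions(p, centers, axis_angles, rocking_rad, jitter)
    cyto_sites = _cytoplasm_sites(p, centers, pole_pos, rng)

    g = _cytoplasm_fold(p)
    r = _pole_rel_intensity(p)
    fold = r / r[0]

    frames = np.empty((p.n_frames, 2, *p.field_size_px), dtype=np.uint16)
    nuclei_frame = _render_nuclei_frame(p, centers)
    for k in range(p.n_frames):
        marker = _render_marker_frame(p, centers, pole_pos[k], g[k], r[k])
        nuclei = nuclei_frame.copy()
        if p.noise_sd > 0:
            marker = marker + rng.normal(0.0, p.noise_sd, size=marker.shape)
            nuclei = nuclei + rng.normal(0.0, p.noise_sd, size=nuclei.shape)
        frames[k, 0] = np.clip(np.round(marker), 0, MAX_UINT16).astype(np.uint16)
        frames[k, 1] = np.clip(np.round(nuclei), 0, MAX_UINT16).astype(np.uint16)

    movie = Movie(
        data=frames,
        pixel_size_um=p.pixel_size_um,
        frame_interval_s=p.frame_interval_s,
        channel_names=[MARKER, NUCLEI],
    )

    rows = []
    for i in range(p.n_nuclei):
        for s_idx, pole in enumerate("ab"):
            for k in range(p.n_frames):
                rows.append(
                    {
                        "nucleus": i,
                        "pole": pole,
                        "frame": k,
                        "time_s": t[k],
                        "x_um": pole_pos[k, i, s_idx, 0],
                        "y_um": pole_pos[k, i, s_idx, 1],
                        "fold": fold[k],
                    }
                )
    pole_table = pd.DataFrame(rows)
    disp = np.linalg.norm(pole_pos - pole_pos[0][None], axis=-1)
    gt = GroundTruth(
        params=p,
        pole_table=pole_table,
        cytoplasm_fold=g,
        rocking_deg=np.rad2deg(rocking_rad),
        max_displacement_um=float(disp.max()),
        cytoplasm_centers_um=cyto_sites,
    )
    return movie, gt


# ---------------------------------------------------------------------------
# presets

# Slopes for the 10-frame enrichment movies: a slow prophase rise to NEB at
# 105 s, then a faster prometaphase rise that reaches the programmed plateau
# around 245 s (frame 7).
_ENRICH_SLOPE1 = 0.0005
_ENRICH_SLOPE2 = 0.00106

# Gaussian spot width for which the max/mean enrichment ratio inside a 1 um
# radius disk is 2 (so a 0.2 mean-fold peak reads 0.4 in max intensity, with
# 10% cytoplasmic depletion): solves (1-exp(-x))/x = (1.2-0.9)/(1.4-0.9),
# x = R^2 / (2 sigma^2).
_REEPB_SIGMA_UM = 0.6646


def _presets() -> dict[str, SimulationParams]:
    base_enrich = dict(
        enrichment_slope1_per_s=_ENRICH_SLOPE1,
        enrichment_slope2_per_s=_ENRICH_SLOPE2,
        phase_break_s=105.0,
        neb_time_s=105.0,
        cytoplasm_depletion_frac=0.1,
        pre_neb_jitter_sd_um=0.05,
        post_neb_drift_max_um=0.1,
        noise_sd=5.0,
    )
    fig2 = dict(
        field_size_px=(256, 256),
        n_frames=23,
        frame_interval_s=30.0,
        n_nuclei=1,
        phase_break_s=540.0,
        neb_time_s=540.0,
        cytoplasm_depletion_frac=0.0,
        noise_sd=0.0,
    )
    return {
        # Rtnl1-GFP: mean and max spindle intensity peak at +0.2 fold over T0
        "fig1d_rtnl1": SimulationParams(peak_enrichment=0.2, **base_enrich),
        # ReepB-GFP: max peaks at +0.4, mean at +0.2
        "fig1f_reepb": SimulationParams(
            peak_enrichment=0.2, pole_sigma_um=_REEPB_SIGMA_UM, **base_enrich
        ),
        # single-pole intensity trace, two-phase kinetics (slopes in
        # baseline-normalized intensity units per second)
        "fig2_rtnl1": SimulationParams(
            enrichment_slope1_per_s=0.01024,
            enrichment_slope2_per_s=0.06733,
            **fig2,
        ),
        "fig2_kdel": SimulationParams(
            enrichment_slope1_per_s=-0.004510,
            enrichment_slope2_per_s=0.1116,
            pole_t0_rel=3.0,
            **fig2,
        ),
        # pole motion: +-5 deg rocking, sub-pixel pre-NEB jitter, 0.9 um
        # maximum post-NEB displacement
        "fig1b_displacement": SimulationParams(
            rocking_amplitude_deg=5.0,
            rocking_period_s=140.0,
            pre_neb_jitter_sd_um=0.15,
            post_neb_drift_max_um=0.9,
            enrichment_slope1_per_s=_ENRICH_SLOPE1,
            enrichment_slope2_per_s=_ENRICH_SLOPE2,
            phase_break_s=105.0,
            neb_time_s=105.0,
            peak_enrichment=0.2,
            cytoplasm_depletion_frac=0.1,
            noise_sd=5.0,
        ),
    }


def preset_names() -> list[str]:
    return sorted(_presets())


def builtin_preset(name: str) -> SimulationParams:
    """Return the fully populated parameter set for a named study condition."""
    presets = _presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(sorted(presets))}"
        )
    return presets[name]


# ---------------------------------------------------------------------------
# ground-truth I/O and ROI placement


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    """Write the per-pole per-frame ground-truth table as CSV."""
    path = Path(path)
    gt.pole_table.to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    """Read a ground-truth table written by :func:`write_ground_truth`."""
    return pd.read_csv(path)


def roi_table_from_ground_truth(
    gt: GroundTruth,
    mode: str = "static",
    poles: str = "a",
    first_visible_frame: int = 2,
    n_cytoplasm: int = 20,
    diameter_um: float = DEFAULT_ROI_DIAMETER_UM,
) -> pd.DataFrame:
    """ROI placement table (frame, roi_class, x_um, y_um, diameter_um) derived
    from ground truth, standing in for manual segmentation.

    mode "static": spindle ROIs are fixed at the pole positions of
    ``first_visible_frame`` for that frame onward (use
    :func:`spindlequant.roi_model.backfill_rois` to cover the earlier,
    pre-visible frames).  mode "tracked": spindle ROIs follow the true pole
    position on every frame.  Cytoplasm ROIs are always static.
    ``poles`` selects "a" (one ROI per nucleus) or "both".
    """
    if mode not in ("static", "tracked"):
        raise ValueError("mode must be 'static' or 'tracked'")
    pole_ids = ["a", "b"] if poles == "both" else [poles]
    p = gt.params
    n_frames = p.n_frames
    rows = []
    # cytoplasm rows first so per-frame id assignment gives every spindle ROI
    # the same id on every frame (cytoplasm ROIs exist on all frames; spindle
    # rows may start only at the first visible frame and then be backfilled)
    for f in range(n_frames):
        for cx, cy in gt.cytoplasm_centers_um[:n_cytoplasm]:
            rows.append((f, "cytoplasm", cx, cy, diameter_um))
    sub = gt.pole_table[gt.pole_table["pole"].isin(pole_ids)]
    if mode == "static":
        anchors = sub[sub["frame"] == first_visible_frame]
        for _, a in anchors.iterrows():
            for f in range(first_visible_frame, n_frames):
                rows.append((f, "spindle", a["x_um"], a["y_um"], diameter_um))
    else:
        for _, a in sub.iterrows():
            rows.append(
                (int(a["frame"]), "spindle", a["x_um"], a["y_um"], diameter_um)
            )
    return pd.DataFrame(
        rows, columns=["frame", "roi_class", "x_um", "y_um", "diameter_um"]
    )


def params_to_dict(p: SimulationParams) -> dict:
    """JSON/YAML-serializable echo of the parameters."""
    d = asdict(p)
    d["field_size_px"] = list(p.field_size_px)
    if math.isinf(d["peak_enrichment"]):
        d["peak_enrichment"] = "inf"
    return d


def params_from_dict(d: dict) -> SimulationParams:
    d = dict(d)
    d["field_size_px"] = tuple(d.get("field_size_px", (512, 512)))
    if d.get("peak_enrichment") in ("inf", None):
        d["peak_enrichment"] = math.inf
    return SimulationParams(**d)


def with_overrides(p: SimulationParams, **kwargs) -> SimulationParams:
    """Convenience wrapper around dataclasses.replace."""
    return replace(p, **kwargs)
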