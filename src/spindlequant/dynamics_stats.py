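"""Statistical layer: Welch tests, two-phase slope fits, spindle displacement
and rocking-angle quantification.

All t-tests are two-sided Welch (unequal-variances) tests with
Welch-Satterthwaite degrees of freedom.  Per-timepoint comparisons report raw
p-values, matching how per-timepoint significance is usually quoted for this
kind of fold-change series; a Benjamini-Hochberg adjustment is available but
off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import Track

__all__ = [
    "WelchResult",
    "PhaseSlopes",
    "DisplacementFit",
    "RockingSeries",
    "welch_t_test",
    "fit_phase_slopes",
    "displacement_analysis",
    "rocking_analysis",
    "timepoint_comparison",
    "benjamini_hochberg",
]


class WelchResult(NamedTuple):
    t_statistic: float
    p_value: float
    df: float


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-sided unequal-variances (Welch) t-test.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with Welch-Satterthwaite
    degrees of freedom.  Identical groups give t = 0, p = 1; swapping the
    arguments negates t and leaves p unchanged.  Two zero-variance groups
    leave the statistic undefined and raise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both groups have zero variance: Welch t is undefined")
    sa, sb = va / a.size, vb / b.size
    se = math.sqrt(sa + sb)
    t = (a.mean() - b.mean()) / se
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t_statistic=float(t), p_value=float(min(p, 1.0)), df=float(df))


@dataclass(frozen=True)
class PhaseSlopes:
    """Two independent OLS lines split at a fixed breakpoint.

    Phase 1 covers [0, t_break] (boundary point included), phase 2
    (t_break, t_end].  Slopes are in value units per second.
    """

    slope1: float
    slope2: float
    t_break_s: float
    intercept1: float
    intercept2: float
    r_squared1: float
    r_squared2: float


def fit_phase_slopes(
    time_s: Sequence[float], value: Sequence[float], t_break_s: float
) -> PhaseSlopes:
    """Fit independent OLS lines to the two kinetic phases of a series."""
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(value, dtype=float)
    if t.shape != v.shape:
        raise ValueError("time and value series must have the same length")
    in1 = t <= t_break_s
    in2 = ~in1
    if in1.sum() < 2 or in2.sum() < 2:
        raise ValueError(
            f"need >= 2 points on each side of t_break={t_break_s}: "
            f"got {int(in1.sum())} and {int(in2.sum())}"
        )
    f1 = _ols(t[in1], v[in1])
    f2 = _ols(t[in2], v[in2])
    return PhaseSlopes(
        slope1=f1[0],
        slope2=f2[0],
        t_break_s=float(t_break_s),
        intercept1=f1[1],
        intercept2=f2[1],
        r_squared1=f1[2],
        r_squared2=f2[2],
    )


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """slope, intercept, r^2, two-sided p of an OLS line (constant-y safe)."""
    if np.ptp(y) == 0.0:  # flat series: no trend, perfectly "explained"
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(t, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


@dataclass(frozen=True)
class DisplacementFit:
    """Linear model of pole displacement from its time-0 position.

    ``displacement_um[k]`` is the Euclidean distance of the pole centroid at
    frame k from its position at the track's first frame, so d(0) = 0.  The
    linear model is d ~ t (OLS); ``se_mean_step_um`` is the standard error of
    the mean between-frame step size, and ``max_displacement_um`` the largest
    d over the track.
    """

    displacement_um: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    se_mean_step_um: float
    max_displacement_um: float


def displacement_analysis(pole_track: Track) -> DisplacementFit:
    """Quantify pole movement relative to the track's time-0 position."""
    if len(pole_track) < 3:
        raise ValueError("displacement analysis needs a track of >= 3 frames")
    if pole_track.has_gaps():
        raise ValueError(f"track {pole_track.track_id} has frame gaps")
    xy = np.column_stack([pole_track.centroid_x_um, pole_track.centroid_y_um])
    d = np.linalg.norm(xy - xy[0], axis=1)
    slope, intercept, r2, p = _ols(pole_track.times_s.astype(float), d)
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    se = float(steps.std(ddof=1) / math.sqrt(steps.size)) if steps.size > 1 else 0.0
    return DisplacementFit(
        displacement_um=d,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        p_value=p,
        se_mean_step_um=se,
        max_displacement_um=float(d.max()),
    )


@dataclass(frozen=True)
class RockingSeries:
    """Signed tilt of the pole-pair axis relative to its time-0 orientation."""

    angle_deg: np.ndarray
    amplitude_deg: float


def rocking_analysis(pole_a_track: Track, pole_b_track: Track) -> RockingSeries:
    """Per-frame signed tilt of the axis p_b - p_a versus its T0 direction.

    Angles are in degrees, wrapped to (-180, 180]; the amplitude is the
    largest absolute tilt.  Coincident poles on any frame are an error.
    """
    if not np.array_equal(pole_a_track.frames, pole_b_track.frames):
        raise ValueError("pole tracks must cover the same frames")
    ax = np.column_stack(
        [pole_a_track.centroid_x_um, pole_a_track.centroid_y_um]
    )
    bx = np.column_stack(
        [pole_b_track.centroid_x_um, pole_b_track.centroid_y_um]
    )
    v = bx - ax
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        bad = pole_a_track.frames[norms == 0].tolist()
        raise ValueError(f"poles coincide at frames {bad}: axis undefined")
    v0 = v[0]
    cross = v0[0] * v[:, 1] - v0[1] * v[:, 0]
    dot = v @ v0
    angle = np.degrees(np.arctan2(cross, dot))
    return RockingSeries(angle_deg=angle, amplitude_deg=float(np.abs(angle).max()))


def timepoint_comparison(
    tracks_condition_a: Sequence[Track],
    tracks_condition_b: Sequence[Track],
    frame: int,
) -> pd.DataFrame:
    """Welch tests between two conditions at one timepoint.

    For every ROI class present in both conditions and for each fold-change
    statistic (mean and max intensity), compares the per-track fold values at
    ``frame``.  Tracks must already be T0-normalized.
    """
    rows = []
    classes = sorted(
        {t.roi_class for t in tracks_condition_a}
        & {t.roi_class for t in tracks_condition_b}
    )
    for roi_class in classes:
        for stat, attr in (("fold_mean", "fold_mean"), ("fold_max", "fold_max")):
            ga = _fold_at_frame(tracks_condition_a, roi_class, attr, frame)
            gb = _fold_at_frame(tracks_condition_b, roi_class, attr, frame)
            if len(ga) < 2 or len(gb) < 2:
                raise ValueError(
                    f"need >= 2 {roi_class} tracks per condition at frame {frame}"
                )
            res = welch_t_test(ga, gb)
            rows.append(
                {
                    "roi_class": roi_class,
                    "statistic": stat,
                    "frame": frame,
                    "n_a": len(ga),
                    "n_b": len(gb),
                    "mean_a": float(np.mean(ga)),
                    "mean_b": float(np.mean(gb)),
                    "t": res.t_statistic,
                    "df": res.df,
                    "p": res.p_value,
                }
            )
    return pd.DataFrame(rows)


def _fold_at_frame(
    tracks: Sequence[Track], roi_class: str, attr: str, frame: int
) -> list[float]:
    vals = []
    for t in tracks:
        if t.roi_class != roi_class:
            continue
        series = getattr(t, attr)
        if series is None:
            raise ValueError(f"track {t.track_id} is not T0-normalized")
        idx = np.nonzero(t.frames == frame)[0]
        if idx.size:
            vals.append(float(series[idx[0]]))
    return vals


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is the default
    reporting mode)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float))
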