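"""Circular measurement ROIs: placement files, retrospective backfill and
rasterization to label masks.

Spindle-pole ROIs are fixed 2 um-diameter circles placed at pole positions;
cytoplasm ROIs are circles of the same size placed away from nuclei.  Because
spindles only become morphologically visible a few frames into a movie, pole
ROIs can be "backfilled": copies of the first-visible-frame ROIs are placed
at the same centre on the preceding frames.  This is sound because pre-NEB
pole movement is small (standard error of the mean between-frame step under
0.3 um) relative to the 2 um ROI.

The "2 um circular ROI" is read as 2 um *diameter*; a 2 um radius disk would
span 4 um, wider than a pole region.  The diameter is configurable
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .imaging_io import BinaryMask

__all__ = [
    "Roi",
    "RoiSet",
    "SPINDLE",
    "CYTOPLASM",
    "DEFAULT_ROI_DIAMETER_UM",
    "load_roi_file",
    "roiset_from_frame_table",
    "backfill_rois",
    "rasterize",
    "disk_pixel_coords",
]

SPINDLE = "spindle"
CYTOPLASM = "cytoplasm"
_CLASSES = (SPINDLE, CYTOPLASM)

DEFAULT_ROI_DIAMETER_UM = 2.0

#: columns of the ROI placement file (diameter optional on disk)
ROI_FILE_COLUMNS = ["frame", "roi_class", "x_um", "y_um", "diameter_um"]


@dataclass(frozen=True)
class Roi:
    """One circular ROI on one frame.

    ``center_um`` is (x, y) in micrometres from the image origin (centre of
    pixel (0, 0)); ``roi_id`` is unique within its frame.
    """

    roi_id: int
    roi_class: str
    center_um: tuple[float, float]
    diameter_um: float
    frame: int

    def __post_init__(self) -> None:
        if self.roi_id < 1:
            raise ValueError("roi_id must be >= 1")
        if self.roi_class not in _CLASSES:
            raise ValueError(f"roi_class must be one of {_CLASSES}")
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be > 0")
        if self.frame < 0:
            raise ValueError("frame must be >= 0")


@dataclass
class RoiSet:
    """A collection of ROIs spanning frames, with the pixel scale they live on."""

    rois: list[Roi]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for frame in self.frames():
            ids = [r.roi_id for r in self.at_frame(frame)]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate roi_id within frame {frame}")

    def frames(self) -> list[int]:
        return sorted({r.frame for r in self.rois})

    def at_frame(self, frame: int) -> list[Roi]:
        return [r for r in self.rois if r.frame == frame]

    def counts(self, frame: int) -> dict[str, int]:
        """Per-class ROI counts on one frame."""
        rois = self.at_frame(frame)
        return {c: sum(r.roi_class == c for r in rois) for c in _CLASSES}

    def to_frame_table(self) -> pd.DataFrame:
        rows = [
            {
                "roi_id": r.roi_id,
                "frame": r.frame,
                "roi_class": r.roi_class,
                "x_um": r.center_um[0],
                "y_um": r.center_um[1],
                "diameter_um": r.diameter_um,
            }
            for r in self.rois
        ]
        return pd.DataFrame(rows)


def load_roi_file(
    path,
    pixel_size_um: float,
    image_shape_px: tuple[int, int] | None = None,
) -> RoiSet:
    """Load a declarative ROI placement file (CSV).

    Expected columns: ``frame, roi_class, x_um, y_um[, diameter_um]``; a
    missing diameter column defaults every ROI to 2 um.  ROI ids are assigned
    per frame in row order, starting at 1.  If ``image_shape_px`` (rows, cols)
    is given, rows whose centre falls outside the image are rejected with
    their (0-based) row numbers.
    """
    return roiset_from_frame_table(pd.read_csv(path), pixel_size_um, image_shape_px)


def roiset_from_frame_table(
    df: pd.DataFrame,
    pixel_size_um: float,
    image_shape_px: tuple[int, int] | None = None,
) -> RoiSet:
    """Build a validated :class:`RoiSet` from an in-memory placement table.

    Same schema and validation as :func:`load_roi_file`.
    """
    df = df.copy()
    required = {"frame", "roi_class", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI file is missing columns {sorted(missing)}")
    if "diameter_um" not in df.columns:
        df["diameter_um"] = DEFAULT_ROI_DIAMETER_UM
    df["diameter_um"] = df["diameter_um"].fillna(DEFAULT_ROI_DIAMETER_UM)

    bad_diam = df.index[df["diameter_um"] <= 0].tolist()
    if bad_diam:
        raise ValueError(f"non-positive diameter_um in rows {bad_diam}")
    bad_class = df.index[~df["roi_class"].isin(_CLASSES)].tolist()
    if bad_class:
        raise ValueError(f"unknown roi_class in rows {bad_class}")
    if image_shape_px is not None:
        ny, nx = image_shape_px
        x_max = (nx - 1) * pixel_size_um
        y_max = (ny - 1) * pixel_size_um
        oob = df.index[
            (df["x_um"] < 0) | (df["x_um"] > x_max)
            | (df["y_um"] < 0) | (df["y_um"] > y_max)
        ].tolist()
        if oob:
            raise ValueError(f"ROI centers outside the image in rows {oob}")

    rois: list[Roi] = []
    for frame, group in df.groupby("frame", sort=True):
        for k, (_, row) in enumerate(group.iterrows(), start=1):
            rois.append(
                Roi(
                    roi_id=k,
                    roi_class=str(row["roi_class"]),
                    center_um=(float(row["x_um"]), float(row["y_um"])),
                    diameter_um=float(row["diameter_um"]),
                    frame=int(frame),
                )
            )
    return RoiSet(rois=rois, pixel_size_um=pixel_size_um)


def backfill_rois(
    roiset: RoiSet, first_visible_frame: int, n_backfill_frames: int
) -> RoiSet:
    """Copy the spindle ROIs of ``first_visible_frame`` onto earlier frames.

    For each spindle ROI at the first morphologically visible frame, an
    identical-centre copy is created at each of the ``n_backfill_frames``
    preceding frames.  Cytoplasm ROIs and all existing ROIs are unchanged.
    """
    if n_backfill_frames < 0:
        raise ValueError("n_backfill_frames must be >= 0")
    if first_visible_frame - n_backfill_frames < 0:
        raise ValueError(
            f"backfilling {n_backfill_frames} frames from frame "
            f"{first_visible_frame} would extend before frame 0"
        )
    seeds = [
        r for r in roiset.at_frame(first_visible_frame) if r.roi_class == SPINDLE
    ]
    if not seeds:
        raise ValueError(f"no spindle ROIs at frame {first_visible_frame}")
    new = []
    for f in range(first_visible_frame - n_backfill_frames, first_visible_frame):
        taken = {r.roi_id for r in roiset.at_frame(f)}
        next_free = max(taken, default=0) + 1
        for r in sorted(seeds, key=lambda r: r.roi_id):
            # keep the seed's id when free; renumber on collision (ids only
            # need to be unique within a frame — tracking re-identifies ROIs
            # by centroid, not id)
            rid = r.roi_id
            if rid in taken:
                rid = next_free
                next_free += 1
            taken.add(rid)
            new.append(replace(r, frame=f, roi_id=rid))
    return RoiSet(rois=list(roiset.rois) + new, pixel_size_um=roiset.pixel_size_um)


def disk_pixel_coords(
    center_um: tuple[float, float],
    radius_um: float,
    image_shape_px: tuple[int, int],
    pixel_size_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of pixels whose centre lies strictly inside a disk.

    The inclusion rule is half-open (distance < radius), which keeps
    rasterized areas deterministic when a pixel centre falls exactly on the
    circle.  Only indices inside the image are returned.
    """
    ny, nx = image_shape_px
    cx, cy = center_um
    r_px = radius_um / pixel_size_um
    cx_px, cy_px = cx / pixel_size_um, cy / pixel_size_um
    r0 = max(int(np.floor(cy_px - r_px)) - 1, 0)
    r1 = min(int(np.ceil(cy_px + r_px)) + 2, ny)
    c0 = max(int(np.floor(cx_px - r_px)) - 1, 0)
    c1 = min(int(np.ceil(cx_px + r_px)) + 2, nx)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    dy2 = (rows * pixel_size_um - cy) ** 2
    dx2 = (cols * pixel_size_um - cx) ** 2
    inside = dy2[:, None] + dx2[None, :] < radius_um**2
    rr, cc = np.nonzero(inside)
    return rows[rr], cols[cc]


def rasterize(
    roiset: RoiSet, frame: int, image_shape: tuple[int, int]
) -> BinaryMask:
    """Rasterize one frame's ROIs into a label mask.

    A pixel gets label k iff its centre lies within ``diameter/2`` of ROI k's
    centre (Euclidean distance in physical units).  Where ROIs overlap, the
    lowest id wins pixel ownership.  An ROI contributing no pixels (fully
    outside the image) is an error.
    """
    labels = np.zeros(image_shape, dtype=np.int32)
    for roi in sorted(roiset.at_frame(frame), key=lambda r: r.roi_id):
        rr, cc = disk_pixel_coords(
            roi.center_um, roi.diameter_um / 2.0, image_shape, roiset.pixel_size_um
        )
        if rr.size == 0:
            raise ValueError(
                f"ROI {roi.roi_id} (frame {frame}) rasterizes to zero pixels "
                "inside the image"
            )
        free = labels[rr, cc] == 0
        labels[rr[free], cc[free]] = roi.roi_id
    return BinaryMask(labels=labels)
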