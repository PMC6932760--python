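"""Image-stack and label-mask I/O, plus maximum-intensity projection.

Movies are multi-frame, multi-channel fluorescence stacks stored as plain
multi-page 16-bit TIFF (frame-major, channel-interleaved pages) with a JSON
sidecar carrying the physical metadata (pixel size, frame interval, channel
names).  Label masks are stored as lossless 16-bit PNG so that ROI
identities survive a round trip; a lossy format would corrupt labels.

Coordinate convention: pixel indices are 0-based and physical (x, y)
positions are measured in micrometres from the centre of pixel (0, 0), i.e.
``x_um = column * pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "Movie",
    "BinaryMask",
    "MetadataError",
    "read_movie",
    "write_movie",
    "max_intensity_project",
    "read_mask",
    "write_mask",
]

MAX_UINT16 = 65535


class MetadataError(ValueError):
    """A movie file is missing required physical metadata."""


@dataclass
class Movie:
    """A (frame, channel, y, x) intensity stack with physical metadata.

    Attributes
    ----------
    data
        Nonnegative intensities, axis order (frame, channel, y, x).
    pixel_size_um
        Lateral pixel size in micrometres per pixel (isotropic).
    frame_interval_s
        Time between consecutive frames in seconds.
    channel_names
        One label per channel, e.g. ``["marker", "nuclei"]``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"movie data must be 4-D (frame, channel, y, x), got {self.data.ndim}-D"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all movie axes must have length >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match the channel axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in {self.channel_names}"
            ) from None


@dataclass
class BinaryMask:
    """A 2-D label image: 0 is background, label k > 0 identifies ROI k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integers")

    def label_ids(self) -> np.ndarray:
        """Sorted nonzero labels present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as a multi-page 16-bit TIFF plus a JSON metadata sidecar.

    Pages are frame-major and channel-interleaved, so the page count equals
    ``n_frames * n_channels``.  The round trip through :func:`read_movie` is
    bit-exact.  Values outside the 16-bit range (or non-integral values) are
    rejected rather than silently clipped.
    """
    path = Path(path)
    data = np.asarray(movie.data)
    if np.issubdtype(data.dtype, np.floating):
        if not np.array_equal(data, np.round(data)):
            raise ValueError("movie intensities must be integral for 16-bit storage")
    if data.min() < 0 or data.max() > MAX_UINT16:
        raise ValueError(
            f"movie intensities outside the 16-bit range [0, {MAX_UINT16}] "
            "cannot be stored losslessly"
        )
    pages = data.astype(np.uint16).reshape(-1, *movie.frame_shape)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
        "channel_names": list(movie.channel_names),
        "n_frames": movie.n_frames,
        "n_channels": movie.n_channels,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


_REQUIRED_META = ("pixel_size_um", "frame_interval_s", "n_channels")


def read_movie(path: str | Path) -> Movie:
    """Read a multi-page TIFF written by :func:`write_movie`.

    The JSON sidecar must provide ``pixel_size_um``, ``frame_interval_s`` and
    the channel layout; a missing sidecar or field raises
    :class:`MetadataError` naming what is absent.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(
            f"no metadata sidecar {sidecar.name}: pixel_size_um, "
            "frame_interval_s and channel layout are unknown"
        )
    meta = json.loads(sidecar.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise MetadataError(f"metadata sidecar is missing field {key!r}")
    pages = np.atleast_3d(pages)
    if pages.ndim == 2:  # single page
        pages = pages[None]
    n_channels = int(meta["n_channels"])
    if pages.shape[0] % n_channels:
        raise MetadataError(
            f"page count {pages.shape[0]} is not a multiple of "
            f"n_channels={n_channels}"
        )
    data = pages.reshape(-1, n_channels, *pages.shape[1:])
    return Movie(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        channel_names=list(meta.get("channel_names", [])),
    )


def max_intensity_project(zstack: np.ndarray) -> np.ndarray:
    """Collapse a (z, y, x) stack to (y, x) by the per-pixel maximum over z.

    Projection is over Z only; callers apply it per channel per frame, never
    over time.  A single slice projects to itself.
    """
    zstack = np.asarray(zstack)
    if zstack.ndim != 3:
        raise ValueError(f"expected a 3-D (z, y, x) stack, got {zstack.ndim}-D")
    if zstack.shape[0] < 1 or zstack.size == 0:
        raise ValueError("cannot project an empty stack")
    return zstack.max(axis=0)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a label mask as lossless 16-bit PNG."""
    path = Path(path)
    labels = mask.labels
    if labels.min() < 0 or labels.max() > MAX_UINT16:
        raise ValueError("mask labels must fit in uint16 for PNG storage")
    iio.imwrite(path, labels.astype(np.uint16), extension=".png")
    return path


def read_mask(path: str | Path) -> BinaryMask:
    """Read a label mask written by :func:`write_mask` (lossless round trip)."""
    labels = np.asarray(iio.imread(path))
    return BinaryMask(labels=labels.astype(np.int64))
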