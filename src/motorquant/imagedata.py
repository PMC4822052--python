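"""Domain types and I/O for image stacks, masks, trajectory tables and result tables.

Conventions
-----------
* Images are indexed ``(frame, channel, row, col)``; missing axes are singletons.
* Pixel coordinates are 0-based with origin at the top-left corner; the
  physical position of a pixel is ``x = col * pixel_size_nm``,
  ``y = row * pixel_size_nm``.
* Calibration (pixel size, frame interval) is always supplied by the caller,
  never read from TIFF tags: tag dialects vary between acquisition systems.
* Trajectory tables are stored in nanometres and seconds, never in
  pixels/frames, which decouples the analysis from the acquisition settings.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "BinaryMask",
    "Trajectory",
    "TrajectorySet",
    "read_image_stack",
    "write_image_stack",
    "read_trajectory_table",
    "write_trajectory_table",
    "write_table",
]


@dataclass
class ImageStack:
    """A calibrated fluorescence image stack.

    Parameters
    ----------
    data
        Non-negative intensities with axes ``(frame, channel, row, col)``.
    pixel_size_nm
        Length of one pixel edge in nanometres, > 0.
    frame_interval_s
        Seconds between consecutive frames; 0 for single images.
    channel_names
        Ordered channel labels, e.g. ``["golgi", "nucleus"]`` or
        ``["561", "488"]``.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float = 0.0
    channel_names: Sequence[str] = ("0",)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"ImageStack data must have 4 axes (frame, channel, row, col), "
                f"got {self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageStack intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("ImageStack intensities must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.frame_interval_s < 0:
            raise ValueError("frame_interval_s must be >= 0")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if self.n_frames > 1 and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0 for multi-frame stacks")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(frame, row, col)`` sub-stack for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[:, idx]

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(self.n_frames) * float(self.frame_interval_s)


@dataclass
class BinaryMask:
    """A boolean annotation of one image plane (nucleus, microtubule, zone...)."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("BinaryMask must be a 2-D boolean grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not self.values.any()


@dataclass
class Trajectory:
    """One tracked particle: time-ordered (t [s], x [nm], y [nm]) samples."""

    track_id: str
    samples: np.ndarray  # shape (n, 3): columns t_s, x_nm, y_nm

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (t, x, y)")
        if len(self.samples) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        t = self.samples[:, 0]
        if not np.all(np.diff(t) > 0):
            raise ValueError(
                f"track {self.track_id}: sample times must be strictly increasing"
            )

    @property
    def times(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:]

    @property
    def lifetime_s(self) -> float:
        return float(self.samples[-1, 0] - self.samples[0, 0])

    def start_to_end_nm(self) -> float:
        """Euclidean displacement from the first to the last sample."""
        return float(np.hypot(*(self.samples[-1, 1:] - self.samples[0, 1:])))

    def path_length_nm(self) -> float:
        """Sum of inter-sample step lengths (>= start_to_end_nm)."""
        steps = np.diff(self.samples[:, 1:], axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


@dataclass
class TrajectorySet:
    """All trajectories from one movie, with acquisition metadata."""

    trajectories: list[Trajectory]
    movie_duration_s: float
    pixel_size_nm: float
    field_id: str = ""

    def __post_init__(self) -> None:
        for tr in self.trajectories:
            t = tr.times
            if t[0] < 0 or t[-1] > self.movie_duration_s + 1e-9:
                raise ValueError(
                    f"track {tr.track_id}: samples outside [0, movie_duration_s]"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


# ---------------------------------------------------------------------------
# TIFF I/O


def read_image_stack(
    path: str | Path,
    pixel_size_nm: float,
    frame_interval_s: float = 0.0,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Axes are normalized to ``(frame, channel, row, col)``.  A stack of
    ``n`` pages declared as ``c`` channels is interpreted as ``n/c`` frames
    with channels interleaved fastest (frame-major page order).  Calibration
    is taken from the arguments only.
    """
    try:
        arr = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim > 4:
        raise ValueError(f"unsupported TIFF with {arr.ndim} axes")
    if arr.ndim >= 3 and arr.shape[-1] in (3, 4) and arr.dtype == np.uint8:
        raise ValueError("RGB(A) TIFFs are not supported; use grayscale planes")

    n_channels = len(channel_names) if channel_names else 1
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        n_pages = arr.shape[0]
        if n_pages % n_channels:
            raise ValueError(
                f"{n_pages} pages not divisible by {n_channels} channels"
            )
        arr = arr.reshape(n_pages // n_channels, n_channels, *arr.shape[1:])
    # ndim == 4: already (frame, channel, row, col)
    if channel_names is None:
        channel_names = [str(i) for i in range(arr.shape[1])]
    return ImageStack(
        data=arr.astype(float),
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
        channel_names=channel_names,
    )


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a multi-page float32 TIFF.

    Pages are ordered frame-major with channels interleaved, matching the
    convention :func:`read_image_stack` uses to rebuild the axes.
    """
    t, c, h, w = stack.shape
    pages = stack.data.reshape(t * c, h, w).astype(np.float32)
    tifffile.imwrite(str(path), pages, photometric="minisblack")


# ---------------------------------------------------------------------------
# Trajectory tables

_TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_nm", "y_nm"]


def read_trajectory_table(
    path: str | Path,
    movie_duration_s: float | None = None,
    pixel_size_nm: float = 1.0,
    field_id: str = "",
) -> TrajectorySet:
    """Read a tracking-output CSV into a :class:`TrajectorySet`.

    The table must have columns ``track_id, frame, t_s, x_nm, y_nm``.  Rows
    are grouped by ``track_id`` and sorted by time; tracks with fewer than
    two samples are dropped with a logged warning.  Duplicate times within a
    track are a validation error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns {missing}")
    trajectories: list[Trajectory] = []
    n_dropped = 0
    for track_id, group in df.groupby("track_id", sort=True):
        group = group.sort_values("t_s")
        if len(group) < 2:
            n_dropped += 1
            continue
        t = group["t_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"track {track_id}: duplicate or non-increasing times")
        samples = np.column_stack(
            [t, group["x_nm"].to_numpy(float), group["y_nm"].to_numpy(float)]
        )
        trajectories.append(Trajectory(track_id=str(track_id), samples=samples))
    if n_dropped:
        logger.warning("dropped %d track(s) with < 2 samples", n_dropped)
    if movie_duration_s is None:
        movie_duration_s = max((tr.times[-1] for tr in trajectories), default=0.0)
    return TrajectorySet(
        trajectories=trajectories,
        movie_duration_s=float(movie_duration_s),
        pixel_size_nm=float(pixel_size_nm),
        field_id=field_id,
    )


def write_trajectory_table(tset: TrajectorySet, path: str | Path) -> None:
    """Write a :class:`TrajectorySet` to CSV (full float precision)."""
    rows = []
    for tr in tset:
        for frame, (t, x, y) in enumerate(tr.samples):
            rows.append((tr.track_id, frame, t, x, y))
    df = pd.DataFrame(rows, columns=_TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def write_table(records: Sequence, path: str | Path, record_type: type | None = None) -> None:
    """Write a collection of result dataclasses to CSV.

    Column order follows the dataclass field order (all records must share a
    type).  Numeric values keep full precision, so write → read → write is
    byte-identical.  An empty collection writes a header-only file;
    ``record_type`` supplies the header when no records are present.
    """
    records = list(records)
    first = records[0] if records else record_type
    if first is None or not dataclasses.is_dataclass(first):
        raise TypeError(
            "write_table expects dataclass records (pass record_type= for an "
            "empty collection)"
        )
    columns = [f.name for f in dataclasses.fields(first)]
    if not records:
        Path(path).write_text(",".join(columns) + "\n")
        return
    rows = []
    for rec in records:
        row = {}
        for name in columns:
            value = getattr(rec, name)
            if isinstance(value, np.ndarray):
                value = ";".join(f"{v:.17g}" for v in np.ravel(value))
            row[name] = value
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.17g")
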