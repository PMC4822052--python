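"""Microtubule sliding quantification from photoconversion time-lapses.

A zone of microtubules is photoconverted and imaged at fixed intervals.
After bleach correction, microtubule pixels are detected by a global
threshold computed on the first frame, the initial photoconverted zone is
identified from that frame, and the motile fraction per frame is

    %MF[k] = 100 * (microtubule pixels outside the zone) / (all microtubule
             pixels)

The gross sliding rate of one cell is the slope (% per minute) of %MF vs
time over the initial linear section: among all windows anchored at frame 0
with at least ``min_points`` points, the one with the highest linear-fit R²
(ties broken toward the longer window).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import closing, convex_hull_image, disk, remove_small_objects

from .imagedata import BinaryMask, ImageStack

__all__ = ["SlidingSeries", "bleach_correct", "motile_fraction_series", "sliding_rate"]


@dataclass
class SlidingSeries:
    """Per-cell motile-fraction series plus (optionally) the fitted rate."""

    times_min: np.ndarray
    mf_pct: np.ndarray
    initial_zone: BinaryMask
    rate_pct_per_min: float = float("nan")
    window: tuple[int, int] = (0, 0)  # fitted segment [start, end) indices
    r2: float = float("nan")
    n_points: int = 0


def bleach_correct(movie: ImageStack) -> ImageStack:
    """Ratio-method photobleaching correction.

    Each frame is rescaled so its whole-frame mean intensity equals frame
    0's; spatial structure within a frame is untouched.
    """
    if movie.n_frames < 2:
        raise ValueError("bleach correction needs at least 2 frames")
    data = movie.data.astype(float).copy()
    ref = data[0].mean()
    for k in range(movie.n_frames):
        m = data[k].mean()
        if m <= 0:
            raise ValueError(f"frame {k} has non-positive mean intensity")
        data[k] *= ref / m
    return ImageStack(
        data, pixel_size_nm=movie.pixel_size_nm,
        frame_interval_s=movie.frame_interval_s,
        channel_names=movie.channel_names,
    )


def motile_fraction_series(
    movie: ImageStack,
    zone: BinaryMask | None = None,
    closing_radius_px: int = 3,
    min_object_px: int = 4,
) -> SlidingSeries:
    """Compute %MF per frame of a (bleach-corrected) single-channel movie.

    The microtubule threshold is an Otsu threshold computed on frame 0 and
    applied to every frame — recomputing per frame would conflate threshold
    drift with motility.  Thresholded components smaller than
    ``min_object_px`` are discarded as shot-noise specks, not microtubules.
    The initial photoconverted zone defaults to the morphological closing of
    the filled convex hull of the frame-0 mask, so %MF is 0 at frame 0 by
    construction; a user-supplied ``zone`` mask overrides it.
    """
    frames = movie.data[:, 0].astype(float)
    thr = threshold_otsu(frames[0])

    def mt_mask(frame: np.ndarray) -> np.ndarray:
        m = frame > thr
        if min_object_px > 1:
            m = remove_small_objects(m, max_size=min_object_px - 1, connectivity=2)
        return m

    mask0 = mt_mask(frames[0])
    if not mask0.any():
        raise ValueError("no microtubule pixels detected in frame 0")
    if zone is None:
        hull = convex_hull_image(mask0)
        zone = BinaryMask(closing(hull, disk(closing_radius_px)),
                          provenance="initial_zone")
    mf = np.zeros(movie.n_frames)
    for k in range(movie.n_frames):
        mask_k = mt_mask(frames[k])
        total = mask_k.sum()
        if total == 0:
            mf[k] = np.nan
            continue
        outside = (mask_k & ~zone.values).sum()
        mf[k] = 100.0 * outside / total
    times_min = movie.times_s() / 60.0
    return SlidingSeries(times_min=times_min, mf_pct=mf, initial_zone=zone)


def _fit_window(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and R² of y on t; zero-variance y gives (0, 0)."""
    if np.allclose(y, y[0]):
        return 0.0, 0.0
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return float(slope), 1.0 - ss_res / ss_tot


def sliding_rate(series: SlidingSeries, min_points: int = 4) -> SlidingSeries:
    """Fit the initial linear section of the %MF curve.

    Every candidate window starts at frame 0 and contains at least
    ``min_points`` points; the window with the highest R² wins, with ties
    (within 1e-12) resolved toward the longer window.  A flat series has no
    defined R² and reports slope 0 over the full series.
    """
    finite = np.isfinite(series.mf_pct)
    t = series.times_min[finite]
    y = series.mf_pct[finite]
    if len(y) < min_points:
        raise ValueError(f"need at least {min_points} finite points")
    best = None  # (r2, n, slope)
    for n in range(min_points, len(y) + 1):
        slope, r2 = _fit_window(t[:n], y[:n])
        if best is None or r2 > best[0] + 1e-12 or abs(r2 - best[0]) <= 1e-12:
            best = (r2, n, slope)
    r2, n, slope = best
    return replace(series, rate_pct_per_min=slope, window=(0, n), r2=r2, n_points=n)
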