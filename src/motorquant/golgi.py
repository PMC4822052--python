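"""Fixed-cell assays: the Golgi integrity statistic and the neurite tip ratio.

The Golgi dispersion readout scores, per cell, how tightly the Golgi staining
is packed around the nucleus.  Within a region of interest built from the
nucleus (segmented from the nucleus channel, then extended outward by a fixed
number of pixels), the statistic is

    integrity = SD_i / sqrt(mean)

where ``SD_i`` is the standard deviation of the Golgi-channel pixel
intensities in the region and ``mean`` their average.  Normalizing by the
square root of the mean makes the statistic insensitive to staining
efficiency and exposure time: for pure photon shot noise (Poisson light,
variance = mean) the statistic is 1 regardless of illumination, so values
well above 1 indicate spatial structure (a compact, bright perinuclear
Golgi), while dispersal of the signal across the cell drives the statistic
down toward the shot-noise floor.

The tip-accumulation readout for neurite-bearing cells is a plain ratio of
distal (tip) to proximal (shaft) mean fluorescence; ratios above 1 indicate
active motors walking to the microtubule plus-ends at the tip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .imagedata import BinaryMask

__all__ = [
    "GolgiMeasurement",
    "TipRatio",
    "nucleus_mask",
    "extend_mask",
    "golgi_integrity",
    "tip_accumulation_ratio",
    "golgi_dispersion",
]


@dataclass
class GolgiMeasurement:
    """Per-cell Golgi integrity (SD_i / sqrt(mean), dimensionless, >= 0)."""

    cell_id: str
    integrity: float
    region_area_px: int
    nucleus_area_px: int


@dataclass
class TipRatio:
    """Per-cell distal/proximal mean-fluorescence ratio (> 0)."""

    cell_id: str
    ratio: float


def nucleus_mask(nucleus_channel: np.ndarray, coarse_roi: BinaryMask) -> BinaryMask:
    """Segment the nucleus inside a coarse, user-drawn ROI.

    An Otsu threshold is computed over the ROI intensities; pixels above it
    are kept, the largest connected component is retained and its holes are
    filled.

    Raises
    ------
    ValueError
        If the ROI is empty, its intensities are constant (no bimodal
        threshold exists), or thresholding leaves nothing.
    """
    nucleus_channel = np.asarray(nucleus_channel, dtype=float)
    if coarse_roi.is_empty():
        raise ValueError("coarse ROI is empty")
    vals = nucleus_channel[coarse_roi.values]
    if np.ptp(vals) == 0:
        raise ValueError("constant intensities in ROI: threshold is degenerate")
    thr = threshold_otsu(vals)
    mask = (nucleus_channel > thr) & coarse_roi.values
    if not mask.any():
        raise ValueError("thresholding left no nucleus pixels")
    labels = label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return BinaryMask(mask, provenance="nucleus")


def extend_mask(mask: BinaryMask, distance_px: int) -> BinaryMask:
    """Dilate a mask with a Euclidean disc of radius ``distance_px``.

    Implemented through the exact Euclidean distance transform, so the
    result is every pixel within ``distance_px`` of the input mask; the
    output always contains the input and is monotone in the distance.
    """
    if mask.is_empty():
        raise ValueError("cannot extend an empty mask")
    if distance_px < 0:
        raise ValueError("distance_px must be >= 0")
    if distance_px == 0:
        return BinaryMask(mask.values.copy(), provenance=mask.provenance)
    dist = ndimage.distance_transform_edt(~mask.values)
    return BinaryMask(dist <= distance_px, provenance=f"{mask.provenance}+{distance_px}px")


def golgi_integrity(
    golgi_channel: np.ndarray,
    region: BinaryMask,
    cell_id: str = "",
    nucleus_area_px: int = 0,
    ddof: int = 0,
) -> GolgiMeasurement:
    """SD of Golgi intensities over ``region``, normalized by sqrt(mean).

    The population (divide-by-N) standard deviation is the default: the
    statistic describes one region, it does not estimate a sampling
    distribution.  ``ddof=1`` switches to the sample convention.
    """
    golgi_channel = np.asarray(golgi_channel, dtype=float)
    if region.is_empty():
        raise ValueError("measurement region is empty")
    vals = golgi_channel[region.values]
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("mean intensity over region must be > 0")
    integrity = float(vals.std(ddof=ddof)) / np.sqrt(mean)
    return GolgiMeasurement(
        cell_id=cell_id,
        integrity=integrity,
        region_area_px=region.count(),
        nucleus_area_px=nucleus_area_px,
    )


def golgi_dispersion(
    golgi_channel: np.ndarray,
    nucleus_channel: np.ndarray,
    coarse_roi: BinaryMask,
    extend_px: int = 10,
    region: str = "full",
    cell_id: str = "",
    ddof: int = 0,
) -> GolgiMeasurement:
    """Full per-cell pipeline: nucleus segmentation → 10-px extension →
    integrity statistic on the Golgi channel.

    ``region="full"`` measures over the whole dilated nuclear area (the
    default); ``region="ring"`` excludes the nucleus proper and measures the
    perinuclear ring only.
    """
    nuc = nucleus_mask(nucleus_channel, coarse_roi)
    extended = extend_mask(nuc, extend_px)
    if region == "ring":
        meas_region = BinaryMask(extended.values & ~nuc.values, provenance="ring")
    elif region == "full":
        meas_region = extended
    else:
        raise ValueError("region must be 'full' or 'ring'")
    return golgi_integrity(
        golgi_channel, meas_region, cell_id=cell_id,
        nucleus_area_px=nuc.count(), ddof=ddof,
    )


def tip_accumulation_ratio(
    img: np.ndarray,
    distal_roi: BinaryMask,
    proximal_roi: BinaryMask,
    cell_id: str = "",
    background: float = 0.0,
) -> TipRatio:
    """Distal (tip) over proximal (shaft) mean fluorescence.

    ``background`` is subtracted from both means before dividing; the
    default of 0 reports the plain ratio.
    """
    img = np.asarray(img, dtype=float)
    if distal_roi.is_empty() or proximal_roi.is_empty():
        raise ValueError("both ROIs must be non-empty")
    if np.any(distal_roi.values & proximal_roi.values):
        raise ValueError("distal and proximal ROIs must be disjoint")
    distal = float(img[distal_roi.values].mean()) - background
    proximal = float(img[proximal_roi.values].mean()) - background
    if proximal <= 0:
        raise ValueError("proximal mean must exceed background")
    return TipRatio(cell_id=cell_id, ratio=distal / proximal)
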