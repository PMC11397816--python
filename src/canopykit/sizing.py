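"""Fruit lineal dimensions from an instance mask plus aligned depth.

Mango fruit are not rotationally symmetric, so a partly occluded silhouette
cannot be extrapolated: occluded fruit must be detected and excluded before
sizing. The pipeline is (i) estimate the camera-to-fruit range from the
depth pixels under the mask, (ii) convert the mask's pixel extents to
millimetres through the pinhole model, (iii) fit an ellipse to the mask via
its second-order central moments and reject masks whose axis ratio or fill
fall outside the range expected for a whole fruit.

The range estimate is the median of valid depths under the mask after one
pass of median-absolute-deviation rejection (|d - median| <= 3 MAD): the
mask may leak onto background foliage several hundred millimetres behind
the fruit, and the median of the majority surface resists that leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import regionprops

from .annotation_io import InstanceMask
from .camera import CameraIntrinsics

#: Whole-fruit ellipse acceptance window. Non-field defaults: mango
#: length/width sits around 1.3-1.6, so a fitted major/minor ratio in
#: [1.1, 2.0] with mask/ellipse overlap of at least 0.85 is taken as
#: "unoccluded"; both are configuration-exposed.
DEFAULT_RATIO_RANGE = (1.1, 2.0)
DEFAULT_MIN_FILL = 0.85


@dataclass
class EllipseDiagnostics:
    major_px: float
    minor_px: float
    axis_ratio: float      # major/minor, >= 1
    fill_ratio: float      # overlap (Jaccard) of mask and fitted ellipse
    reason: str = ""       # non-empty iff the filter failed


@dataclass
class FruitSizeEstimate:
    """Lineal fruit dimensions (mm) with the occlusion-filter verdict."""

    instance_id: int
    length_mm: float       # vertical extent (long axis of a hanging fruit)
    width_mm: float        # horizontal extent
    distance_mm: float
    pixel_extent: tuple    # (height px, width px)
    ellipse: EllipseDiagnostics
    passed_filter: bool


@dataclass(frozen=True)
class SizingStats:
    """Accuracy summary of estimates vs ground truth (all mm)."""

    bias: float
    rmse: float
    rmse_bc: float         # bias-corrected: sqrt(rmse^2 - bias^2)
    n: int


def fruit_distance(mask: InstanceMask, depth_image) -> float:
    """Camera-to-fruit range (mm): MAD-filtered median depth under the mask."""
    depth = np.asarray(depth_image, dtype=float)
    if mask.pixels.shape != depth.shape:
        raise ValueError("mask and depth resolutions differ")
    values = depth[mask.pixels]
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("no valid depth under the mask")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    kept = values[np.abs(values - med) <= 3.0 * mad]
    return float(np.median(kept))


def fit_ellipse(mask: InstanceMask) -> EllipseDiagnostics:
    """Ellipse axes from second-order central moments of the mask.

    The fill ratio is the Jaccard overlap between the mask and the fitted
    ellipse rasterised at the mask centroid with the fitted orientation: a
    whole convex fruit scores near 1, while a chord-truncated silhouette
    (occluder edge) leaves part of the fitted ellipse uncovered and part of
    the mask outside it, pulling the overlap down. (A plain area quotient
    cannot see truncation: a moments-fitted ellipse nearly matches its own
    mask's area even for a half silhouette.)

    Degenerate (effectively one-dimensional) masks yield a diagnostic with
    ``reason`` set rather than raising.
    """
    props = regionprops(mask.pixels.astype(np.uint8))[0]
    major, minor = props.axis_major_length, props.axis_minor_length
    if minor <= 0:
        return EllipseDiagnostics(major_px=major, minor_px=0.0,
                                  axis_ratio=np.inf, fill_ratio=0.0,
                                  reason="degenerate mask (zero minor axis)")
    cy, cx = props.centroid
    ori = props.orientation  # angle of major axis from the row direction
    r0, c0, r1, c1 = props.bbox
    pad = int(np.ceil(major / 2)) + 2
    rows = np.arange(max(r0 - pad, 0), min(r1 + pad, mask.pixels.shape[0]))
    cols = np.arange(max(c0 - pad, 0), min(c1 + pad, mask.pixels.shape[1]))
    dy = rows[:, None] - cy
    dx = cols[None, :] - cx
    along = dy * np.cos(ori) - dx * np.sin(ori)
    across = dy * np.sin(ori) + dx * np.cos(ori)
    ellipse = (along / (major / 2)) ** 2 + (across / (minor / 2)) ** 2 <= 1.0
    window = mask.pixels[np.ix_(rows, cols)]
    union = np.logical_or(ellipse, window).sum()
    overlap = np.logical_and(ellipse, window).sum() / union if union else 0.0
    return EllipseDiagnostics(major_px=major, minor_px=minor,
                              axis_ratio=major / minor,
                              fill_ratio=float(overlap))


def ellipse_filter(mask: InstanceMask,
                   ratio_range: tuple = DEFAULT_RATIO_RANGE,
                   min_fill: float = DEFAULT_MIN_FILL):
    """Occlusion rejection: pass iff the fitted-ellipse axis ratio lies in
    the whole-fruit window and the mask fills the ellipse.

    Returns (passed, EllipseDiagnostics).
    """
    diag = fit_ellipse(mask)
    if diag.reason:
        return False, diag
    reasons = []
    if not (ratio_range[0] <= diag.axis_ratio <= ratio_range[1]):
        reasons.append(f"axis ratio {diag.axis_ratio:.2f} outside "
                       f"[{ratio_range[0]}, {ratio_range[1]}]")
    if diag.fill_ratio < min_fill:
        reasons.append(f"fill {diag.fill_ratio:.2f} < {min_fill}")
    diag.reason = "; ".join(reasons)
    return not reasons, diag


def size_from_mask(mask: InstanceMask, depth_image, K: CameraIntrinsics,
                   ratio_range: tuple = DEFAULT_RATIO_RANGE,
                   min_fill: float = DEFAULT_MIN_FILL) -> FruitSizeEstimate:
    """Estimate fruit length/width (mm) from mask extents and range.

    length = height_px * Z / fy and width = width_px * Z / fx with Z the
    MAD-filtered median mask depth; fx and fy are applied per axis.
    """
    Z = fruit_distance(mask, depth_image)
    rows, cols = np.nonzero(mask.pixels)
    height_px = int(rows.max() - rows.min() + 1)
    width_px = int(cols.max() - cols.min() + 1)
    passed, diag = ellipse_filter(mask, ratio_range, min_fill)
    return FruitSizeEstimate(
        instance_id=mask.instance_id,
        length_mm=height_px * Z / K.fy,
        width_mm=width_px * Z / K.fx,
        distance_mm=Z,
        pixel_extent=(height_px, width_px),
        ellipse=diag,
        passed_filter=passed)


def sizing_stats(estimates, truths) -> SizingStats:
    """Bias, RMSE and bias-corrected RMSE of estimate - truth errors (mm).

    The identity rmse^2 = bias^2 + rmse_bc^2 holds exactly on the same
    error vector.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("estimates and truths must be equal-length, non-empty")
    err = est - tru
    bias = float(err.mean())
    rmse = float(np.sqrt(np.mean(err ** 2)))
    rmse_bc = float(np.sqrt(np.mean((err - bias) ** 2)))
    return SizingStats(bias=bias, rmse=rmse, rmse_bc=rmse_bc, n=err.size)


def bias_corrected_rmse(bias: float, rmse: float) -> float:
    """RMSE-bc from summary values alone: sqrt(rmse^2 - bias^2)."""
    if rmse < abs(bias):
        raise ValueError("rmse must be >= |bias|")
    return float(np.sqrt(rmse ** 2 - bias ** 2))
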