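"""Stationary-tissue mask from the temporal variance of velocity.

Stationary tissue is identified pixelwise as the fraction (default 15%) of
eligible pixels with the lowest temporal variance of velocity over the
cardiac cycle.  Before thresholding, manually traced wraparound regions and
near-zero-variance (constant-filled) pixels are excluded.  To suppress
isolated noise pixels in air and at tissue:air boundaries, the initial
percentile is set above the target and the resulting mask is eroded by one
pixel, with the initial percentile tuned so the *final* mask holds the
target fraction of eligible pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datamodel import CorrectionConfig, InvariantError, PolygonROI, VelocityCineSeries
from .roi import rasterize_roi

__all__ = [
    "StationaryMask",
    "MaskTuningError",
    "temporal_variance_map",
    "eligible_map",
    "build_stationary_mask",
]

# 3x3 structuring element (8-connected); border treated as outside, so
# border pixels always erode away.
_STRUCT = np.ones((3, 3), dtype=bool)


class MaskTuningError(RuntimeError):
    """Percentile tuning could not reach the target mask fraction."""

    def __init__(self, message: str, best_fraction: float):
        super().__init__(message)
        self.best_fraction = best_fraction


@dataclass
class StationaryMask:
    """Result of the stationary-mask procedure.

    ``achieved_fraction`` counts final-mask pixels relative to the eligible
    set (after wraparound and near-zero-variance exclusions), which is also
    the base of the stationarity percentile.
    """

    pixels: np.ndarray
    eligible_count: int
    achieved_fraction: float
    initial_percentile_used: float

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


def temporal_variance_map(series: VelocityCineSeries) -> np.ndarray:
    """Per-pixel population variance of velocity across cardiac phases,
    in (cm/s)^2.

    Raises
    ------
    InvariantError
        If the series has fewer than 2 phases (variance undefined).
    """
    if series.n_phases < 2:
        raise InvariantError("temporal variance needs at least 2 cardiac phases")
    return np.var(series.velocity.astype(np.float64), axis=0, ddof=0)


def eligible_map(
    series: VelocityCineSeries,
    exclusions: list[PolygonROI],
    config: CorrectionConfig,
) -> np.ndarray:
    """Boolean map of pixels eligible for the stationary mask.

    A pixel is eligible iff it lies outside every wraparound-exclusion
    polygon and its temporal variance is at or above the exclusion
    threshold (constant-filled reconstruction pixels fall below it).
    """
    for roi in exclusions:
        if roi.label != "wraparound_exclusion":
            raise InvariantError(f"exclusion ROI has label {roi.label!r}")
    variance = temporal_variance_map(series)
    eligible = variance >= config.variance_exclusion_threshold
    for roi in exclusions:
        eligible &= ~rasterize_roi(roi, series.shape)
    return eligible


def _initial_mask(order: np.ndarray, eligible_count: int, percentile: float) -> np.ndarray:
    """Lowest-variance mask at ``percentile`` of the eligible pixels.

    ``order`` holds the flat indices of eligible pixels sorted by
    (variance, row-major index); the stable ordering makes percentile cuts
    deterministic under ties.
    """
    k = int(round(percentile * eligible_count))
    return order[:k]


def build_stationary_mask(
    series: VelocityCineSeries,
    exclusions: list[PolygonROI],
    config: CorrectionConfig,
) -> StationaryMask:
    """Build the stationary-tissue mask with the erode-and-retune procedure.

    The final mask is the 1-pixel erosion of an initial lowest-variance
    mask whose percentile is tuned by bisection over
    ``[p, min(3p, 0.9)]`` (at most 50 iterations) until the final mask
    fraction is within ``mask_fraction_tolerance`` of
    ``stationarity_percentile``.

    Raises
    ------
    MaskTuningError
        If no percentile in the search range achieves the target fraction;
        carries the best achieved fraction.
    InvariantError
        If the eligible set is empty.
    """
    eligible = eligible_map(series, exclusions, config)
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise InvariantError("eligible pixel set is empty")

    variance = temporal_variance_map(series)
    flat_eligible = np.flatnonzero(eligible.ravel())
    # stable ordering on (variance, row-major index): lexsort's last key is
    # primary and flat_eligible is already ascending, breaking ties
    order = flat_eligible[np.argsort(variance.ravel()[flat_eligible], kind="stable")]

    target = config.stationarity_percentile
    tol = config.mask_fraction_tolerance
    shape = series.shape

    def final_mask_at(p: float) -> tuple[np.ndarray, float]:
        initial = np.zeros(shape, dtype=bool)
        initial.ravel()[_initial_mask(order, n_eligible, p)] = True
        final = ndimage.binary_erosion(initial, structure=_STRUCT, border_value=0)
        return final, final.sum() / n_eligible

    lo, hi = target, min(3.0 * target, 0.9)
    best_mask, best_frac, best_p = None, -1.0, lo
    mask_lo, frac_lo = final_mask_at(lo)
    if abs(frac_lo - target) <= tol:
        best_mask, best_frac, best_p = mask_lo, frac_lo, lo
    else:
        mask_hi, frac_hi = final_mask_at(hi)
        if abs(frac_hi - target) <= tol:
            best_mask, best_frac, best_p = mask_hi, frac_hi, hi
        elif frac_lo > target or frac_hi < target:
            # target not bracketed by the search range
            best = (frac_lo, lo, mask_lo) if abs(frac_lo - target) < abs(frac_hi - target) else (
                frac_hi, hi, mask_hi)
            raise MaskTuningError(
                f"mask fraction target {target} not reachable in percentile range "
                f"[{lo}, {hi}]; best achieved fraction {best[0]:.4f}",
                best_fraction=float(best[0]),
            )
        else:
            best_frac, best_p, best_mask = frac_lo, lo, mask_lo
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                mask_mid, frac_mid = final_mask_at(mid)
                if abs(frac_mid - target) < abs(best_frac - target):
                    best_mask, best_frac, best_p = mask_mid, frac_mid, mid
                if abs(frac_mid - target) <= tol:
                    break
                if frac_mid < target:
                    lo = mid
                else:
                    hi = mid
            if abs(best_frac - target) > tol:
                raise MaskTuningError(
                    f"percentile bisection did not reach target {target} within "
                    f"tolerance {tol}; best achieved fraction {best_frac:.4f}",
                    best_fraction=float(best_frac),
                )

    return StationaryMask(
        pixels=best_mask,
        eligible_count=n_eligible,
        achieved_fraction=float(best_frac),
        initial_percentile_used=float(best_p),
    )
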