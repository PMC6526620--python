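"""Polygon-ROI rasterization.

A pixel belongs to a rasterized ROI iff its *center* lies inside the polygon,
with the polygon boundary counting as inside.  This pixel-center rule is the
simplest reproducible convention; no partial-volume weighting is applied at
vessel edges.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
from shapely.geometry import Polygon

from .datamodel import InvariantError, PolygonROI

__all__ = ["rasterize_roi", "roi_pixel_area_cm2"]


def rasterize_roi(roi: PolygonROI, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon ROI onto an image grid.

    Parameters
    ----------
    roi : PolygonROI
        Vertices in continuous (row, col) pixel coordinates; pixel centers
        sit at integer coordinates.
    shape : (rows, cols)
        Target image shape.

    Returns
    -------
    ndarray of bool, shape ``shape``
        True where the pixel center lies inside or on the polygon boundary.

    Raises
    ------
    InvariantError
        If the polygon is degenerate (zero area) or self-intersecting.
    """
    poly = Polygon(roi.vertices)
    if poly.area == 0.0:
        raise InvariantError("degenerate polygon: zero area")
    if not poly.is_valid:
        raise InvariantError("polygon must be simple (non-self-intersecting)")
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pts = shapely.points(rr.ravel().astype(float), cc.ravel().astype(float))
    # covers() is boundary-inclusive, unlike contains()
    inside = shapely.covers(poly, pts).reshape(rows, cols)
    if not inside.any():
        warnings.warn(
            f"ROI {roi.label!r} rasterizes to an empty mask (no pixel centers inside)",
            stacklevel=2,
        )
    return inside


def roi_pixel_area_cm2(
    mask: np.ndarray, pixel_spacing_row: float, pixel_spacing_col: float
) -> float:
    """Area of a rasterized ROI in cm^2 (pixel count x pixel area)."""
    return int(mask.sum()) * pixel_spacing_row * pixel_spacing_col / 100.0
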