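"""Core data types for 2D cine phase-contrast velocity series and ROIs.

All velocities are stored in cm/s with aliasing already resolved, so values
may legitimately exceed the encoding velocity (venc).  Geometry is expressed
in 0-based (row, col) pixel coordinates with row increasing downward; pixel
spacings are millimetres and areas are converted to cm^2 downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "VelocityCineSeries",
    "PolygonROI",
    "CorrectionConfig",
    "StudyRecord",
    "InvariantError",
    "FormatError",
]

ROI_LABELS = ("vessel", "thorax_wall", "wraparound_exclusion")


class InvariantError(ValueError):
    """A domain-type invariant is violated."""


class FormatError(ValueError):
    """A container file does not conform to the fixture schema."""


@dataclass
class VelocityCineSeries:
    """Paired magnitude/velocity image stacks over cardiac phases.

    Parameters
    ----------
    magnitude : ndarray, shape (n_phases, rows, cols)
        Magnitude images, arbitrary units.
    velocity : ndarray, shape (n_phases, rows, cols)
        Through-plane velocity maps in cm/s (aliasing resolved).
    pixel_spacing_row, pixel_spacing_col : float
        Pixel spacing in mm, strictly positive.
    venc : float
        Encoding velocity in cm/s; the velocity mapped to a phase of +/-pi.
    heart_rate : float
        Beats per minute; for phantom series the simulated-trigger rate.
    flow_sign : int
        +1 or -1: the through-plane direction in which vessel flow is
        counted positive.  A stored velocity of +v corresponds to
        ``flow_sign * v`` in the flow-positive convention.
    series_kind : {"in_vivo", "phantom"}
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    pixel_spacing_row: float
    pixel_spacing_col: float
    venc: float
    heart_rate: float
    flow_sign: int
    series_kind: Literal["in_vivo", "phantom"]

    def __post_init__(self) -> None:
        # preserve floating dtype (float32 fixtures stay float32, analysis
        # in float64 stays float64); promote anything else
        self.magnitude = np.asarray(self.magnitude)
        self.velocity = np.asarray(self.velocity)
        if not np.issubdtype(self.magnitude.dtype, np.floating):
            self.magnitude = self.magnitude.astype(np.float64)
        if not np.issubdtype(self.velocity.dtype, np.floating):
            self.velocity = self.velocity.astype(np.float64)
        if self.magnitude.ndim != 3 or self.velocity.ndim != 3:
            raise InvariantError("magnitude and velocity must be [phase, row, col] stacks")
        if self.magnitude.shape != self.velocity.shape:
            raise InvariantError(
                f"magnitude shape {self.magnitude.shape} != velocity shape {self.velocity.shape}"
            )
        if self.n_phases < 1:
            raise InvariantError("series needs at least one cardiac phase")
        for name in ("pixel_spacing_row", "pixel_spacing_col", "venc", "heart_rate"):
            if not (float(getattr(self, name)) > 0):
                raise InvariantError(f"{name} must be strictly positive")
        if self.flow_sign not in (1, -1):
            raise InvariantError("flow_sign must be +1 or -1")
        if self.series_kind not in ("in_vivo", "phantom"):
            raise InvariantError(f"unknown series_kind {self.series_kind!r}")

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of a single image."""
        return self.velocity.shape[1:]

    @property
    def pixel_area_cm2(self) -> float:
        """Area of one pixel in cm^2."""
        return self.pixel_spacing_row * self.pixel_spacing_col / 100.0

    @property
    def rr_interval_s(self) -> float:
        """R-R interval in seconds."""
        return 60.0 / self.heart_rate

    def with_velocity(self, velocity: np.ndarray) -> "VelocityCineSeries":
        """Copy of this series with a replaced velocity stack."""
        return replace(self, velocity=np.asarray(velocity))


@dataclass
class PolygonROI:
    """Labelled planar polygon in continuous (row, col) pixel coordinates.

    ``phase_index`` is the cardiac phase the ROI was drawn on, or "all" when
    a single contour is reused for every phase.
    """

    vertices: np.ndarray
    label: Literal["vessel", "thorax_wall", "wraparound_exclusion"]
    phase_index: int | Literal["all"] = "all"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise InvariantError("polygon needs >= 3 (row, col) vertices")
        if self.label not in ROI_LABELS:
            raise InvariantError(f"unknown ROI label {self.label!r}")


@dataclass
class CorrectionConfig:
    """Tunable parameters of the interpolation-based offset correction.

    stationarity_percentile
        Fraction of eligible pixels retained in the stationary-tissue mask
        (0.15 by default, following the original stationarity criterion;
        8-10% can be more reliable for oversized fields of view).
    variance_exclusion_threshold
        Pixels with temporal velocity variance below this are excluded as
        constant-filled reconstruction artefacts.  Stored on the variance
        scale; see the methods note on its units.
    fit_order
        Total degree (1-3) of the 2D polynomial offset surface.
    gate_threshold
        Agreement limit, cm/s, for the phantom accuracy check and the
        interpolation-order performance target.
    mask_fraction_tolerance
        Acceptable deviation of the achieved mask fraction from
        ``stationarity_percentile``.
    """

    stationarity_percentile: float = 0.15
    variance_exclusion_threshold: float = 1e-6
    fit_order: int = 1
    gate_threshold: float = 0.6
    mask_fraction_tolerance: float = 0.0025

    def __post_init__(self) -> None:
        if not (0.0 < self.stationarity_percentile < 1.0):
            raise InvariantError("stationarity_percentile must lie in (0, 1)")
        if self.fit_order not in (1, 2, 3):
            raise InvariantError("fit_order must be 1, 2 or 3")
        for name in ("variance_exclusion_threshold", "gate_threshold", "mask_fraction_tolerance"):
            if not (float(getattr(self, name)) > 0):
                raise InvariantError(f"{name} must be strictly positive")


@dataclass
class StudyRecord:
    """One flow acquisition: an in-vivo series, its paired stationary-phantom
    series acquired with identical protocol settings, and the analysis ROIs.

    Exactly one vessel ROI is required; a thorax-wall ROI is required for the
    phantom accuracy check; zero or more wraparound-exclusion ROIs mark
    phase-encode infolding to remove before mask construction.
    """

    in_vivo: VelocityCineSeries
    phantom: VelocityCineSeries
    rois: list[PolygonROI] = field(default_factory=list)
    system_id: str = ""
    vessel: Literal["aorta", "MPA"] = "aorta"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.in_vivo.shape != self.phantom.shape:
            raise InvariantError("in-vivo and phantom image shapes differ")
        if (
            self.in_vivo.pixel_spacing_row != self.phantom.pixel_spacing_row
            or self.in_vivo.pixel_spacing_col != self.phantom.pixel_spacing_col
        ):
            raise InvariantError("in-vivo and phantom pixel spacings differ")
        if self.vessel not in ("aorta", "MPA"):
            raise InvariantError(f"unknown vessel {self.vessel!r}")
        n_vessel = sum(1 for r in self.rois if r.label == "vessel")
        n_wall = sum(1 for r in self.rois if r.label == "thorax_wall")
        if n_vessel != 1:
            raise InvariantError(f"exactly one vessel ROI required, got {n_vessel}")
        if n_wall > 1:
            raise InvariantError("at most one thorax-wall ROI allowed")

    def roi(self, label: str) -> PolygonROI:
        """Return the unique ROI with ``label`` or raise KeyError."""
        matches = [r for r in self.rois if r.label == label]
        if not matches:
            raise KeyError(f"no ROI labelled {label!r}")
        return matches[0]

    @property
    def wraparound_exclusions(self) -> list[PolygonROI]:
        return [r for r in self.rois if r.label == "wraparound_exclusion"]
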