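"""Vessel flow quantification and phantom-referenced offset assessment.

Volume flow through the vessel cross-section is ROI mean velocity (cm/s)
times ROI area (cm^2), i.e. ml/s, integrated over the retro-gated cardiac
cycle by the rectangle rule with uniform phase duration RR / n_phases.
Cardiac output is stroke volume times heart rate.

Offset sign convention: all reported offsets are multiplied by the series
``flow_sign`` so that a positive offset always corresponds to an
*overestimation* of cardiac output, regardless of the stored through-plane
direction.

The pre-correction offset at the vessel is the phantom reference itself,

    v_pre  = v_phantom                                   (phantom ROI mean,
                                                          all phases)
and the residual after interpolation-based correction is

    v_post = v_ib - v_phantom                            (fitted field ROI
                                                          mean minus phantom)

with the vessel ROI drawn at the first cardiac phase after the R-wave
(end-diastole) and copied onto the fitted offset field and the phantom
images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .datamodel import InvariantError, PolygonROI, StudyRecord, VelocityCineSeries
from .roi import rasterize_roi
from .surface import OffsetSurface, evaluate_surface

__all__ = [
    "FlowResult",
    "VesselOffsetAssessment",
    "roi_mean_velocity",
    "volume_flow",
    "assess_vessel_offsets",
    "cardiac_output_error",
    "qp_qs",
]


@dataclass
class FlowResult:
    """Per-phase and cycle-integrated flow quantities for one vessel ROI."""

    per_phase_mean_velocity: np.ndarray  # cm/s, flow-positive convention
    roi_area: np.ndarray  # cm^2 per phase
    per_phase_flow: np.ndarray  # ml/s
    phase_duration: float  # s
    heart_rate: float  # beats/min
    stroke_volume: float  # ml/beat
    cardiac_output: float  # l/min

    @property
    def mean_roi_area(self) -> float:
        return float(np.mean(self.roi_area))


@dataclass
class VesselOffsetAssessment:
    """Pre-/post-correction velocity offsets at the vessel and the errors
    they induce in cardiac output.

    All velocities are signed in the flow-positive convention (positive =>
    cardiac-output overestimation).
    """

    v_ib: float  # interpolation-estimated offset, vessel ROI mean, cm/s
    v_phantom: float  # phantom offset, vessel ROI mean over all phases, cm/s
    v_pre: float  # pre-correction offset (= v_phantom), cm/s
    v_post: float  # residual offset after correction (v_ib - v_phantom), cm/s
    co_error_pre: float  # % of uncorrected cardiac output
    co_error_post: float  # %


def roi_mean_velocity(
    series: VelocityCineSeries,
    roi: PolygonROI,
    phase: int | Literal["time-averaged"] = "time-averaged",
) -> float:
    """Arithmetic mean of stored velocity over the rasterized ROI, cm/s.

    ``phase`` selects one cardiac phase, or "time-averaged" for the mean
    over all ROI pixels and phases.
    """
    pixels = rasterize_roi(roi, series.shape)
    if not pixels.any():
        raise InvariantError(f"ROI {roi.label!r} rasterizes to an empty mask")
    if phase == "time-averaged":
        return float(series.velocity.astype(np.float64)[:, pixels].mean())
    return float(series.velocity[int(phase)].astype(np.float64)[pixels].mean())


def volume_flow(series: VelocityCineSeries, vessel_roi: PolygonROI) -> FlowResult:
    """Time-integrated vessel volume flow over the cardiac cycle.

    The vessel ROI is copied to every velocity image (vessel motion over
    the cycle is neglected); per-phase flow is
    ``flow_sign * mean_velocity * area`` in ml/s and the stroke volume is
    its rectangle-rule integral over the R-R interval.
    """
    pixels = rasterize_roi(vessel_roi, series.shape)
    if not pixels.any():
        raise InvariantError("vessel ROI rasterizes to an empty mask")
    area = pixels.sum() * series.pixel_area_cm2
    mean_v = series.flow_sign * series.velocity.astype(np.float64)[:, pixels].mean(axis=1)
    per_phase_flow = mean_v * area  # cm/s * cm^2 = ml/s
    phase_duration = series.rr_interval_s / series.n_phases
    stroke_volume = float(per_phase_flow.sum() * phase_duration)
    cardiac_output = stroke_volume * series.heart_rate / 1000.0
    return FlowResult(
        per_phase_mean_velocity=mean_v,
        roi_area=np.full(series.n_phases, area),
        per_phase_flow=per_phase_flow,
        phase_duration=phase_duration,
        heart_rate=series.heart_rate,
        stroke_volume=stroke_volume,
        cardiac_output=float(cardiac_output),
    )


def cardiac_output_error(offset: float, flow: FlowResult) -> float:
    """Relative error (%) in cardiac output caused by a velocity offset.

    A constant offset of ``offset`` cm/s (flow-positive convention) over
    the vessel ROI adds ``offset * area * RR`` ml to every beat; the error
    is that volume as a percentage of the stroke volume.  The denominator
    is the uncorrected (site's initial) measurement.
    """
    if flow.stroke_volume == 0:
        raise InvariantError("stroke volume is zero; relative CO error undefined")
    rr = 60.0 / flow.heart_rate
    extra_ml_per_beat = offset * flow.mean_roi_area * rr
    return 100.0 * extra_ml_per_beat / flow.stroke_volume


def assess_vessel_offsets(
    study: StudyRecord,
    surface: OffsetSurface,
    end_diastolic_phase: int = 0,
) -> VesselOffsetAssessment:
    """Phantom-referenced offset assessment at the vessel ROI.

    The end-diastolic vessel ROI (first phase after the R-wave) is copied
    onto the fitted offset field (giving ``v_ib``) and onto the phantom
    images averaged over all simulated phases (giving ``v_phantom``).
    Both are signed with ``flow_sign`` so positive means cardiac-output
    overestimation.

    Raises
    ------
    InvariantError
        If the phantom series is missing (assessment is phantom-referenced)
        or the vessel ROI is absent.
    """
    if study.phantom is None:
        raise InvariantError("offset assessment requires the paired phantom series")
    vessel_roi = study.roi("vessel")
    sign = study.in_vivo.flow_sign

    pixels = rasterize_roi(vessel_roi, study.in_vivo.shape)
    if not pixels.any():
        raise InvariantError("vessel ROI rasterizes to an empty mask")
    field = evaluate_surface(surface, study.in_vivo.shape)
    v_ib = sign * float(field[pixels].mean())
    v_phantom = sign * roi_mean_velocity(study.phantom, vessel_roi, "time-averaged")

    v_pre = v_phantom
    v_post = v_ib - v_phantom

    flow = volume_flow(study.in_vivo, vessel_roi)
    return VesselOffsetAssessment(
        v_ib=v_ib,
        v_phantom=v_phantom,
        v_pre=v_pre,
        v_post=v_post,
        co_error_pre=cardiac_output_error(v_pre, flow),
        co_error_post=cardiac_output_error(v_post, flow),
    )


def qp_qs(mpa: FlowResult, aorta: FlowResult) -> float:
    """Pulmonic-to-systemic flow ratio Qp/Qs (≈ 1 in shunt-free subjects)."""
    if aorta.cardiac_output <= 0:
        raise InvariantError("aortic cardiac output must be positive for Qp/Qs")
    return mpa.cardiac_output / aorta.cardiac_output
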