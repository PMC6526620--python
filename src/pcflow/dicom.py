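"""DICOM adapter: map a scanner cine phase-contrast export into a
:class:`~pcflow.datamodel.VelocityCineSeries`.

The directory is expected to hold exactly one magnitude and one
phase/velocity cine series (distinguished by the DICOM ImageType M/P flag).
Phase images are converted once at import via

    velocity = venc * phase_radians / pi

where ``phase_radians`` comes from the rescale slope/intercept, assumed to
map stored values onto [-pi, pi] unless explicit scaling parameters are
given.  Velocity, not raw phase, is the canonical stored quantity from this
point on.  No vendor private tags are interpreted.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pydicom

from .datamodel import FormatError, VelocityCineSeries

__all__ = ["import_dicom_series"]


def _is_phase(ds: pydicom.Dataset) -> bool:
    image_type = [str(v).upper() for v in getattr(ds, "ImageType", [])]
    if "P" in image_type or any("PHASE" in v or "VELOCITY" in v for v in image_type):
        return True
    if "M" in image_type or any("MAG" in v for v in image_type):
        return False
    raise FormatError(
        f"cannot classify instance {getattr(ds, 'SOPInstanceUID', '?')} as "
        "magnitude or phase from its ImageType"
    )


def _rescaled(ds: pydicom.Dataset) -> np.ndarray:
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def import_dicom_series(
    directory: str | Path,
    venc: float,
    flow_sign: int,
    heart_rate: float | None = None,
    phase_scale: float | None = None,
    series_kind: str = "in_vivo",
) -> VelocityCineSeries:
    """Read a magnitude+phase cine pair from ``directory``.

    Parameters
    ----------
    venc : float
        Encoding velocity in cm/s; a rescaled phase of +pi maps to +venc.
    flow_sign : int
        Direction (+1/-1) in which vessel flow is counted positive.
    heart_rate : float, optional
        Beats/min.  Derived from the DICOM HeartRate tag when omitted.
    phase_scale : float, optional
        Extra factor applied to rescaled phase values to obtain radians,
        for exports whose rescale does not already yield radians.  Required
        (an error instructs so) when rescaled values exceed pi and do not
        look like cm/s either.

    Returns
    -------
    VelocityCineSeries sorted by trigger time.
    """
    directory = Path(directory)
    datasets = [pydicom.dcmread(p) for p in sorted(directory.iterdir()) if p.is_file()]
    if not datasets:
        raise FormatError(f"no DICOM instances found in {directory}")

    geometries = {
        (ds.Rows, ds.Columns, tuple(float(x) for x in ds.PixelSpacing)) for ds in datasets
    }
    if len(geometries) != 1:
        raise FormatError(f"mixed image geometries in {directory}: {sorted(geometries)}")

    mag = sorted(
        (ds for ds in datasets if not _is_phase(ds)),
        key=lambda ds: float(getattr(ds, "TriggerTime", 0.0)),
    )
    pha = sorted(
        (ds for ds in datasets if _is_phase(ds)),
        key=lambda ds: float(getattr(ds, "TriggerTime", 0.0)),
    )
    if not mag or not pha or len(mag) != len(pha):
        raise FormatError(
            f"expected paired magnitude and phase cine series, got "
            f"{len(mag)} magnitude and {len(pha)} phase instances"
        )

    magnitude = np.stack([ds.pixel_array.astype(np.float64) for ds in mag])
    phase = np.stack([_rescaled(ds) for ds in pha])
    if phase_scale is not None:
        phase = phase * phase_scale
    else:
        peak = float(np.abs(phase).max())
        if peak > math.pi * 1.0001:
            raise FormatError(
                f"rescaled phase values reach {peak:.3g}, outside [-pi, pi]; "
                "pass phase_scale (radians per stored unit) explicitly"
            )
    velocity = venc * phase / math.pi

    ds0 = pha[0]
    spacing = [float(x) for x in ds0.PixelSpacing]
    if heart_rate is None:
        hr = getattr(ds0, "HeartRate", None)
        if hr is None:
            raise FormatError("heart rate not in DICOM headers; pass heart_rate explicitly")
        heart_rate = float(hr)

    return VelocityCineSeries(
        magnitude=magnitude,
        velocity=velocity,
        pixel_spacing_row=spacing[0],
        pixel_spacing_col=spacing[1],
        venc=venc,
        heart_rate=heart_rate,
        flow_sign=flow_sign,
        series_kind=series_kind,
    )
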