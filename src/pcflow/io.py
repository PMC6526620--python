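"""Fixture-file reading and writing.

The fixture format is a single ``.npz`` archive (a zip of NumPy arrays)
holding the four float32 image stacks plus one JSON metadata entry.  It is
the test and interchange surface of the package; scanner DICOM exports enter
through :mod:`pcflow.dicom` instead.

Archive members::

    in_vivo_magnitude, in_vivo_velocity,
    phantom_magnitude, phantom_velocity   float32 [phase, row, col]
    meta.json                             JSON (see below)

The metadata block carries pixel spacings, venc, the two heart rates,
flow_sign, system/vessel/subject labels and the ROI vertex lists under their
labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datamodel import FormatError, PolygonROI, StudyRecord, VelocityCineSeries

__all__ = ["read_fixture", "write_fixture"]

_ARRAY_KEYS = (
    "in_vivo_magnitude",
    "in_vivo_velocity",
    "phantom_magnitude",
    "phantom_velocity",
)
_META_FIELDS = (
    "pixel_spacing_row",
    "pixel_spacing_col",
    "venc",
    "in_vivo_heart_rate",
    "phantom_heart_rate",
    "flow_sign",
    "system_id",
    "vessel",
    "subject_id",
    "rois",
)


def write_fixture(study: StudyRecord, path: str | Path) -> Path:
    """Write a StudyRecord to a fixture archive; returns the path written."""
    path = Path(path)
    meta = {
        "pixel_spacing_row": study.in_vivo.pixel_spacing_row,
        "pixel_spacing_col": study.in_vivo.pixel_spacing_col,
        "venc": study.in_vivo.venc,
        "in_vivo_heart_rate": study.in_vivo.heart_rate,
        "phantom_heart_rate": study.phantom.heart_rate,
        "flow_sign": study.in_vivo.flow_sign,
        "system_id": study.system_id,
        "vessel": study.vessel,
        "subject_id": study.subject_id,
        "rois": [
            {
                "label": r.label,
                "phase_index": r.phase_index,
                "vertices": np.asarray(r.vertices, dtype=float).tolist(),
            }
            for r in study.rois
        ],
    }
    np.savez(
        path,
        in_vivo_magnitude=study.in_vivo.magnitude.astype(np.float32),
        in_vivo_velocity=study.in_vivo.velocity.astype(np.float32),
        phantom_magnitude=study.phantom.magnitude.astype(np.float32),
        phantom_velocity=study.phantom.velocity.astype(np.float32),
        **{"meta.json": np.array(json.dumps(meta))},
    )
    # np.savez appends .npz when the name lacks it
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def read_fixture(path: str | Path) -> StudyRecord:
    """Read a fixture archive written by :func:`write_fixture`.

    Raises
    ------
    FormatError
        If an array member or metadata field is missing.
    InvariantError
        If the contained series violate a type invariant (e.g. shape
        mismatch between in-vivo and phantom members).
    """
    path = Path(path)
    with np.load(path, allow_pickle=False) as archive:
        for key in _ARRAY_KEYS:
            if key not in archive:
                raise FormatError(f"fixture {path} is missing array {key!r}")
        if "meta.json" not in archive:
            raise FormatError(f"fixture {path} is missing the 'meta.json' metadata block")
        arrays = {key: archive[key] for key in _ARRAY_KEYS}
        meta = json.loads(str(archive["meta.json"]))

    for fieldname in _META_FIELDS:
        if fieldname not in meta:
            raise FormatError(f"fixture {path} metadata is missing field {fieldname!r}")

    common = dict(
        pixel_spacing_row=meta["pixel_spacing_row"],
        pixel_spacing_col=meta["pixel_spacing_col"],
        venc=meta["venc"],
        flow_sign=int(meta["flow_sign"]),
    )
    in_vivo = VelocityCineSeries(
        magnitude=arrays["in_vivo_magnitude"],
        velocity=arrays["in_vivo_velocity"],
        heart_rate=meta["in_vivo_heart_rate"],
        series_kind="in_vivo",
        **common,
    )
    phantom = VelocityCineSeries(
        magnitude=arrays["phantom_magnitude"],
        velocity=arrays["phantom_velocity"],
        heart_rate=meta["phantom_heart_rate"],
        series_kind="phantom",
        **common,
    )
    rois = [
        PolygonROI(
            vertices=np.asarray(r["vertices"], dtype=float),
            label=r["label"],
            phase_index=r["phase_index"],
        )
        for r in meta["rois"]
    ]
    return StudyRecord(
        in_vivo=in_vivo,
        phantom=phantom,
        rois=rois,
        system_id=meta["system_id"],
        vessel=meta["vessel"],
        subject_id=meta["subject_id"],
    )
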