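import numpy as np
import pytest

from pcflow.datamodel import PolygonROI, VelocityCineSeries
from pcflow.synth import SyntheticStudyConfig, compact_config, generate_study


@pytest.fixture(scope="session")
def compact_study():
    """One 64x64/10-phase study with default noise and a planted tilt."""
    cfg = compact_config(
        seed=42, offset_order=1, offset_coefficients=(0.6, 0.9, -0.4)
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """One full-size (128x128, 30-phase) study with default noise."""
    cfg = SyntheticStudyConfig(
        seed=7, offset_order=1, offset_coefficients=(-0.3, 0.5, 0.2)
    )
    return generate_study(cfg)


def constant_series(value, shape=(4, 20, 20), heart_rate=60.0, flow_sign=1,
                    kind="in_vivo", spacing=1.5):
    """Float64 series with a spatially/temporally constant velocity."""
    vel = np.full(shape, float(value))
    return VelocityCineSeries(
        magnitude=np.ones(shape),
        velocity=vel,
        pixel_spacing_row=spacing,
        pixel_spacing_col=spacing,
        venc=150.0,
        heart_rate=heart_rate,
        flow_sign=flow_sign,
        series_kind=kind,
    )


def square_roi(label, r0, c0, r1, c1, phase_index="all"):
    return PolygonROI(
        [(r0, c0), (r0, c1), (r1, c1), (r1, c0)], label, phase_index=phase_index
    )
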