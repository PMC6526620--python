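"""Synthetic paired in-vivo/phantom cine phase-contrast studies.

Each synthetic study emulates a transaxial 2D flow acquisition through the
thorax: anterior and posterior stationary-tissue bands, a central air/lung
region, and a circular vessel with pulsatile through-plane flow.  A planted
polynomial velocity-offset field (order <= 3, in the same normalized
coordinates the fitting module uses) is added to *all* velocities, region-
dependent noise is drawn on top, and a paired stationary "phantom" series
shares the acquisition geometry: inside the phantom footprint its velocity
is the offset field (plus optional instability and tissue-level noise),
outside it is air-like noise.  The phantom footprint covers the vessel and
part of the anterior thorax wall, but not the posterior band — mirroring a
practical phantom smaller than an adult thorax.

What the generator emulates, and what it does not: planted offsets are
ideal smooth polynomial fields (no eddy-current physics, ghosting or
respiratory motion is simulated), noise is independent Gaussian per pixel
and phase (uniform for air, whose phase is noise-dominated), and tissue
noise SD varies smoothly with distance from the band centre so that the
temporal-variance ordering has the spatial structure real coil-sensitivity
and tissue heterogeneity produce.

All randomness flows from ``config.seed``; a fixed seed gives bit-identical
studies and cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import InvariantError, PolygonROI, StudyRecord, VelocityCineSeries
from .roi import rasterize_roi
from .surface import OffsetSurface, evaluate_surface, monomial_exponents

__all__ = [
    "VesselWaveform",
    "ThoraxLayout",
    "NoiseConfig",
    "SyntheticStudyConfig",
    "SystemProfile",
    "GroundTruth",
    "circle_polygon",
    "planted_surface",
    "generate_study",
    "generate_cohort",
    "predict_post_offset_sd",
]

# region label codes in GroundTruth.region_labels
AIR, TISSUE, VESSEL, WRAPAROUND, CONSTANT_FILL = 0, 1, 2, 3, 4


@dataclass
class VesselWaveform:
    """Per-phase mean-velocity profile of the vessel, cm/s.

    A rectified-sinusoid systolic pulse over the first ``systole_fraction``
    of the R-R interval followed by a small constant diastolic tail:

        v(t) = peak * sin(pi * t / Ts)   0 <= t < Ts
        v(t) = diastolic                 Ts <= t < RR

    chosen so the stroke volume has the closed form
    ``area * (peak * 2 Ts / pi + diastolic * (RR - Ts))``.
    """

    peak: float = 45.0  # cm/s (ROI-mean systolic peak, not centerline)
    systole_fraction: float = 0.40
    diastolic: float = 2.0  # cm/s

    def sample(self, n_phases: int, rr_s: float) -> np.ndarray:
        """Waveform at phase midpoints t_k = (k + 1/2) RR / n."""
        t = (np.arange(n_phases) + 0.5) * rr_s / n_phases
        ts = self.systole_fraction * rr_s
        v = np.where(t < ts, self.peak * np.sin(np.pi * t / ts), self.diastolic)
        return v

    def stroke_volume_per_cm2(self, rr_s: float) -> float:
        """Closed-form time integral of v(t) over one beat, cm (ml per cm^2)."""
        ts = self.systole_fraction * rr_s
        return self.peak * 2.0 * ts / math.pi + self.diastolic * (rr_s - ts)

    def with_stroke_volume(self, sv_ml: float, area_cm2: float, rr_s: float) -> "VesselWaveform":
        """Copy whose peak yields stroke volume ``sv_ml`` through ``area_cm2``."""
        ts = self.systole_fraction * rr_s
        peak = (sv_ml / area_cm2 - self.diastolic * (rr_s - ts)) / (2.0 * ts / math.pi)
        return replace(self, peak=peak)


@dataclass
class ThoraxLayout:
    """Row extents (inclusive start, exclusive end) of the stationary
    bands, the vessel position, and the phantom footprint, in pixels/cm."""

    anterior_rows: tuple[int, int] = (8, 30)
    posterior_rows: tuple[int, int] = (98, 120)
    vessel_center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    vessel_radius_cm: float = 1.5
    flow_sign: int = 1
    # phantom covers vessel + anterior wall, not the posterior band
    phantom_rows: tuple[int, int] = (4, 90)
    phantom_cols: tuple[int, int] = (12, 116)


@dataclass
class NoiseConfig:
    """Per-region velocity noise, cm/s.

    Tissue and vessel noise is zero-mean Gaussian per pixel and phase; air
    noise is uniform (noise-dominated phase) with SD ``air`` defaulting to
    venc/3.  Tissue SD varies smoothly with distance d in [0, 1] from the
    band centre as ``tissue * (1 + tissue_gradient * d)``.
    """

    tissue: float = 0.3
    vessel: float = 1.0
    air: float | None = None  # None -> venc / 3
    tissue_gradient: float = 1.0

    def air_sd(self, venc: float) -> float:
        return self.air if self.air is not None else venc / 3.0


@dataclass
class SyntheticStudyConfig:
    grid: tuple[int, int] = (128, 128)
    pixel_spacing: float = 1.5  # mm, isotropic
    n_phases: int = 30
    heart_rate: float = 60.0  # beats/min
    venc: float = 150.0  # cm/s
    # planted offset field: monomial coefficients in normalized [-1,1]^2
    # coordinates, ordered as pcflow.surface.monomial_exponents(order)
    offset_order: int = 1
    offset_coefficients: tuple[float, ...] = (0.0, 0.0, 0.0)
    layout: ThoraxLayout = field(default_factory=ThoraxLayout)
    waveform: VesselWaveform = field(default_factory=VesselWaveform)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    phantom_instability: float = 0.0  # cm/s added uniformly to the phantom field
    phantom_heart_rate: float | None = None  # None -> in-vivo rate
    wraparound_vertices: tuple | None = None  # optional contaminated polygon
    wraparound_noise_sd: float = 8.0  # cm/s extra noise inside it
    constant_border: int = 2  # zero-filled border width (reconstruction fill-in)
    vessel_label: str = "aorta"
    subject_id: str = ""
    system_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        n_coef = (self.offset_order + 1) * (self.offset_order + 2) // 2
        if len(self.offset_coefficients) != n_coef:
            raise InvariantError(
                f"offset order {self.offset_order} needs {n_coef} coefficients"
            )


@dataclass
class GroundTruth:
    """Everything the generator knows that a scanner never reveals."""

    offset_field: np.ndarray  # cm/s, the planted in-vivo field
    clean_velocity: np.ndarray  # [phase, row, col], cm/s, no offset, no noise
    region_labels: np.ndarray  # int map of AIR/TISSUE/VESSEL/WRAPAROUND/CONSTANT_FILL
    true_stroke_volume: float  # ml/beat, closed form
    true_cardiac_output: float  # l/min
    vessel_offset: float  # planted field mean over the vessel ROI, stored units
    phantom_instability: float  # cm/s
    config: SyntheticStudyConfig


def circle_polygon(
    center: tuple[float, float], radius_px: float, n_vertices: int = 64
) -> np.ndarray:
    """Regular polygon approximating a circle, (row, col) vertices."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [center[0] + radius_px * np.sin(theta), center[1] + radius_px * np.cos(theta)]
    )


def planted_surface(config: SyntheticStudyConfig) -> OffsetSurface:
    """The planted offset field as an OffsetSurface on the study grid."""
    return OffsetSurface(
        order=config.offset_order,
        coefficients=np.asarray(config.offset_coefficients, dtype=float),
        shape=config.grid,
        mask_residual_rms=0.0,
    )


def _tissue_sd_map(config: SyntheticStudyConfig, labels: np.ndarray) -> np.ndarray:
    """Per-pixel noise SD map for the in-vivo series (cm/s)."""
    rows = np.arange(config.grid[0], dtype=float)[:, None]
    sd = np.full(config.grid, config.noise.air_sd(config.venc))
    for start, end in (config.layout.anterior_rows, config.layout.posterior_rows):
        center, halfwidth = (start + end - 1) / 2.0, max((end - start) / 2.0, 1.0)
        d = np.abs(rows - center) / halfwidth
        band_sd = config.noise.tissue * (1.0 + config.noise.tissue_gradient * d)
        band = (labels == TISSUE) & (np.arange(config.grid[0])[:, None] >= start) & (
            np.arange(config.grid[0])[:, None] < end
        )
        sd = np.where(band, band_sd, sd)
    sd = np.where(labels == VESSEL, config.noise.vessel, sd)
    return sd


def _region_labels(config: SyntheticStudyConfig, vessel_mask: np.ndarray) -> np.ndarray:
    labels = np.full(config.grid, AIR, dtype=np.int8)
    for start, end in (config.layout.anterior_rows, config.layout.posterior_rows):
        labels[start:end, :] = TISSUE
    labels[vessel_mask] = VESSEL
    if config.wraparound_vertices is not None:
        wrap = rasterize_roi(
            PolygonROI(np.asarray(config.wraparound_vertices), "wraparound_exclusion"),
            config.grid,
        )
        labels[wrap] = WRAPAROUND
    b = config.constant_border
    if b > 0:
        border = np.zeros(config.grid, dtype=bool)
        border[:b, :] = border[-b:, :] = True
        border[:, :b] = border[:, -b:] = True
        labels[border] = CONSTANT_FILL
    return labels


def _draw_noise(
    rng: np.random.Generator,
    labels: np.ndarray,
    sd_map: np.ndarray,
    n_phases: int,
    air_sd: float,
    extra_wrap_sd: float,
) -> np.ndarray:
    """Region-dependent velocity noise stack: Gaussian in tissue/vessel,
    uniform (noise-dominated phase) in air, zero on constant fill."""
    shape = (n_phases,) + labels.shape
    noise = rng.standard_normal(shape) * sd_map[None, :, :]
    air_like = (labels == AIR) | (labels == WRAPAROUND)
    half_width = air_sd * math.sqrt(3.0)  # uniform on [-w, w] has SD w/sqrt(3)
    noise[:, air_like] = rng.uniform(-half_width, half_width, (n_phases, int(air_like.sum())))
    if extra_wrap_sd > 0 and (labels == WRAPAROUND).any():
        wrap = labels == WRAPAROUND
        noise[:, wrap] += rng.standard_normal((n_phases, int(wrap.sum()))) * extra_wrap_sd
    noise[:, labels == CONSTANT_FILL] = 0.0
    return noise


def generate_study(config: SyntheticStudyConfig) -> tuple[StudyRecord, GroundTruth]:
    """Generate one paired in-vivo/phantom study with known ground truth.

    The in-vivo velocity is ``clean + planted offset field + noise``; the
    phantom velocity inside its footprint is ``offset field + instability +
    tissue-level noise`` (no flow), air-like noise outside.  Image stacks
    are stored float32, matching the fixture format; ground truth is kept
    in float64.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid
    layout = config.layout
    radius_px = layout.vessel_radius_cm * 10.0 / config.pixel_spacing

    vessel_poly = circle_polygon(layout.vessel_center, radius_px)
    vessel_roi = PolygonROI(vessel_poly, "vessel", phase_index=0)
    vessel_mask = rasterize_roi(vessel_roi, config.grid)
    for start, end in (layout.anterior_rows, layout.posterior_rows):
        if vessel_mask[start:end, :].any():
            raise InvariantError("vessel overlaps a stationary band")

    labels = _region_labels(config, vessel_mask)
    offset_field = evaluate_surface(planted_surface(config), config.grid)

    # clean in-vivo velocity: vessel waveform inside the vessel, 0 elsewhere
    rr = 60.0 / config.heart_rate
    waveform = config.waveform.sample(config.n_phases, rr)
    clean = np.zeros((config.n_phases, rows, cols))
    clean[:, vessel_mask] = layout.flow_sign * waveform[:, None]

    sd_map = _tissue_sd_map(config, labels)
    air_sd = config.noise.air_sd(config.venc)
    noise = _draw_noise(
        rng, labels, sd_map, config.n_phases, air_sd, config.wraparound_noise_sd
    )
    velocity = clean + offset_field[None, :, :] + noise
    velocity[:, labels == CONSTANT_FILL] = 0.0

    magnitude = np.full((config.n_phases, rows, cols), 5.0)
    magnitude[:, labels == TISSUE] = 100.0
    magnitude[:, labels == VESSEL] = 150.0
    magnitude[:, labels == CONSTANT_FILL] = 0.0
    magnitude += rng.standard_normal(magnitude.shape)

    # phantom: shared geometry, no flow; offset field (+ instability) and
    # tissue-level noise inside the footprint, air-like noise outside
    phantom_hr = config.phantom_heart_rate or config.heart_rate
    footprint = np.zeros(config.grid, dtype=bool)
    footprint[layout.phantom_rows[0] : layout.phantom_rows[1],
              layout.phantom_cols[0] : layout.phantom_cols[1]] = True
    p_labels = np.where(footprint, TISSUE, AIR).astype(np.int8)
    p_sd = np.where(footprint, config.noise.tissue, air_sd)
    p_noise = _draw_noise(rng, p_labels, p_sd, config.n_phases, air_sd, 0.0)
    p_velocity = np.where(
        footprint[None, :, :],
        offset_field[None, :, :] + config.phantom_instability,
        0.0,
    ) + p_noise
    p_magnitude = np.where(footprint[None, :, :], 100.0, 5.0) + rng.standard_normal(
        (config.n_phases, rows, cols)
    )

    common = dict(
        pixel_spacing_row=config.pixel_spacing,
        pixel_spacing_col=config.pixel_spacing,
        venc=config.venc,
        flow_sign=layout.flow_sign,
    )
    in_vivo = VelocityCineSeries(
        magnitude=magnitude.astype(np.float32),
        velocity=velocity.astype(np.float32),
        heart_rate=config.heart_rate,
        series_kind="in_vivo",
        **common,
    )
    phantom = VelocityCineSeries(
        magnitude=p_magnitude.astype(np.float32),
        velocity=p_velocity.astype(np.float32),
        heart_rate=phantom_hr,
        series_kind="phantom",
        **common,
    )

    # auto-placed ROIs: vessel circle; thorax-wall rectangle inside the
    # anterior band and the phantom footprint; wraparound polygon if set
    a0, a1 = layout.anterior_rows
    inset = max(1, min(3, (a1 - a0 - 2) // 2))
    wall_r0, wall_r1 = a0 + inset, a1 - inset
    wall_c0, wall_c1 = cols // 2 - 12, cols // 2 + 12
    wall_roi = PolygonROI(
        [(wall_r0, wall_c0), (wall_r0, wall_c1), (wall_r1, wall_c1), (wall_r1, wall_c0)],
        "thorax_wall",
    )
    rois = [vessel_roi, wall_roi]
    if config.wraparound_vertices is not None:
        rois.append(
            PolygonROI(np.asarray(config.wraparound_vertices), "wraparound_exclusion")
        )

    area_cm2 = int(vessel_mask.sum()) * (config.pixel_spacing**2) / 100.0
    sv = area_cm2 * config.waveform.stroke_volume_per_cm2(rr)
    truth = GroundTruth(
        offset_field=offset_field,
        clean_velocity=clean,
        region_labels=labels,
        true_stroke_volume=sv,
        true_cardiac_output=sv * config.heart_rate / 1000.0,
        vessel_offset=float(offset_field[vessel_mask].mean()),
        phantom_instability=config.phantom_instability,
        config=config,
    )
    study = StudyRecord(
        in_vivo=in_vivo,
        phantom=phantom,
        rois=rois,
        system_id=config.system_id,
        vessel=config.vessel_label,
        subject_id=config.subject_id,
    )
    return study, truth


def compact_config(**overrides) -> SyntheticStudyConfig:
    """A 64x64, 10-phase study configuration with the thorax layout scaled
    to match.  Used for Monte-Carlo exercises that run the full pipeline
    many times; the package default (128x128, 30 phases) remains the
    reference acquisition geometry."""
    layout = ThoraxLayout(
        anterior_rows=(4, 15),
        posterior_rows=(49, 60),
        vessel_center=(32.0, 32.0),
        vessel_radius_cm=0.75,
        phantom_rows=(2, 45),
        phantom_cols=(6, 58),
    )
    defaults = dict(grid=(64, 64), n_phases=10, layout=layout)
    defaults.update(overrides)
    return SyntheticStudyConfig(**defaults)


@dataclass
class SystemProfile:
    """Offset-field statistics of one simulated CMR system.

    ``vessel_offset_sd`` is the SD (cm/s) of the planted field averaged
    over the vessel ROI across studies — the quantity the phantom reference
    measures pre-correction.  ``field_order`` is the spatial order of the
    planted fields (a pure order-2 profile emulates a system needing
    second-order correction).  With probability ``instability_rate`` the
    phantom field is shifted by a uniform draw from
    ``+/-[instability_min, instability_max]`` cm/s, emulating thermal
    drift between the in-vivo and phantom acquisitions.
    """

    system_id: str = "system-1"
    vessel_offset_sd: float = 1.5  # cm/s
    tilt_sd: float = 0.8  # cm/s per normalized unit, order-1 terms
    curvature_sd: float = 0.0  # cm/s, order-2 terms (0 for linear systems)
    field_order: int = 1
    instability_rate: float = 0.0
    instability_min: float = 1.0  # cm/s, only drawn when unstable
    instability_max: float = 2.0


def _draw_offset_coefficients(
    rng: np.random.Generator,
    profile: SystemProfile,
    base: SyntheticStudyConfig,
) -> tuple[int, tuple[float, ...]]:
    """Random planted-field coefficients whose vessel-ROI mean is a
    Normal(0, vessel_offset_sd^2) draw."""
    order = profile.field_order
    n_coef = (order + 1) * (order + 2) // 2
    coef = np.zeros(n_coef)
    # order-1 tilt terms
    coef[1:3] = rng.normal(0.0, profile.tilt_sd, 2)
    if order >= 2:
        coef[3:6] = rng.normal(0.0, profile.curvature_sd, 3)
    if order >= 3:
        coef[6:10] = rng.normal(0.0, profile.curvature_sd / 2.0, 4)
    # set the intercept so the field mean over the vessel ROI hits the draw
    target = rng.normal(0.0, profile.vessel_offset_sd)
    probe = replace(base, offset_order=order, offset_coefficients=tuple(coef))
    field_no_intercept = evaluate_surface(planted_surface(probe), base.grid)
    vessel_mask = rasterize_roi(
        PolygonROI(
            circle_polygon(
                base.layout.vessel_center,
                base.layout.vessel_radius_cm * 10.0 / base.pixel_spacing,
            ),
            "vessel",
        ),
        base.grid,
    )
    coef[0] = target - float(field_no_intercept[vessel_mask].mean())
    return order, tuple(coef)


def generate_cohort(
    n_studies: int,
    system_profiles: list[SystemProfile],
    seed: int,
    base_config: SyntheticStudyConfig | None = None,
) -> list[tuple[StudyRecord, GroundTruth]]:
    """Generate ``n_studies`` per system profile, alternating aorta/MPA.

    Aorta and MPA studies use distinct waveforms (the MPA pulse is broader
    and lower-peaked); per-study stroke volumes are drawn Normal(80, 10^2)
    ml.  Reproducible for a fixed ``seed``.
    """
    base = base_config or SyntheticStudyConfig()
    rng = np.random.default_rng(seed)
    out: list[tuple[StudyRecord, GroundTruth]] = []
    rr = 60.0 / base.heart_rate
    vessel_mask_count = int(
        rasterize_roi(
            PolygonROI(
                circle_polygon(
                    base.layout.vessel_center,
                    base.layout.vessel_radius_cm * 10.0 / base.pixel_spacing,
                ),
                "vessel",
            ),
            base.grid,
        ).sum()
    )
    area_cm2 = vessel_mask_count * (base.pixel_spacing**2) / 100.0

    for profile in system_profiles:
        for k in range(n_studies):
            vessel = "aorta" if k % 2 == 0 else "MPA"
            order, coef = _draw_offset_coefficients(rng, profile, base)
            sv = rng.normal(80.0, 10.0)
            shape = (
                VesselWaveform(systole_fraction=0.40, diastolic=2.0)
                if vessel == "aorta"
                else VesselWaveform(systole_fraction=0.48, diastolic=1.0)
            )
            waveform = shape.with_stroke_volume(sv, area_cm2, rr)
            unstable = rng.random() < profile.instability_rate
            instability = 0.0
            if unstable:
                instability = rng.choice([-1.0, 1.0]) * rng.uniform(
                    profile.instability_min, profile.instability_max
                )
            config = replace(
                base,
                offset_order=order,
                offset_coefficients=coef,
                waveform=waveform,
                phantom_instability=instability,
                vessel_label=vessel,
                subject_id=f"{profile.system_id}-subj{k:03d}",
                system_id=profile.system_id,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append(generate_study(config))
    return out


def predict_post_offset_sd(
    config: SyntheticStudyConfig,
    mask_pixels: np.ndarray,
    vessel_pixels: np.ndarray,
    fit_order: int = 1,
) -> float:
    """Noise-floor prediction of the post-correction residual SD, cm/s.

    With the planted field inside the fitted model space, the residual
    v_post = v_ib - v_phantom is purely noise-driven:

    * Var(v_ib) = a^T (X^T X)^-1 X^T S X (X^T X)^-1 a, with X the design on
      the mask pixels, S the diagonal of per-pixel time-averaged noise
      variances (sd^2 / n_phases), and a the ROI-averaged design row;
    * Var(v_phantom) = tissue_sd^2 / (n_roi * n_phases).

    The two noise sources are independent, so the SDs add in quadrature.
    """
    from .surface import _design_matrix, _normalized_coords  # shared basis

    labels = _region_labels(config, vessel_pixels)
    sd_map = _tissue_sd_map(config, labels)
    rows, cols = np.nonzero(mask_pixels)
    x, y = _normalized_coords(config.grid, rows, cols)
    design = _design_matrix(fit_order, x, y)
    s = (sd_map[rows, cols] ** 2) / config.n_phases
    xtx_inv = np.linalg.inv(design.T @ design)
    cov = xtx_inv @ (design.T * s) @ design @ xtx_inv
    r, c = np.nonzero(vessel_pixels)
    xr, yr = _normalized_coords(config.grid, r, c)
    a = _design_matrix(fit_order, xr, yr).mean(axis=0)
    var_ib = float(a @ cov @ a)
    var_phantom = config.noise.tissue**2 / (int(vessel_pixels.sum()) * config.n_phases)
    return math.sqrt(var_ib + var_phantom)
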