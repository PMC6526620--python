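"""2D polynomial offset-surface fitting and subtraction.

The background velocity offset is estimated by an unweighted least-squares
fit of a total-degree-1..3 polynomial surface to the *time-averaged*
velocity at the stationary-mask pixels, then the evaluated surface is
subtracted from every cardiac phase.  The field is static over the cycle
(retrospective gating); per-phase offset models are out of scope.

Pixel coordinates are affinely normalized to (x, y) in [-1, 1]^2 over the
full field of view before building monomials, for numerical conditioning;
the evaluated field is independent of this parameterization.  Monomials
x^i * y^j with i + j <= order are ordered by total degree, then by i, with
x the normalized column and y the normalized row coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import InvariantError, VelocityCineSeries
from .mask import StationaryMask

__all__ = [
    "OffsetSurface",
    "DegenerateFitError",
    "monomial_exponents",
    "time_averaged_velocity",
    "fit_offset_surface",
    "evaluate_surface",
    "correct_series",
]

_COND_LIMIT = 1e8


class DegenerateFitError(ValueError):
    """The design matrix is rank-deficient or too ill-conditioned to fit."""


def monomial_exponents(order: int) -> list[tuple[int, int]]:
    """(i, j) exponent pairs of x^i * y^j with i+j <= order, ordered by
    total degree then by i: [(0,0), (0,1), (1,0), (0,2), (1,1), (2,0), ...]."""
    return [(i, d - i) for d in range(order + 1) for i in range(d + 1)]


@dataclass
class OffsetSurface:
    """A fitted polynomial offset field.

    coefficients are in cm/s per unit monomial of the *normalized*
    coordinates; ``shape`` records the (rows, cols) grid the normalization
    maps onto [-1, 1]^2, with the FOV center at (0, 0).
    """

    order: int
    coefficients: np.ndarray
    shape: tuple[int, int]
    mask_residual_rms: float

    def __post_init__(self) -> None:
        n_expected = (self.order + 1) * (self.order + 2) // 2
        if len(self.coefficients) != n_expected:
            raise InvariantError(
                f"order {self.order} needs {n_expected} coefficients, "
                f"got {len(self.coefficients)}"
            )

    @property
    def intercept(self) -> float:
        """Surface value at the FOV center."""
        return float(self.coefficients[0])


def _normalized_coords(shape: tuple[int, int], rows: np.ndarray, cols: np.ndarray):
    """Map pixel (row, col) onto (x, y) in [-1, 1]^2 over the full grid."""
    n_rows, n_cols = shape
    y = 2.0 * rows / (n_rows - 1) - 1.0 if n_rows > 1 else np.zeros_like(rows, dtype=float)
    x = 2.0 * cols / (n_cols - 1) - 1.0 if n_cols > 1 else np.zeros_like(cols, dtype=float)
    return x, y


def _design_matrix(order: int, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x**i * y**j for i, j in monomial_exponents(order)])


def time_averaged_velocity(series: VelocityCineSeries) -> np.ndarray:
    """Per-pixel arithmetic mean of velocity over all cardiac phases, cm/s."""
    return np.mean(series.velocity.astype(np.float64), axis=0)


def fit_offset_surface(
    avg_velocity: np.ndarray,
    mask: StationaryMask | np.ndarray,
    order: int,
) -> OffsetSurface:
    """Least-squares polynomial fit of the time-averaged velocity on the
    stationary mask.

    Parameters
    ----------
    avg_velocity : 2D map, cm/s
    mask : StationaryMask or boolean map
        Pixels entering the fit, all with equal weight.
    order : int
        Total polynomial degree, 1-3.

    Raises
    ------
    DegenerateFitError
        If the mask holds fewer than 3x the coefficient count, or the
        design condition number exceeds 1e8 (e.g. all mask pixels on one
        line for order >= 1).
    """
    if order not in (1, 2, 3):
        raise InvariantError("fit order must be 1, 2 or 3")
    pixels = mask.pixels if isinstance(mask, StationaryMask) else np.asarray(mask, dtype=bool)
    if pixels.shape != avg_velocity.shape:
        raise InvariantError("mask and velocity map shapes differ")
    rows, cols = np.nonzero(pixels)
    n_coef = (order + 1) * (order + 2) // 2
    if len(rows) < 3 * n_coef:
        raise DegenerateFitError(
            f"mask holds {len(rows)} pixels; order {order} needs at least {3 * n_coef}"
        )
    x, y = _normalized_coords(avg_velocity.shape, rows, cols)
    design = _design_matrix(order, x, y)
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        # report which monomial directions have (near-)zero spread
        spreads = design.std(axis=0)
        weak = [
            f"x^{i}y^{j}"
            for (i, j), s in zip(monomial_exponents(order)[1:], spreads[1:])
            if s < 1e-12
        ]
        raise DegenerateFitError(
            f"degenerate design for order {order} (condition {cond:.3g}); "
            f"deficient directions: {', '.join(weak) or 'near-collinear monomials'}"
        )
    values = avg_velocity[rows, cols].astype(np.float64)
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    residual = values - design @ coef
    rms = float(np.sqrt(np.mean(residual**2)))
    return OffsetSurface(
        order=order,
        coefficients=coef,
        shape=avg_velocity.shape,
        mask_residual_rms=rms,
    )


def evaluate_surface(surface: OffsetSurface, shape: tuple[int, int]) -> np.ndarray:
    """Evaluate the fitted offset field on the full pixel grid, cm/s.

    ``shape`` must match the grid the surface was fitted on (the
    normalization is tied to it).
    """
    if tuple(shape) != tuple(surface.shape):
        raise InvariantError(
            f"shape {tuple(shape)} does not match the surface grid {tuple(surface.shape)}"
        )
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    x, y = _normalized_coords(shape, rr.ravel(), cc.ravel())
    design = _design_matrix(surface.order, x, y)
    return (design @ surface.coefficients).reshape(shape)


def correct_series(
    series: VelocityCineSeries, surface: OffsetSurface
) -> VelocityCineSeries:
    """Subtract the evaluated offset field from every cardiac phase.

    Magnitude stack and all metadata are unchanged.
    """
    if series.shape != tuple(surface.shape):
        raise InvariantError("series and surface grids differ")
    field = evaluate_surface(surface, series.shape)
    return series.with_velocity(series.velocity.astype(np.float64) - field[None, :, :])
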