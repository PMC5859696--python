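"""Background phase-offset correction and temporal phase unwrapping.

Phase-contrast velocity data carry two systematic errors that must be
removed before any pathline is traced:

* slowly varying background phase offsets (eddy currents, gradient-field
  imperfections), modelled as one 3D polynomial of total degree <= 4 per
  velocity component, fitted to static tissue and subtracted everywhere;
* phase wraps, where true velocities beyond +/-VENC alias back into the
  measured range and are restored by a temporal unwrapping pass.

The polynomial is fitted to the *time-averaged* velocity (a single
offset field per component); per-frame offsets are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow_io import ConfigurationError, VelocityField


class RankDeficiencyError(ConfigurationError):
    """Static mask too small for the requested polynomial order."""


def monomial_exponents(order: int) -> list[tuple[int, int, int]]:
    """All (i, j, k) with i + j + k <= order; 35 monomials at order 4."""
    return [
        (i, j, k)
        for i in range(order + 1)
        for j in range(order + 1 - i)
        for k in range(order + 1 - i - j)
    ]


def scaled_coordinates(grid_shape: tuple[int, int, int]) -> list[np.ndarray]:
    """Per-axis voxel-index coordinates scaled to [-1, 1].

    Scaling keeps the degree-4 Vandermonde matrix well conditioned
    regardless of grid size; a single-voxel axis maps to 0.
    """
    coords = []
    for n in grid_shape:
        if n > 1:
            coords.append(2.0 * np.arange(n) / (n - 1) - 1.0)
        else:
            coords.append(np.zeros(1))
    return coords


def design_matrix(
    grid_shape: tuple[int, int, int],
    order: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Monomial design matrix (n_voxels, n_monomials) on the scaled grid."""
    cx, cy, cz = scaled_coordinates(grid_shape)
    if mask is None:
        ix, iy, iz = [c.ravel() for c in np.indices(grid_shape)]
    else:
        ix, iy, iz = np.argwhere(mask).T
    x, y, z = cx[ix], cy[iy], cz[iz]
    cols = [x**i * y**j * z**k for i, j, k in monomial_exponents(order)]
    return np.stack(cols, axis=1)


@dataclass
class BackgroundModel:
    """Least-squares polynomial background, one coefficient set per component."""

    order: int
    coefficients: np.ndarray  # (n_monomials, 3)
    residual_rms: np.ndarray  # (3,) m/s, on the static voxels
    grid_shape: tuple[int, int, int]

    def evaluate(self) -> np.ndarray:
        """Background velocity offset on the full grid, shape (nx, ny, nz, 3)."""
        design = design_matrix(self.grid_shape, self.order)
        return (design @ self.coefficients).reshape(*self.grid_shape, 3)


def fit_background(
    field: VelocityField,
    static_mask: np.ndarray,
    order: int = 4,
) -> BackgroundModel:
    """Fit the per-component background polynomial to static tissue.

    The model is fitted to the time-averaged velocity over the voxels of
    ``static_mask`` (which must not overlap the blood pool).
    """
    static_mask = np.asarray(static_mask).astype(bool)
    if static_mask.shape != field.grid_shape:
        raise ConfigurationError(
            f"static mask grid {static_mask.shape} does not match field grid {field.grid_shape}"
        )
    n_static = int(static_mask.sum())
    n_monomials = len(monomial_exponents(order))
    if n_static == 0:
        raise ConfigurationError("static mask is empty")
    if n_static < n_monomials:
        raise RankDeficiencyError(
            f"{n_static} static voxels cannot constrain {n_monomials} monomials; "
            "enlarge the static mask or lower the polynomial order"
        )
    design = design_matrix(field.grid_shape, order, static_mask)
    tavg = field.values.mean(axis=0)[static_mask]  # (n_static, 3)
    coeffs, *_ = np.linalg.lstsq(design, tavg, rcond=None)
    residual = tavg - design @ coeffs
    rms = np.sqrt(np.mean(residual**2, axis=0))
    return BackgroundModel(order=order, coefficients=coeffs, residual_rms=rms,
                           grid_shape=field.grid_shape)


def subtract_background(field: VelocityField, model: BackgroundModel) -> VelocityField:
    """Subtract the fitted offset from every frame; geometry/timing untouched."""
    if model.grid_shape != field.grid_shape:
        raise ConfigurationError("background model fitted on a different grid")
    offset = model.evaluate()
    return field.copy_with(field.values - offset[None])


def auto_static_mask(field: VelocityField, percentile: float = 10.0) -> np.ndarray:
    """Heuristic static-tissue detector: lowest temporal speed variation.

    Voxels whose temporal standard deviation of speed falls below the
    given percentile are taken as static.  A user-supplied mask always
    takes precedence over this helper.
    """
    speed = np.linalg.norm(field.values, axis=-1)
    sd = speed.std(axis=0)
    return sd <= np.percentile(sd, percentile)


@dataclass
class UnwrapReport:
    wrap_count: int
    n_unreliable_voxels: int
    unreliable_mask: np.ndarray  # (nx, ny, nz) bool


def unwrap_temporal(
    field: VelocityField,
    max_wraps: int = 3,
) -> tuple[VelocityField, UnwrapReport]:
    """Correct phase wraps by walking each voxel's time series.

    Whenever the difference between consecutive samples exceeds VENC in
    magnitude, the later sample (and implicitly all that follow) is
    shifted by the nearest multiple of 2*VENC.  The first frame anchors
    the series and is assumed unwrapped.  A voxel/component series that
    needs more than ``max_wraps`` corrections is left at its original
    values and flagged unreliable: that many alternating jumps is more
    plausibly noise than aliasing.

    The VENC threshold is the tightest one that cannot fire on valid
    data: a physically possible difference satisfies ``|dv| <= 2 VENC``
    only through a wrap once it exceeds VENC.
    """
    two_venc = 2.0 * field.venc
    values = field.values
    diffs = np.diff(values, axis=0)
    # nearest wrap multiple per inter-frame jump; 0 whenever |diff| <= VENC
    steps = np.rint(diffs / two_venc)
    level = np.cumsum(steps, axis=0)  # cumulative wrap level from frame 1 on

    corrected = values.copy()
    corrected[1:] -= two_venc * level

    # samples actually altered, per voxel/component time series
    per_series = np.count_nonzero(level, axis=0)  # (nx, ny, nz, 3)
    exceeded = per_series > max_wraps
    if exceeded.any():
        bad = np.broadcast_to(exceeded[None], values.shape) & True
        corrected[bad] = values[bad]
    unreliable_mask = exceeded.any(axis=-1)
    wrap_count = int(per_series[~exceeded].sum())
    report = UnwrapReport(
        wrap_count=wrap_count,
        n_unreliable_voxels=int(unreliable_mask.sum()),
        unreliable_mask=unreliable_mask,
    )
    return field.copy_with(corrected), report
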