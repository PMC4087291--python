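"""The core dose-plane reconstruction: fan-line product of PDD and profile.

Given the two 1-D inputs — a central-axis percentage depth dose PDD(d) and
one off-axis ratio profile OAR(x) measured at the reference depth d_ref —
the relative dose at a pixel center (x, d) is

    PD(x, d) = PDD(d) * OAR(x_ref) / 100,      x_ref = x * (ssd + d_ref) / (ssd + d)

with both factors in percent.  The profile factor is looked up at the
position where the fan line through the source and (x, d) crosses the
reference depth, so the flat top widens with depth exactly as the beam
diverges; the PDD factor is taken at the vertical depth of the point.
Both curves are first resampled to pixel pitch by linear interpolation and
the product is formed pixel by pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import PDDCurve, ProfileCurve, check_ref_depth, resample_curve
from .geometry import BeamGeometry, GridSpec, fan_map

__all__ = ["DoseMatrix", "reconstruct_plane", "dose_at_point"]

_DOSE_TOL = 1e-6


@dataclass(frozen=True)
class DoseMatrix:
    """A reconstructed percent-dose plane on a :class:`GridSpec` lattice.

    ``values[i, j]`` is the dose in percent of the global maximum at depth
    row ``i`` (increasing downward) and lateral column ``j``.
    """

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError(f"values shape {v.shape} != grid shape {self.grid.shape}")
        if np.any(v < -_DOSE_TOL) or np.any(v > 100.0 + _DOSE_TOL):
            raise ValueError("dose values must lie in [0, 100] percent")
        object.__setattr__(self, "values", v)

    def max_location(self) -> tuple[float, float]:
        """(x, d) of the pixel holding the global maximum."""
        i, j = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return (
            float(self.grid.lateral_centers()[j]),
            float(self.grid.depth_centers()[i]),
        )

    def row_at_depth(self, depth: float) -> np.ndarray:
        return self.values[self.grid.nearest_row(depth)]

    def axis_column(self) -> np.ndarray:
        return self.values[:, self.grid.nearest_col(0.0)]


def _profile_lattice(
    profile: ProfileCurve, grid: GridSpec, geom: BeamGeometry, d_ref: float
):
    """Resample the profile at pixel pitch over the fan-mapped lateral range.

    The fan mapping can push queries slightly beyond the grid's own lateral
    extent (shallow depths map outward), so the lattice is extended to cover
    the widest mapped position, aligned with the grid's lateral origin.
    """
    h = grid.pixel_spacing
    lat = grid.lateral_centers()
    depths = grid.depth_centers()
    factors = (geom.ssd + d_ref) / (geom.ssd + depths)
    fmax = float(np.max(factors))
    lo_needed = min(lat[0] * fmax, lat[0])
    hi_needed = max(lat[-1] * fmax, lat[-1])
    k_lo = int(np.floor((lo_needed - grid.lateral_origin) / h)) - 1
    k_hi = int(np.ceil((hi_needed - grid.lateral_origin) / h)) + 1
    start = grid.lateral_origin + k_lo * h
    count = k_hi - k_lo + 1
    return resample_curve(profile, start, h, count)


def reconstruct_plane(
    pdd: PDDCurve,
    profile: ProfileCurve,
    geom: BeamGeometry,
    grid: GridSpec,
) -> DoseMatrix:
    """Reconstruct the full 2-D relative dose plane from the two input curves.

    Parameters
    ----------
    pdd
        Central-axis percentage depth dose (normalized to max 100).
    profile
        Off-axis ratio at its ``ref_depth`` (normalized to 100 on axis).
        ``ref_depth`` anchors the fan geometry; if it disagrees with the
        PDD maximum by more than one pixel a warning is raised and the
        profile's depth wins.
    geom, grid
        Beam geometry and the target pixel lattice; every pixel center
        must lie inside the phantom.

    Returns
    -------
    DoseMatrix
        ``n_depth x n_lateral`` percent-dose plane whose maximum is 100 on
        the axis at the reference depth (up to interpolation tolerance).
    """
    if not grid.inside_phantom(geom):
        raise ValueError("grid extends beyond the phantom volume")
    d_ref = check_ref_depth(pdd, profile, tol=grid.pixel_spacing)

    pdd_res = resample_curve(pdd, grid.depth_origin, grid.pixel_spacing, grid.n_depth)
    prof_res = _profile_lattice(profile, grid, geom, d_ref)

    lat = grid.lateral_centers()
    depths = grid.depth_centers()
    # fan-map every pixel center to the reference depth, then take the product
    x_ref = lat[None, :] * ((geom.ssd + d_ref) / (geom.ssd + depths))[:, None]
    oar = prof_res.evaluate(x_ref)
    values = pdd_res.values[:, None] * oar / 100.0
    return DoseMatrix(grid=grid, values=np.clip(values, 0.0, None))


def dose_at_point(
    x: float,
    d: float,
    pdd: PDDCurve,
    profile: ProfileCurve,
    geom: BeamGeometry,
    grid: GridSpec | None = None,
) -> float:
    """Relative dose in percent at a single point ``(x, d)``.

    Applies the same fan-line product formula as one pixel of
    :func:`reconstruct_plane`.  When ``grid`` is given the curves are
    resampled to that grid's pitch first, so the result matches the
    corresponding matrix pixel exactly; without a grid the input curves
    are interpolated directly at their native sampling.
    """
    if d < 0:
        raise ValueError("depth must be >= 0")
    d_ref = profile.ref_depth
    x_ref = fan_map(x, d, d_ref, geom)
    if grid is not None:
        pdd_res = resample_curve(pdd, grid.depth_origin, grid.pixel_spacing, grid.n_depth)
        prof_res = _profile_lattice(profile, grid, geom, d_ref)
        return float(pdd_res.evaluate(d) * prof_res.evaluate(x_ref) / 100.0)
    return float(pdd.evaluate(d) * profile.evaluate(x_ref) / 100.0)
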