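"""Beam geometry, coordinate conventions, and the pixel grid.

Conventions used throughout the package:

* depth axis positive downward, ``d = 0`` at the phantom surface;
* lateral axis with ``x = 0`` on the beam central axis;
* all positions refer to pixel/voxel *centers*;
* the X-ray source sits on the central axis at height ``ssd`` above the
  surface, so the fan line through the source and a point ``(x, d)``
  crosses depth ``d'`` at lateral position ``x * (ssd + d') / (ssd + d)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BeamGeometry", "GridSpec", "fan_map"]


@dataclass(frozen=True)
class BeamGeometry:
    """Square-field photon beam incident normally on a water phantom.

    Parameters
    ----------
    ssd
        Source-to-surface distance in cm.
    field_size
        Side of the square field in cm, defined at the phantom surface
        (the SSD plane).
    phantom_halfwidth
        Lateral half-extent of the phantom in cm.
    phantom_depth
        Depth extent of the phantom in cm.
    """

    ssd: float = 100.0
    field_size: float = 10.0
    phantom_halfwidth: float = 25.0
    phantom_depth: float = 30.0

    def __post_init__(self) -> None:
        if not self.ssd > 0:
            raise ValueError(f"ssd must be positive, got {self.ssd}")
        if not self.field_size > 0:
            raise ValueError(f"field_size must be positive, got {self.field_size}")
        if self.field_size > 2.0 * self.phantom_halfwidth:
            raise ValueError(
                "field_size exceeds the phantom width: "
                f"{self.field_size} > {2 * self.phantom_halfwidth}"
            )
        if not self.phantom_depth > 0:
            raise ValueError(f"phantom_depth must be positive, got {self.phantom_depth}")

    def field_halfwidth_at(self, depth: float) -> float:
        """Geometric half-width of the field at ``depth``, by divergence."""
        return 0.5 * self.field_size * (self.ssd + depth) / self.ssd

    def divergence_angle(self, x_surface: float) -> float:
        """Fan-line angle (radians from the axis) through surface point ``x``."""
        return float(np.arctan2(x_surface, self.ssd))


def fan_map(x, d, d_ref: float, geom: BeamGeometry):
    """Project off-axis position(s) along the diverging fan line.

    Returns the lateral position at depth ``d_ref`` of the straight line
    through the source and the point ``(x, d)``:

        x_ref = x * (ssd + d_ref) / (ssd + d)

    ``x`` and ``d`` may be scalars or ndarrays (broadcast together).
    The map is linear and odd in ``x``, the identity for ``d == d_ref``,
    and its own inverse under swapping the two depths.
    """
    d = np.asarray(d, dtype=float)
    if np.any(geom.ssd + d <= 0) or geom.ssd + d_ref <= 0:
        raise ValueError("fan_map requires ssd + depth > 0 on both planes")
    out = np.asarray(x, dtype=float) * (geom.ssd + d_ref) / (geom.ssd + d)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GridSpec:
    """Uniform pixel lattice for a reconstructed dose plane.

    Row index runs over depth (increasing downward), column index over
    lateral position (increasing left to right).  ``lateral_origin`` and
    ``depth_origin`` are the coordinates of the *center* of the first
    column / first row.
    """

    pixel_spacing: float
    n_lateral: int
    n_depth: int
    lateral_origin: float
    depth_origin: float

    def __post_init__(self) -> None:
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        if self.n_lateral < 2 or self.n_depth < 2:
            raise ValueError("grid needs at least 2 pixels per axis")

    @classmethod
    def from_extents(
        cls,
        pixel_spacing: float,
        lateral_halfwidth: float,
        depth_max: float,
        depth_min: float | None = None,
    ) -> "GridSpec":
        """Symmetric lateral lattice including the axis column ``x = 0``.

        Lateral centers run ``-lateral_halfwidth .. +lateral_halfwidth``;
        depth centers start at ``depth_min`` (default: half a pixel below
        the surface) and stop at or before ``depth_max``.
        """
        if depth_min is None:
            depth_min = pixel_spacing / 2.0
        n_half = int(round(lateral_halfwidth / pixel_spacing))
        n_lat = 2 * n_half + 1
        n_dep = int(np.floor((depth_max - depth_min) / pixel_spacing + 1e-9)) + 1
        return cls(
            pixel_spacing=pixel_spacing,
            n_lateral=n_lat,
            n_depth=n_dep,
            lateral_origin=-n_half * pixel_spacing,
            depth_origin=depth_min,
        )

    def lateral_centers(self) -> np.ndarray:
        return self.lateral_origin + self.pixel_spacing * np.arange(self.n_lateral)

    def depth_centers(self) -> np.ndarray:
        return self.depth_origin + self.pixel_spacing * np.arange(self.n_depth)

    def nearest_row(self, depth: float) -> int:
        i = int(round((depth - self.depth_origin) / self.pixel_spacing))
        return min(max(i, 0), self.n_depth - 1)

    def nearest_col(self, x: float) -> int:
        j = int(round((x - self.lateral_origin) / self.pixel_spacing))
        return min(max(j, 0), self.n_lateral - 1)

    def inside_phantom(self, geom: BeamGeometry) -> bool:
        """True when every pixel center lies inside the phantom volume."""
        lat = self.lateral_centers()
        dep = self.depth_centers()
        return bool(
            np.all(np.abs(lat) <= geom.phantom_halfwidth)
            and np.all(dep >= 0)
            and np.all(dep <= geom.phantom_depth)
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_depth, self.n_lateral)
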