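"""Quantitative comparison of a reconstructed plane against a reference.

Deviations are absolute differences in percentage points of the global
maximum (both planes normalized to 100), not local percent differences,
which would blow up wherever the dose is small.  Pixels are grouped into
the standard dosimetric regions by the fan-mapped off-axis ratio r of the
reference profile:

    in field      r >= 80 %
    penumbra      20 % <= r < 80 %
    out of field  r < 20 %

and deviation statistics are reported per region and per comparison depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .curves import ProfileCurve, ResampledCurve, resample_curve
from .geometry import BeamGeometry, GridSpec, fan_map
from .reconstruct import DoseMatrix

__all__ = [
    "COMPARISON_DEPTHS",
    "RegionMasks",
    "AgreementReport",
    "extract_profile",
    "region_masks",
    "agreement",
]

#: Depths (cm) at which profile agreement is tabulated by default: four in
#: the build-up region up to the dose maximum, then six from the maximum to
#: 25.25 cm.
COMPARISON_DEPTHS = (0.75, 1.25, 1.75, 3.25, 4.75, 6.75, 9.25, 15.25, 20.25, 25.25)


def extract_profile(dm: DoseMatrix, depth: float) -> ResampledCurve:
    """Return the lateral dose row nearest to ``depth`` as a curve.

    Snaps to the nearest row center; warns when the requested depth is
    more than half a pixel away from it.
    """
    grid = dm.grid
    i = grid.nearest_row(depth)
    actual = float(grid.depth_centers()[i])
    if abs(actual - depth) > grid.pixel_spacing / 2.0 + 1e-12:
        warnings.warn(
            f"depth {depth:g} cm is outside the grid; snapped to row at "
            f"{actual:g} cm",
            stacklevel=2,
        )
    return ResampledCurve(
        start=grid.lateral_origin,
        spacing=grid.pixel_spacing,
        values=dm.values[i].copy(),
        kind="profile",
    )


@dataclass(frozen=True)
class RegionMasks:
    """Disjoint boolean masks partitioning a dose plane into the in-field,
    penumbra, and out-of-field regions."""

    in_field: np.ndarray
    penumbra: np.ndarray
    out_of_field: np.ndarray

    def __post_init__(self) -> None:
        total = (
            self.in_field.astype(int)
            + self.penumbra.astype(int)
            + self.out_of_field.astype(int)
        )
        if np.any(total != 1):
            raise ValueError("region masks must partition the plane")


def region_masks(
    geom: BeamGeometry, profile: ProfileCurve, grid: GridSpec
) -> RegionMasks:
    """Classify each pixel by the fan-mapped reference off-axis ratio.

    For a pixel at (x, d) the ratio is the profile evaluated at
    ``fan_map(x, d -> ref_depth)`` divided by its axis value, so the field
    and penumbra boundaries widen with depth along the beam divergence.
    """
    prof = resample_curve(
        profile,
        float(profile.positions[0]),
        grid.pixel_spacing,
        int(np.ceil((profile.positions[-1] - profile.positions[0]) / grid.pixel_spacing)) + 1,
    )
    lat = grid.lateral_centers()
    dep = grid.depth_centers()
    x_ref = fan_map(lat[None, :], dep[:, None], profile.ref_depth, geom)
    r = prof.evaluate(x_ref) / 100.0
    in_field = r >= 0.8
    penumbra = (r >= 0.2) & ~in_field
    out_of_field = ~in_field & ~penumbra
    return RegionMasks(in_field=in_field, penumbra=penumbra, out_of_field=out_of_field)


@dataclass(frozen=True)
class AgreementReport:
    """Per-region and per-depth deviation summary, in percentage points of
    the global maximum."""

    region_max: dict
    region_mean: dict
    depth_table: list = field(default_factory=list)  # (depth, max_dev, mean_dev)

    def within(self, in_field_bound: float, penumbra_bound: float) -> bool:
        """True when the region maxima respect the configured bounds."""
        ok_if = self.region_max.get("in_field", 0.0) <= in_field_bound
        ok_pen = self.region_max.get("penumbra", 0.0) <= penumbra_bound
        return bool(ok_if and ok_pen)

    def to_text(self) -> str:
        lines = ["region      max_dev_pp  mean_dev_pp"]
        for name in ("in_field", "penumbra", "out_of_field"):
            lines.append(
                f"{name:<12}{self.region_max[name]:>10.4f}  {self.region_mean[name]:>10.4f}"
            )
        if self.depth_table:
            lines.append("")
            lines.append("depth_cm  max_dev_pp  mean_dev_pp")
            for d, mx, mn in self.depth_table:
                lines.append(f"{d:>8.2f}  {mx:>10.4f}  {mn:>10.4f}")
        return "\n".join(lines)


def agreement(
    recon: DoseMatrix,
    reference: DoseMatrix,
    masks: RegionMasks,
    depths=COMPARISON_DEPTHS,
) -> AgreementReport:
    """Compare two planes pixel by pixel.

    Both planes are renormalized to 100 at their own maxima, then the
    absolute difference is aggregated per region mask and per listed
    comparison depth (nearest row).  The metric is symmetric in the two
    planes.
    """
    if recon.grid != reference.grid:
        raise ValueError("agreement requires identical grids")
    a = recon.values * (100.0 / recon.values.max())
    b = reference.values * (100.0 / reference.values.max())
    dev = np.abs(a - b)

    region_max, region_mean = {}, {}
    for name, mask in (
        ("in_field", masks.in_field),
        ("penumbra", masks.penumbra),
        ("out_of_field", masks.out_of_field),
    ):
        region_max[name] = float(dev[mask].max()) if mask.any() else 0.0
        region_mean[name] = float(dev[mask].mean()) if mask.any() else 0.0

    table = []
    grid = recon.grid
    for d in depths:
        if d < grid.depth_centers()[0] - grid.pixel_spacing / 2 or d > grid.depth_centers()[-1] + grid.pixel_spacing / 2:
            continue
        row = dev[grid.nearest_row(d)]
        table.append((float(d), float(row.max()), float(row.mean())))
    return AgreementReport(region_max=region_max, region_mean=region_mean, depth_table=table)
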