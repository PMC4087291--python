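"""Input dose curves: central-axis PDD and off-axis profile, plus resampling.

Both curve types normalize themselves on construction, because all of the
reconstruction arithmetic works in percent of the dose maximum: a PDD is
scaled so its largest sample is 100, a profile so its (interpolated) value
on the central axis is 100.

Out-of-range evaluation rules differ by curve kind and are deliberate:

* PDD queries outside the sampled depth range clamp to the nearest endpoint
  sample, so a shallow query never produces a negative or wild value;
* profile queries beyond the last sampled position taper linearly to zero
  over one taper length (one pixel spacing when resampling for a grid) and
  are zero beyond that, giving the profile finite support and avoiding
  spurious dose at the phantom edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PDDCurve", "ProfileCurve", "ResampledCurve", "resample_curve"]

_NORM_TOL = 1e-6


def _check_samples(abscissae: np.ndarray, values: np.ndarray, what: str) -> None:
    if abscissae.ndim != 1 or values.ndim != 1 or abscissae.size != values.size:
        raise ValueError(f"{what}: abscissae and values must be 1-D and equal length")
    if abscissae.size < 2:
        raise ValueError(f"{what}: need at least 2 samples, got {abscissae.size}")
    if not np.all(np.diff(abscissae) > 0):
        raise ValueError(f"{what}: abscissae must be strictly increasing")
    if np.any(values < 0):
        raise ValueError(f"{what}: dose values must be non-negative")
    if not np.all(np.isfinite(abscissae)) or not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: samples must be finite")


@dataclass(frozen=True)
class PDDCurve:
    """Central-axis percentage depth dose, normalized to max = 100.

    ``d_ref`` is the depth of the maximum; on ties the shallowest maximum
    is taken (the physical build-up picture: dose rises to a single peak).
    """

    depths: np.ndarray
    values: np.ndarray

    def __init__(self, depths, values):
        depths = np.asarray(depths, dtype=float)
        values = np.asarray(values, dtype=float)
        _check_samples(depths, values, "PDDCurve")
        if np.any(depths < 0):
            raise ValueError("PDDCurve: depths must be >= 0")
        vmax = values.max()
        if vmax <= 0:
            raise ValueError("PDDCurve: all-zero curve cannot be normalized")
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "values", values * (100.0 / vmax))

    @property
    def d_ref(self) -> float:
        """Depth of maximum dose (shallowest sample attaining the max)."""
        return float(self.depths[int(np.argmax(self.values))])

    def evaluate(self, d) -> np.ndarray:
        """Linear interpolation in percent; clamped outside the sampled range."""
        return np.interp(d, self.depths, self.values)


@dataclass(frozen=True)
class ProfileCurve:
    """Off-axis dose at a stated reference depth, in percent of the axis value."""

    positions: np.ndarray
    values: np.ndarray
    ref_depth: float

    def __init__(self, positions, values, ref_depth: float):
        positions = np.asarray(positions, dtype=float)
        values = np.asarray(values, dtype=float)
        _check_samples(positions, values, "ProfileCurve")
        if not (positions[0] < 0.0 < positions[-1]):
            raise ValueError("ProfileCurve: positions must span the central axis")
        if not ref_depth >= 0:
            raise ValueError("ProfileCurve: ref_depth must be >= 0")
        v0 = float(np.interp(0.0, positions, values))
        if v0 <= 0:
            raise ValueError("ProfileCurve: axis value must be positive")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "values", values * (100.0 / v0))
        object.__setattr__(self, "ref_depth", float(ref_depth))

    def evaluate(self, x, taper: float | None = None) -> np.ndarray:
        """Linear interpolation; tapers to 0 over ``taper`` cm past each end.

        ``taper`` defaults to the curve's mean sample spacing.
        """
        if taper is None:
            taper = float(np.mean(np.diff(self.positions)))
        return _interp_tapered(x, self.positions, self.values, taper)


def _interp_tapered(xq, xs: np.ndarray, ys: np.ndarray, taper: float) -> np.ndarray:
    xq = np.asarray(xq, dtype=float)
    out = np.interp(xq, xs, ys)
    lo, hi = xs[0], xs[-1]
    left = xq < lo
    right = xq > hi
    if taper > 0:
        out = np.where(left, ys[0] * np.clip(1.0 - (lo - xq) / taper, 0.0, 1.0), out)
        out = np.where(right, ys[-1] * np.clip(1.0 - (xq - hi) / taper, 0.0, 1.0), out)
    else:
        out = np.where(left | right, 0.0, out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ResampledCurve:
    """A curve resampled onto a dense uniform lattice at pixel pitch."""

    start: float
    spacing: float
    values: np.ndarray
    kind: str = field(default="pdd")  # 'pdd' (clamped) or 'profile' (tapered)

    def positions(self) -> np.ndarray:
        return self.start + self.spacing * np.arange(self.values.size)

    def evaluate(self, x) -> np.ndarray:
        """Piecewise-linear evaluation on the lattice, with the kind's
        out-of-range rule (clamp for PDD, one-spacing taper for profile)."""
        if self.kind == "profile":
            return _interp_tapered(x, self.positions(), self.values, self.spacing)
        out = np.interp(x, self.positions(), self.values)
        return out if np.ndim(out) else float(out)


def resample_curve(curve, start: float, spacing: float, count: int) -> ResampledCurve:
    """Resample a :class:`PDDCurve` or :class:`ProfileCurve` to pixel pitch.

    Values are obtained by piecewise-linear interpolation at the lattice
    points ``start + k * spacing``; outside the sampled range the curve's
    own extrapolation rule applies (clamp for PDD, taper-to-zero over one
    ``spacing`` for profiles).
    """
    if count < 2:
        raise ValueError("resample_curve: count must be >= 2")
    if spacing <= 0:
        raise ValueError("resample_curve: spacing must be positive")
    grid = start + spacing * np.arange(count)
    if isinstance(curve, PDDCurve):
        vals = curve.evaluate(grid)
        kind = "pdd"
    elif isinstance(curve, ProfileCurve):
        vals = curve.evaluate(grid, taper=spacing)
        kind = "profile"
    else:
        raise TypeError(f"cannot resample object of type {type(curve).__name__}")
    return ResampledCurve(start=start, spacing=spacing, values=np.asarray(vals), kind=kind)


def check_ref_depth(pdd: PDDCurve, profile: ProfileCurve, tol: float) -> float:
    """Reconcile the profile's stated depth with the PDD maximum.

    Warns when they disagree by more than ``tol`` (one pixel spacing) and
    returns the profile's ``ref_depth``, which anchors the fan geometry.
    """
    if abs(pdd.d_ref - profile.ref_depth) > tol:
        warnings.warn(
            f"profile ref_depth {profile.ref_depth:g} cm differs from the PDD "
            f"maximum at {pdd.d_ref:g} cm; using the profile's ref_depth",
            stacklevel=3,
        )
    return profile.ref_depth
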