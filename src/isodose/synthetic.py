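"""Analytic 18 MV-like beam fixture: PDD, profile, and ground-truth planes.

Monte-Carlo beam data is expensive (days of transport per plane), so this
module provides a closed-form stand-in with the gross features of an 18 MV
photon beam in water: a build-up-times-attenuation depth dose

    PDD(d)  propto  (1 - exp(-alpha d)) * exp(-mu d)

peaking at d_max = ln(1 + alpha/mu) / alpha, and a flat-top profile with
error-function penumbrae

    OAR(x)  propto  erf((a - x)/sigma) + erf((a + x)/sigma)

with the field half-width ``a`` projected to the reference depth.  The
attenuation coefficient mu is a cosmetic default giving a realistic 18 MV
tail slope; alpha is solved so the peak sits at the configured depth
(3.25 cm by default, the build-up maximum of the modeled beam).

Two ground-truth planes are available:

* :func:`separable_truth` — exactly the fan-line product model, so a
  reconstruction from its own sampled curves must reproduce it up to pure
  interpolation error (the closure oracle);
* :func:`nonseparable_truth` — adds what the product model cannot
  represent: a penumbra that widens with depth faster than pure beam
  divergence and a small long-range scatter tail outside the field, both
  stand-ins for the extra scatter of a polyenergetic beam at depth.

Everything here is deterministic given its parameters; optional Gaussian
noise on the truth planes takes an explicit seed and defaults to off.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .curves import PDDCurve, ProfileCurve
from .geometry import BeamGeometry, GridSpec, fan_map
from .reconstruct import DoseMatrix

__all__ = [
    "BeamModelParams",
    "ScoringGrid",
    "synth_pdd",
    "synth_profile",
    "separable_truth",
    "nonseparable_truth",
    "sample_curves_from_truth",
    "paper_scoring_grid",
]


@dataclass(frozen=True)
class BeamModelParams:
    """Parameters of the analytic beam model.

    mu : cm^-1
        Effective linear attenuation of the exponential PDD tail.
    d_max_target : cm
        Depth where the PDD must peak; the build-up rate alpha is solved
        from it.
    penumbra_sigma0 : cm
        Error-function penumbra width of the profile (and of the separable
        truth) at the reference depth.
    penumbra_growth : cm of sigma per cm of depth
        Extra penumbra widening used only by the non-separable truth.
    tail_amplitude : fraction
        Out-of-field scatter tail of the non-separable truth, as a fraction
        of the local central-axis dose (<= 0.03).
    tail_length : cm
        Exponential decay length of that tail beyond the field edge.
    """

    mu: float = 0.045
    d_max_target: float = 3.25
    penumbra_sigma0: float = 0.3
    penumbra_growth: float = 0.04
    tail_amplitude: float = 0.02
    tail_length: float = 5.0

    def __post_init__(self) -> None:
        for name in ("mu", "d_max_target", "penumbra_sigma0", "tail_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.penumbra_growth < 0 or self.tail_amplitude < 0:
            raise ValueError("penumbra_growth and tail_amplitude must be >= 0")
        if self.tail_amplitude > 0.03:
            raise ValueError("tail_amplitude above 3% is outside the model's remit")
        self.alpha  # solve now so an unreachable peak fails at construction

    @cached_property
    def alpha(self) -> float:
        """Build-up rate solved so the PDD peaks at ``d_max_target``.

        The peak of (1 - e^{-alpha d}) e^{-mu d} sits at
        d* = ln(1 + alpha/mu) / alpha, which decreases monotonically in
        alpha; a bracketing root-find pins d* to the target.
        """
        mu, target = self.mu, self.d_max_target

        def f(a: float) -> float:
            return np.log1p(a / mu) / a - target

        lo, hi = mu, 1e3 * mu
        if f(lo) < 0 or f(hi) > 0:
            raise ValueError(
                f"no build-up rate in ({lo:g}, {hi:g}) cm^-1 yields a peak at "
                f"{target:g} cm; alpha > mu is required for a maximum"
            )
        return float(brentq(f, lo, hi, xtol=1e-12))

    def pdd_percent(self, d) -> np.ndarray:
        """Analytic PDD in percent of its continuous maximum."""
        a, mu = self.alpha, self.mu
        dstar = np.log1p(a / mu) / a
        peak = (1.0 - np.exp(-a * dstar)) * np.exp(-mu * dstar)
        d = np.asarray(d, dtype=float)
        out = (1.0 - np.exp(-a * d)) * np.exp(-mu * d) * (100.0 / peak)
        return out if out.ndim else float(out)

    def oar_fraction(self, x, a_edge: float, sigma: float) -> np.ndarray:
        """Flat-top profile as a fraction of its axis value."""
        x = np.asarray(x, dtype=float)
        num = erf((a_edge - x) / sigma) + erf((a_edge + x) / sigma)
        den = 2.0 * erf(a_edge / sigma)
        out = num / den
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ScoringGrid:
    """The coarse voxel lattice dose is scored on (0.5 cm cubic voxels)."""

    voxel_side: float
    depth_centers: np.ndarray
    lateral_centers: np.ndarray

    @property
    def voxel_volume(self) -> float:
        return self.voxel_side ** 3

    @property
    def n_rows(self) -> int:
        return int(np.size(self.depth_centers))

    @property
    def n_cols(self) -> int:
        return int(np.size(self.lateral_centers))

    @property
    def n_voxels(self) -> int:
        return self.n_rows * self.n_cols

    def to_gridspec(self) -> GridSpec:
        return GridSpec(
            pixel_spacing=self.voxel_side,
            n_lateral=self.n_cols,
            n_depth=self.n_rows,
            lateral_origin=float(self.lateral_centers[0]),
            depth_origin=float(self.depth_centers[0]),
        )


def paper_scoring_grid() -> ScoringGrid:
    """Default scoring lattice: 56 depth rows x 60 lateral columns of
    0.5 cm voxels (3360 voxels of 0.125 cm^3), depth centers 0.25-27.75 cm,
    lateral centers spanning 30 cm."""
    side = 0.5
    return ScoringGrid(
        voxel_side=side,
        depth_centers=0.25 + side * np.arange(56),
        lateral_centers=-14.75 + side * np.arange(60),
    )


def synth_pdd(params: BeamModelParams, depths) -> PDDCurve:
    """Sample the analytic PDD on ``depths`` (cm).  The surface value of
    the build-up form is 0; the curve renormalizes to max 100 on its own
    grid."""
    depths = np.asarray(depths, dtype=float)
    return PDDCurve(depths, params.pdd_percent(depths))


def _edge_at_ref(params: BeamModelParams, geom: BeamGeometry) -> float:
    return geom.field_halfwidth_at(params.d_max_target)


def synth_profile(params: BeamModelParams, geom: BeamGeometry, positions) -> ProfileCurve:
    """Sample the flat-top profile at the reference depth.

    The field edge ``a`` is the surface half-field projected to
    ``d_max_target`` along the fan lines; sigma is ``penumbra_sigma0``.
    """
    positions = np.asarray(positions, dtype=float)
    vals = 100.0 * params.oar_fraction(
        positions, _edge_at_ref(params, geom), params.penumbra_sigma0
    )
    return ProfileCurve(positions, vals, ref_depth=params.d_max_target)


def separable_truth(
    params: BeamModelParams, geom: BeamGeometry, grid: GridSpec
) -> DoseMatrix:
    """Ground-truth plane that is exactly the fan-line product model:
    ``PDD(d) * OAR(fan_map(x, d -> d_ref)) / 100`` evaluated analytically
    at every pixel center."""
    d_ref = params.d_max_target
    lat = grid.lateral_centers()
    dep = grid.depth_centers()
    x_ref = fan_map(lat[None, :], dep[:, None], d_ref, geom)
    oar = params.oar_fraction(x_ref, _edge_at_ref(params, geom), params.penumbra_sigma0)
    values = params.pdd_percent(dep)[:, None] * oar
    return DoseMatrix(grid=grid, values=values)


def nonseparable_truth(
    params: BeamModelParams,
    geom: BeamGeometry,
    grid: GridSpec,
    noise_percent: float = 0.0,
    seed: int | None = None,
) -> DoseMatrix:
    """Ground truth the product model can only approximate.

    Relative to :func:`separable_truth` the penumbra width grows linearly
    with depth, ``sigma(d) = penumbra_sigma0 + penumbra_growth * d``, and an
    exponential scatter tail of ``tail_amplitude`` times the local axis
    dose is added outside the field edge.  With ``penumbra_growth = 0`` and
    ``tail_amplitude = 0`` this reduces exactly to the separable plane.

    ``noise_percent`` adds zero-mean Gaussian noise (percent of maximum,
    clipped to the valid range) from an explicit ``seed``; off by default.
    """
    d_ref = params.d_max_target
    a_edge = _edge_at_ref(params, geom)
    lat = grid.lateral_centers()
    dep = grid.depth_centers()
    x_ref = fan_map(lat[None, :], dep[:, None], d_ref, geom)
    sigma = params.penumbra_sigma0 + params.penumbra_growth * dep
    oar = params.oar_fraction(x_ref, a_edge, sigma[:, None])
    pdd = params.pdd_percent(dep)[:, None]
    values = pdd * oar
    outside = np.abs(x_ref) > a_edge
    tail = (
        params.tail_amplitude
        * pdd
        * np.exp(-(np.abs(x_ref) - a_edge) / params.tail_length)
    )
    values = values + np.where(outside, tail, 0.0)
    if noise_percent > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_percent, size=values.shape)
    values = np.clip(values, 0.0, None)
    return DoseMatrix(grid=grid, values=values * (100.0 / values.max()))


def sample_curves_from_truth(dm: DoseMatrix) -> tuple[PDDCurve, ProfileCurve]:
    """Extract the reconstruction's two inputs from a ground-truth plane:
    the central-axis column as a PDD (renormalized to 100) and the row at
    that PDD's maximum as the profile, anchored at the row's depth."""
    grid = dm.grid
    pdd = PDDCurve(grid.depth_centers(), dm.axis_column())
    row = grid.nearest_row(pdd.d_ref)
    profile = ProfileCurve(
        grid.lateral_centers(),
        dm.values[row],
        ref_depth=float(grid.depth_centers()[row]),
    )
    return pdd, profile
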