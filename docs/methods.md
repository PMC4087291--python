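# Methods

## The reconstruction model

`isodose` reconstructs the full 2-D relative absorbed-dose distribution of a
divergent megavoltage photon beam in a homogeneous water phantom from two
one-dimensional inputs:

* the **central-axis percentage depth dose** PDD(d), normalized to 100 % at
  the depth of maximum dose d_ref;
* one **off-axis profile** OAR(x) measured at d_ref, normalized to 100 % on
  the axis.

For a point (x, d) — lateral position x, vertical depth d, both in cm with
the origin on the axis at the phantom surface — the relative dose is the
separable fan-line product

    PD(x, d) = PDD(d) · OAR(x_ref) / 100,
    x_ref    = x · (SSD + d_ref) / (SSD + d),

where SSD is the source-to-surface distance. The profile factor is read at
the point where the straight line through the source and (x, d) crosses the
reference depth, so the flat top of the field widens with depth exactly as
the beam diverges. The PDD factor uses the vertical depth of the point, not
the slant depth along the fan line; for a 100 cm SSD and depths up to 30 cm
the slant correction inside a 10 × 10 cm² field is below 1.5 % of depth and
the vertical convention keeps the axis column an exact copy of the input
PDD.

Both curves are resampled to the pixel pitch by piecewise-linear
interpolation before the product is formed (no smoothing), and the matrix
is laid out with the depth index increasing downward and the lateral index
left to right.

**Assumptions.** The model is exact only for a separable dose distribution:
one profile shape, rescaled geometrically, must describe every depth. Real
megavoltage beams violate this mainly in the penumbra (scatter widens it
with depth faster than pure divergence) and through out-of-field scatter;
the validation fixtures quantify exactly this error mode. Heterogeneities,
wedges, non-square fields, oblique incidence and absolute dose are out of
scope; every value the package handles is a percent of the dose maximum.

### Numerical conventions

* **Normalization.** A PDD is divided by its maximum sample; a profile by
  its interpolated value at x = 0. All internal arithmetic is in percent.
* **d_ref ties.** If several depths share the PDD maximum the shallowest
  wins — deterministic and consistent with the build-up picture.
* **d_ref mismatch.** When the profile's stated depth disagrees with the
  PDD argmax by more than one pixel, the code warns and trusts the
  profile's depth: it is the geometric anchor of the fan mapping.
* **Extrapolation.** PDD queries outside the sampled depth range clamp to
  the endpoint samples (never negative, never extrapolated upward).
  Profile queries beyond the last sample taper linearly to zero over one
  pixel spacing and are zero beyond — finite support avoids spurious dose
  at the phantom edge where the fan mapping can query past the data.
* **Grids.** All positions are pixel *centers*; `GridSpec.from_extents`
  builds a symmetric lateral lattice that contains the axis column, and the
  default depth lattice (0.05, 0.15, …) contains d_ref = 3.25 cm so the
  global maximum is represented exactly.

## Rendering

The grayscale image is `round(dose/100 · 255)` (half away from zero,
clamped to 0–255) on all three RGB channels, so 100 % maps to 255 and 0 %
to 0. Decile isodose bands use edges 1, 10, 20, …, 100 with half-open
`(lo, hi]` intervals, the lowest band closed below and doses under 1 %
labelled background; pixels whose 4-neighborhood contains another label
form the isodose contour lines, and a sub-pixel polyline tracer
(`skimage.measure.find_contours` on the label matrix) is available for
vector output.

Color rendering uses the HSI triangle model. Hue is a three-sector
quantity selected by the smallest RGB channel (see the formulas in
`isodose.render`); the raw hue in [0, 3) is stored divided by 3. The
G-smallest branch is implemented with the pattern-consistent denominator
3I − 3G; a variant with 3I − 3R (seen in some printed sources) sits behind
a flag. Achromatic pixels pin S = 0 and H = 0 so serialization is
deterministic. A matrix-form transform (opponent axes, hue as
`atan2(V1, V2)`, saturation as the chroma radius) is provided for
completeness with a standard invertible matrix — printed variants of that
matrix are often singular — but the triangle-model branches are the
rendering path actually used.

The default palette follows the hot-to-cold clinical reading: red-orange
for 80–100 %, yellow for 70–80 %, green for 25–70 %, blue for 0–25 %,
with the intensity channel scaling linearly with dose inside each band
(uniform channel scaling leaves triangle-model hue and saturation
invariant, which is why band colors stay pure as they darken).

## The synthetic beam fixture

Monte-Carlo or measured beam data is not shipped; an analytic stand-in with
the gross features of an 18 MV beam provides inputs and ground truth.

* **PDD:** `(1 − e^(−α d)) · e^(−μ d)`, the product of electron build-up
  and exponential photon attenuation. μ = 0.045 cm⁻¹ is a cosmetic default
  giving a realistic 18 MV tail slope; α is root-solved (Brent, bracketed
  on (μ, 1000 μ)) so the continuous peak d* = ln(1 + α/μ)/α lands at the
  configured 3.25 cm. The surface value of this form is 0; real surface
  dose (electron contamination) is not modeled.
* **Profile:** the erf flat top `½[erf((a−x)/σ) + erf((a+x)/σ)]` with the
  field edge a = half-field projected to d_ref along the fan (5.1625 cm for
  a 10 cm field at 100 cm SSD) and σ = 0.3 cm, a typical megavoltage
  penumbra width. No horns or asymmetry are modeled.
* **Scoring grid:** the coarse lattice mirrors the simulation bookkeeping
  of the modeled experiment: 0.5 cm cubic voxels, 56 depth rows with
  centers 0.25–27.75 cm, 60 lateral columns spanning 30 cm — 3360 voxels
  of 0.125 cm³. The first/last row depths are the unique 0.5 cm lattice
  consistent with those counts and the 30 cm phantom.
* **Separable truth** evaluates the fan-line product analytically at every
  pixel — by construction inside the reconstruction's model class, so
  reconstructing from its own sampled curves isolates pure interpolation
  error ("closure").
* **Non-separable truth** adds the physics the product model cannot
  represent: penumbra width σ(d) = 0.3 + 0.04·d cm (growth well above the
  ~0.003 cm/cm that divergence alone provides) and a 2 % of-local-axis-dose
  scatter tail decaying over 5 cm outside the field edge. With growth and
  tail set to zero it reduces exactly to the separable plane. Optional
  Gaussian noise takes an explicit seed and defaults to off, so all
  fixtures are deterministic.

**What passing the closure tests shows — and does not.** The separable
closure (in-field max deviation 0.65 pp at 0.1 cm pixels, shrinking as the
pixel shrinks: 2.34 → 0.65 → 0.17 pp over 0.2 → 0.1 → 0.05 cm) verifies
the interpolation and fan-mapping machinery, not fidelity to real beams.
The non-separable comparison measures the model error itself: with the
fixture's deliberately aggressive penumbra growth the penumbra-region
deviation reaches ≈ 9 pp of D_max (peaking near 16 cm depth), an expected
and instructive failure of any single-profile product model — the erf-width
mismatch between the fan-scaled σ ≈ 0.5 cm and the true σ ≈ 1.4 cm at
depth predicts this magnitude analytically. Against milder truths (growth
off, tail only) the penumbra deviation stays within ~2.7 pp.

## Validation metrics

Deviations are absolute differences in **percentage points of the global
maximum** after renormalizing both planes to 100 — not local percent
differences, which diverge at low dose. Regions follow the standard
dosimetric convention on the fan-mapped reference off-axis ratio r:
in-field r ≥ 80 %, penumbra 20 % ≤ r < 80 %, out-of-field r < 20 %; the
three masks partition the plane. Agreement is tabulated per region and at
ten comparison depths (0.75–25.25 cm, four in the build-up region). No
gamma-index analysis is performed; the comparison is raw percent values.

## Problem sizes and runtime

The default reconstruction grid is 0.1 cm pixels over ±15 cm × 0.05–27.95
cm (301 × 280 ≈ 84 000 pixels); a full simulate–reconstruct–validate cycle
takes well under a second, and the refinement study at 0.05 cm pixels a
few seconds. These sizes resolve the 0.3 cm penumbra with ≥ 3 pixels per
sigma while keeping every example and test quick.

## Known limitations

* Single square field, normal incidence, homogeneous water; relative dose
  only.
* The fixture is qualitative: it reproduces the shape of megavoltage depth
  dose and profiles, not any measured beam's numbers.
* Profiles with off-axis values above the axis value (horns) are not
  representable: the dose matrix enforces a 100 % ceiling.
* The half-open band rule places a dose exactly at a decile edge in the
  lower band; renderers using a different closure will disagree on edge
  pixels only.
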