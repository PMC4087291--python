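# isodose

Reconstruction and isodose rendering of 2-D relative dose distributions for
megavoltage photon beams in water, from just two 1-D inputs: the
central-axis percentage depth dose (PDD) and a single off-axis profile at
the depth of maximum dose.

Commissioning a radiotherapy beam yields exactly these two curves long
before a full 2-D/3-D dataset exists, and Monte-Carlo planes take hours to
days to compute. For a homogeneous phantom and a single square field the
whole plane is well approximated by a separable product read along the
beam's diverging fan lines:

    PD(x, d) = PDD(d) · OAR(x_ref) / 100,     x_ref = x · (SSD + d_ref) / (SSD + d)

with SSD the source-to-surface distance and d_ref the depth of maximum
dose. `isodose` implements this reconstruction at arbitrary pixel pitch,
segments the result into decile isodose bands, renders it in grayscale
(`gray = dose/100 · 255`) and in HSI color (red-orange ≥ 80 %, yellow
70–80 %, green 25–70 %, blue < 25 %), and quantifies agreement against
reference planes in percentage points of D_max, split into in-field,
penumbra, and out-of-field regions. An analytic 18 MV-like beam fixture
(build-up × attenuation PDD peaking at 3.25 cm, erf flat-top profile,
10 × 10 cm² field at 100 cm SSD) provides deterministic inputs and ground
truth. See `docs/methods.md` for the model, conventions, and limitations.

Intended users: medical-physics students and researchers prototyping
dose-plane tooling, and anyone needing a transparent, testable baseline for
separable dose reconstruction.

## Worked example

```sh
python examples/reconstruct_plane.py
```

prints

```
plane shape (depth rows x lateral cols): (280, 301)
global maximum: 100.00 %
dose on axis at d_max (3.25 cm): 100.00 %
dose on axis at 10 cm depth:    77.28 %
dose at (4 cm, 10 cm):          77.28 %
dose outside field (8, 10):      0.00 %
50% field edge at 10 cm depth:   5.50 cm (5 cm at the surface)
```

The axis dose falls to 77 % at 10 cm depth (exponential attenuation past
the build-up peak); 4 cm off-axis is still inside the flat top so it reads
the same 77 %; 8 cm is outside the field, essentially zero. The 50 % edge
sits at 5.50 cm = 5 · 110/100: the field widens with depth exactly as the
beam diverges. `examples/render_isodose.py` writes the grayscale, banded,
and color PNGs, and `examples/validate_closure.py` prints the full
region/depth agreement tables against separable and non-separable ground
truth.

The same workflows are available as a CLI:

```sh
isodose simulate --out beamdata          # pdd.csv, profile.csv, truth.dat
isodose reconstruct beamdata/pdd.csv beamdata/profile.csv --out plane.dat
isodose render plane.dat --mode hsi --out plane.png
isodose validate plane.dat beamdata/truth.dat
isodose --show-config                    # all defaults as YAML
```

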