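"""Render a reconstructed dose plane as grayscale, isodose bands, and color.

Writes three PNGs next to this script and prints what each encodes:
gray tone = dose/100 * 255; decile bands whose borders are the isodose
curves; HSI color with red-orange >80%, yellow 70-80%, green 25-70%,
blue <25%.
"""

from pathlib import Path

import numpy as np

from isodose import (
    BeamGeometry,
    BeamModelParams,
    GridSpec,
    band_contours,
    bands_to_gray,
    reconstruct_plane,
    render_color,
    segment_bands,
    synth_pdd,
    synth_profile,
    to_gray,
)
from isodose.io import write_png

geom = BeamGeometry()
params = BeamModelParams()
pdd = synth_pdd(params, np.arange(0.0, 28.01, 0.25))
profile = synth_profile(params, geom, np.arange(-15.0, 15.01, 0.25))
grid = GridSpec.from_extents(0.1, 15.0, 27.95)
plane = reconstruct_plane(pdd, profile, geom, grid)

out = Path(__file__).resolve().parent

gray = to_gray(plane)
write_png(out / "plane_gray.png", gray)
print(f"plane_gray.png: gray levels 0..{gray.max()} (255 = the 100% dose maximum)")

bands = segment_bands(plane)
write_png(out / "plane_bands.png", bands_to_gray(bands))
n_contour = int(band_contours(bands).sum())
print(f"plane_bands.png: {bands.labels.max()} decile bands, "
      f"{n_contour} isodose-contour pixels")

color = render_color(plane)
write_png(out / "plane_color.png", color)
rgb_max = tuple(int(c) for c in color[grid.nearest_row(3.25), grid.nearest_col(0)])
print(f"plane_color.png: HSI palette, e.g. the dose maximum renders red-orange, RGB {rgb_max}")
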