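"""Rendering of dose planes: 8-bit grayscale, decile isodose bands, HSI color.

The grayscale map is the straight linear transform of the normalized dose,
``gray = round(dose/100 * 255)``, replicated over the three RGB channels.
Isodose bands group doses into decile intervals ([1,10], (10,20], ...,
(90,100]); the 1-pixel borders between bands are the isodose curves.

Color rendering goes through the HSI (hue, saturation, intensity) triangle
model.  Hue is a 3-sector quantity selected by the smallest RGB channel:

    I = (R + G + B) / 3
    B smallest:  H = (G - B) / (3I - 3B),      S = (I - B) / I
    R smallest:  H = (B - R) / (3I - 3R) + 1,  S = (I - R) / I
    G smallest:  H = (R - G) / (3I - 3G) + 2,  S = (I - G) / I

and the raw hue in [0, 3) is stored divided by 3, in [0, 1).  Some published
variants of the G-smallest branch put ``3I - 3R`` in the denominator; that
form is available behind ``g_branch_denominator="r"`` but the
pattern-consistent ``3I - 3G`` is the default.  Achromatic pixels (all
channels equal) take S = 0 and, by convention, H = 0.

A matrix-form RGB -> (I, V1, V2) transform with H = atan(V1/V2) and
S = sqrt(V1^2 + V2^2) is provided for completeness; published matrix
variants of this transform are frequently misprinted (non-invertible rows),
so this implementation uses a standard invertible opponent-axis matrix and
the triangle-model branches above remain the authoritative rendering path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruct import DoseMatrix

__all__ = [
    "BandMap",
    "PaletteBand",
    "DEFAULT_EDGES",
    "DEFAULT_PALETTE",
    "to_gray",
    "segment_bands",
    "band_contours",
    "band_polylines",
    "bands_to_gray",
    "rgb_to_hsi",
    "hsi_to_rgb",
    "hsi_matrix_transform",
    "hsi_matrix_inverse",
    "render_color",
]

#: Decile isodose edges: bands [1,10], (10,20], ..., (90,100] in percent.
DEFAULT_EDGES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)

_DOSE_TOL = 1e-6


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (doses are non-negative here)."""
    return np.floor(np.asarray(x) + 0.5)


def to_gray(dm: DoseMatrix) -> np.ndarray:
    """8-bit grayscale image of a dose plane: ``round(dose/100 * 255)``.

    100 % dose maps to gray level 255, 0 % to 0; the map is monotone
    non-decreasing.  The same value serves all three RGB channels.
    """
    v = dm.values
    if np.any(v > 100.0 + _DOSE_TOL):
        raise ValueError("dose values above 100 percent cannot be rendered")
    return np.clip(_round_half_away(v / 100.0 * 255.0), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class BandMap:
    """Per-pixel isodose band labels.

    ``labels[i, j] == k`` means the dose falls in band ``k`` (1-based,
    ``(edges[k-1], edges[k]]`` with the lowest band closed below); 0 marks
    background pixels below the lowest edge.
    """

    labels: np.ndarray
    edges: tuple[float, ...]

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1


def segment_bands(dm: DoseMatrix, edges=DEFAULT_EDGES) -> BandMap:
    """Assign each pixel to an isodose dose band.

    ``edges`` must be strictly increasing; band ``k`` covers
    ``(edges[k-1], edges[k]]`` except the first band which also includes
    its lower edge.  Doses below ``edges[0]`` are background (label 0).
    """
    edges = tuple(float(e) for e in edges)
    if len(edges) < 2 or not all(a < b for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    v = dm.values
    # numerical residue just above the top edge still belongs to the top band
    v = np.where((v > edges[-1]) & (v <= edges[-1] + _DOSE_TOL), edges[-1], v)
    labels = np.searchsorted(edges[1:], v, side="left") + 1
    labels = np.where(v < edges[0], 0, labels)
    labels = np.where(v > edges[-1], 0, labels)  # truly above top edge: background
    return BandMap(labels=labels.astype(np.int32), edges=edges)


def band_contours(bm: BandMap) -> np.ndarray:
    """Boolean mask of isodose contour pixels.

    A pixel is a contour pixel when any of its 4-neighbors carries a
    different band label; the borders between gray tones are the isodose
    curves.
    """
    lab = bm.labels
    edge = np.zeros(lab.shape, dtype=bool)
    edge[:-1, :] |= lab[:-1, :] != lab[1:, :]
    edge[1:, :] |= lab[1:, :] != lab[:-1, :]
    edge[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    edge[:, 1:] |= lab[:, 1:] != lab[:, :-1]
    return edge


def band_polylines(bm: BandMap) -> list[np.ndarray]:
    """Sub-pixel isodose polylines, one array of (row, col) vertices each.

    Traces the half-level contours of the label matrix, giving a vector
    version of :func:`band_contours`.
    """
    from skimage import measure

    lines: list[np.ndarray] = []
    for k in range(1, bm.n_bands + 1):
        lines.extend(measure.find_contours(bm.labels.astype(float), level=k - 0.5))
    return lines


def bands_to_gray(bm: BandMap, draw_contours: bool = True) -> np.ndarray:
    """Render a band map as an 8-bit image, one gray tone per band.

    Each band takes the gray tone of its midpoint dose; background is 0 and
    contour pixels are drawn black when ``draw_contours`` is set.
    """
    edges = np.asarray(bm.edges)
    mids = (edges[:-1] + edges[1:]) / 2.0
    tones = np.concatenate([[0.0], np.clip(_round_half_away(mids / 100.0 * 255.0), 0, 255)])
    img = tones[bm.labels].astype(np.uint8)
    if draw_contours:
        img[band_contours(bm)] = 0
    return img


# ---------------------------------------------------------------------------
# HSI triangle model
# ---------------------------------------------------------------------------

def rgb_to_hsi(rgb, g_branch_denominator: str = "g") -> np.ndarray:
    """Triangle-model RGB -> HSI for unit-interval channels.

    ``rgb`` is an array of shape (..., 3) with channels in [0, 1]; the
    result has the same shape, channels (H, S, I) with H in [0, 1) (raw
    3-sector hue divided by 3), S in [0, 1], I in [0, 1].  Branches are
    tested in the order B-smallest, R-smallest, G-smallest with non-strict
    comparisons, so channel ties resolve deterministically.
    """
    if g_branch_denominator not in ("g", "r"):
        raise ValueError("g_branch_denominator must be 'g' or 'r'")
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("rgb must have a trailing axis of size 3")
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise ValueError("RGB channels must lie in [0, 1]")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    i = (r + g + b) / 3.0

    with np.errstate(divide="ignore", invalid="ignore"):
        b_small = (b <= r) & (b <= g)
        r_small = ~b_small & (r <= b) & (r <= g)
        g_small = ~b_small & ~r_small

        h_b = (g - b) / (3.0 * (i - b))
        s_b = (i - b) / i
        h_r = (b - r) / (3.0 * (i - r)) + 1.0
        s_r = (i - r) / i
        g_den = i - (g if g_branch_denominator == "g" else r)
        h_g = (r - g) / (3.0 * g_den) + 2.0
        s_g = (i - g) / i

        h = np.select([b_small, r_small, g_small], [h_b, h_r, h_g])
        s = np.select([b_small, r_small, g_small], [s_b, s_r, s_g])

    achromatic = np.isclose(r, g) & np.isclose(g, b)
    h = np.where(achromatic, 0.0, h) / 3.0
    s = np.where(achromatic | (i == 0), 0.0, s)
    h = np.where(s == 0, 0.0, h)
    return np.stack([h, s, i], axis=-1)


def hsi_to_rgb(hsi) -> np.ndarray:
    """Inverse triangle-model transform, HSI -> RGB in [0, 1].

    The sector is the integer part of the raw hue ``3 H``; within a sector
    the smallest channel is ``I (1 - S)`` and the other two follow from the
    hue fraction.  Exact inverse of :func:`rgb_to_hsi` (default branch
    form) wherever the smallest channel is unique.
    """
    hsi = np.asarray(hsi, dtype=float)
    h, s, i = hsi[..., 0], hsi[..., 1], hsi[..., 2]
    h_raw = np.clip(h * 3.0, 0.0, np.nextafter(3.0, 0.0))
    sector = np.floor(h_raw).astype(int)
    f = h_raw - sector

    low = i * (1.0 - s)          # the smallest channel in every sector
    mid = low + f * 3.0 * i * s  # channel whose difference defines the hue
    high = 3.0 * i - low - mid

    r = np.select([sector == 0, sector == 1, sector == 2], [high, low, mid])
    g = np.select([sector == 0, sector == 1, sector == 2], [mid, high, low])
    b = np.select([sector == 0, sector == 1, sector == 2], [low, mid, high])
    rgb = np.stack([r, g, b], axis=-1)
    gray = np.broadcast_to((s == 0)[..., None], rgb.shape)
    return np.where(gray, np.broadcast_to(i[..., None], rgb.shape), rgb)


# Standard invertible opponent-axis matrix: intensity plus two chroma axes
# (blue-yellow and red-green), rows orthogonal.
_OPPONENT = np.array(
    [
        [1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0],
        [-1.0 / np.sqrt(6.0), -1.0 / np.sqrt(6.0), 2.0 / np.sqrt(6.0)],
        [1.0 / np.sqrt(2.0), -1.0 / np.sqrt(2.0), 0.0],
    ]
)


def hsi_matrix_transform(rgb) -> tuple[np.ndarray, ...]:
    """Matrix-form color transform: RGB -> (I, V1, V2, H, S).

    Applies the opponent-axis matrix to the RGB vector, then reads hue as
    the angle of the chroma vector (``atan2(V1, V2)``) and saturation as
    its length.  Gray pixels give V1 = V2 = S = 0.  Provided for
    completeness; isodose color rendering uses the triangle-model path.
    """
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise ValueError("RGB channels must lie in [0, 1]")
    ivv = rgb @ _OPPONENT.T
    i, v1, v2 = ivv[..., 0], ivv[..., 1], ivv[..., 2]
    h = np.arctan2(v1, v2)
    s = np.hypot(v1, v2)
    return i, v1, v2, h, s


def hsi_matrix_inverse(i, h, s) -> np.ndarray:
    """Invert :func:`hsi_matrix_transform`: (I, H, S) -> RGB."""
    v1 = s * np.sin(h)
    v2 = s * np.cos(h)
    ivv = np.stack([np.asarray(i, dtype=float), v1, v2], axis=-1)
    return ivv @ np.linalg.inv(_OPPONENT).T


# ---------------------------------------------------------------------------
# Color rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PaletteBand:
    """One dose range of the color palette: ``(lo, hi]`` percent -> hue/sat."""

    lo: float
    hi: float
    hue: float        # triangle-model hue in [0, 1)
    saturation: float = 1.0


#: Hot-to-cold clinical palette: red-orange for the high-dose core, yellow,
#: green and blue toward the periphery, intensity scaling with dose inside
#: each band ("light-dark" shading).
DEFAULT_PALETTE = (
    PaletteBand(0.0, 25.0, hue=2.0 / 3.0),   # blue
    PaletteBand(25.0, 70.0, hue=1.0 / 3.0),  # green
    PaletteBand(70.0, 80.0, hue=1.0 / 6.0),  # yellow
    PaletteBand(80.0, 100.0, hue=0.06),      # red-orange
)


def render_color(dm: DoseMatrix, palette=DEFAULT_PALETTE) -> np.ndarray:
    """Render a dose plane as an 8-bit RGB image through the HSI model.

    Each palette band fixes hue and saturation; within a band the pixel
    intensity scales linearly with dose (dose 0 is black), so band edges
    land exactly where :func:`segment_bands` would put them for the same
    thresholds.  Bands use half-open ``(lo, hi]`` ranges, the lowest band
    closed below.
    """
    bands = sorted(palette, key=lambda b: b.lo)
    for a, b in zip(bands, bands[1:]):
        if b.lo < a.hi:
            raise ValueError("palette dose ranges overlap")
    v = dm.values
    if np.any(v > 100.0 + _DOSE_TOL):
        raise ValueError("dose values above 100 percent cannot be rendered")

    out = np.zeros(v.shape + (3,), dtype=float)
    for k, band in enumerate(bands):
        hsi = np.array([band.hue, band.saturation, 1.0 / 3.0])
        base = hsi_to_rgb(hsi)
        base = base / base.max()  # full-brightness color; scaling keeps H and S
        if k == 0:
            mask = (v >= band.lo) & (v <= band.hi)
        else:
            mask = (v > band.lo) & (v <= band.hi)
        out[mask] = base[None, :] * (v[mask, None] / 100.0)
    return np.clip(_round_half_away(out * 255.0), 0, 255).astype(np.uint8)
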