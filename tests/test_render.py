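"""Grayscale transform, isodose banding, and the HSI color model."""

import numpy as np
import pytest

from isodose import (
    DoseMatrix,
    GridSpec,
    PaletteBand,
    band_contours,
    band_polylines,
    bands_to_gray,
    hsi_matrix_inverse,
    hsi_matrix_transform,
    hsi_to_rgb,
    render_color,
    rgb_to_hsi,
    segment_bands,
    to_gray,
)
from isodose.render import DEFAULT_PALETTE


def make_plane(values):
    values = np.asarray(values, dtype=float)
    grid = GridSpec(
        pixel_spacing=1.0,
        n_lateral=values.shape[1],
        n_depth=values.shape[0],
        lateral_origin=-(values.shape[1] - 1) / 2.0,
        depth_origin=0.5,
    )
    return DoseMatrix(grid=grid, values=values)


class TestToGray:
    def test_endpoints(self):
        dm = make_plane([[100.0, 0.0], [50.0, 20.0]])
        img = to_gray(dm)
        assert img[0, 0] == 255       # maximum dose -> maximum gray tone
        assert img[0, 1] == 0
        assert img[1, 1] == 51        # 0.2 * 255 exactly

    def test_monotone_over_dose_range(self):
        doses = np.arange(0, 100.05, 0.1)
        dm = make_plane(np.tile(doses, (2, 1)))
        img = to_gray(dm)
        assert np.all(np.diff(img[0].astype(int)) >= 0)
        assert img[0, 0] == 0 and img[0, -1] == 255

    def test_rejects_dose_above_100(self):
        grid = GridSpec(pixel_spacing=1.0, n_lateral=2, n_depth=2,
                        lateral_origin=-0.5, depth_origin=0.5)
        dm = DoseMatrix(grid=grid, values=np.full((2, 2), 100.0))
        object.__setattr__(dm, "values", np.full((2, 2), 105.0))  # bypass ctor
        with pytest.raises(ValueError):
            to_gray(dm)


class TestSegmentBands:
    def test_decile_examples(self):
        dm = make_plane([[5.0, 95.0], [10.0, 0.5]])
        bm = segment_bands(dm)
        assert bm.labels[0, 0] == 1     # 1-10 % band
        assert bm.labels[0, 1] == 10    # 91-100 % band
        assert bm.labels[1, 0] == 1     # upper edge inclusive
        assert bm.labels[1, 1] == 0     # below 1 %: background

    def test_rejects_unordered_edges(self):
        dm = make_plane([[5.0, 95.0]] * 2)
        with pytest.raises(ValueError):
            segment_bands(dm, edges=[10, 5, 20])

    def test_histogram_matches_threshold_scan(self):
        rng = np.random.default_rng(7)
        doses = rng.uniform(0, 100, size=(40, 40))
        dm = make_plane(doses)
        bm = segment_bands(dm)
        edges = bm.edges
        # independent per-pixel threshold scan
        expected = np.zeros_like(doses, dtype=int)
        for i in range(40):
            for j in range(40):
                v = doses[i, j]
                if v < edges[0]:
                    continue
                for k in range(1, len(edges)):
                    if v <= edges[k]:
                        expected[i, j] = k
                        break
        np.testing.assert_array_equal(bm.labels, expected)

    def test_partition_conservation(self):
        rng = np.random.default_rng(11)
        dm = make_plane(rng.uniform(0, 100, size=(30, 30)))
        bm = segment_bands(dm)
        counts = np.bincount(bm.labels.ravel(), minlength=bm.n_bands + 1)
        assert counts.sum() == dm.values.size


class TestBandContours:
    def test_uniform_map_has_no_contours(self):
        dm = make_plane(np.full((5, 5), 50.0))
        assert not band_contours(segment_bands(dm)).any()

    def test_two_half_planes_edge(self):
        vals = np.full((6, 6), 5.0)
        vals[:, 3:] = 95.0
        mask = band_contours(segment_bands(make_plane(vals)))
        expected = np.zeros((6, 6), dtype=bool)
        expected[:, 2:4] = True
        np.testing.assert_array_equal(mask, expected)

    def test_disk_contour_matches_neighborhood_scan(self):
        yy, xx = np.mgrid[0:21, 0:21]
        vals = np.where((yy - 10) ** 2 + (xx - 10) ** 2 <= 36, 95.0, 5.0)
        bm = segment_bands(make_plane(vals))
        mask = band_contours(bm)
        lab = bm.labels
        count = 0
        for i in range(21):
            for j in range(21):
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < 21 and 0 <= jj < 21 and lab[ii, jj] != lab[i, j]:
                        count += 1
                        break
        assert mask.sum() == count

    def test_polylines_trace_the_boundary(self):
        vals = np.full((6, 6), 5.0)
        vals[:, 3:] = 95.0
        lines = band_polylines(segment_bands(make_plane(vals)))
        assert len(lines) > 0
        cols = np.concatenate([ln[:, 1] for ln in lines])
        # every traced vertex sits between the two label columns
        assert np.all((cols > 2.0) & (cols < 3.0))

    def test_bands_to_gray_tones(self):
        dm = make_plane(np.full((4, 4), 95.0))
        img = bands_to_gray(segment_bands(dm), draw_contours=False)
        assert img.dtype == np.uint8
        assert len(np.unique(img)) == 1


class TestTriangleHSI:
    def test_achromatic_pins_hue_and_saturation(self):
        h, s, i = rgb_to_hsi([0.5, 0.5, 0.5])
        assert (h, s, i) == (0.0, 0.0, pytest.approx(0.5))

    def test_printed_branch_example(self):
        # B is the smallest channel: H_raw = (G-B)/(3I-3B), S = (I-B)/I
        h, s, i = rgb_to_hsi([1.0, 0.5, 0.0])
        assert i == pytest.approx(0.5)
        assert h * 3.0 == pytest.approx(1.0 / 3.0)
        assert s == pytest.approx(1.0)

    def test_primary_hues_land_in_their_sectors(self):
        for rgb, h_expected in [
            ([1.0, 0.0, 0.0], 0.0),        # red: start of sector 0
            ([1.0, 1.0, 0.0], 1.0 / 6.0),  # yellow: middle of sector 0
            ([0.0, 0.0, 1.0], 2.0 / 3.0),  # blue: start of sector 2... via branch order
        ]:
            h, s, i = rgb_to_hsi(rgb)
            assert h == pytest.approx(h_expected, abs=1e-12)

    def test_round_trip_1000_random_pixels(self):
        rng = np.random.default_rng(42)
        rgb = rng.uniform(0.0, 1.0, size=(1000, 3))
        back = hsi_to_rgb(rgb_to_hsi(rgb))
        assert np.abs(back - rgb).max() < 1e-10

    def test_g_branch_denominator_flag(self):
        rgb = [0.6, 0.1, 0.9]  # G smallest
        h_default = rgb_to_hsi(rgb, g_branch_denominator="g")[0]
        h_printed = rgb_to_hsi(rgb, g_branch_denominator="r")[0]
        assert h_default != h_printed
        # pattern-consistent form keeps raw hue inside sector 2
        assert 2.0 <= h_default * 3.0 < 3.0

    def test_rejects_out_of_range_channels(self):
        with pytest.raises(ValueError):
            rgb_to_hsi([1.2, 0.0, 0.0])


class TestMatrixHSI:
    def test_gray_pixel_has_zero_chroma(self):
        i, v1, v2, h, s = hsi_matrix_transform([0.3, 0.3, 0.3])
        assert abs(v1) < 1e-12 and abs(v2) < 1e-12
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_saturation_is_chroma_radius(self):
        rng = np.random.default_rng(3)
        rgb = rng.uniform(0, 1, (50, 3))
        _, v1, v2, _, s = hsi_matrix_transform(rgb)
        np.testing.assert_allclose(s, np.hypot(v1, v2), atol=1e-12)

    def test_linear_round_trip(self):
        rng = np.random.default_rng(5)
        rgb = rng.uniform(0, 1, (200, 3))
        i, _, _, h, s = hsi_matrix_transform(rgb)
        back = hsi_matrix_inverse(i, h, s)
        assert np.abs(back - rgb).max() < 1e-10


class TestRenderColor:
    def test_band_hues_and_black_zero(self):
        dm = make_plane([[90.0, 10.0], [0.0, 75.0]])
        img = render_color(dm)
        # dose 90: red-orange (R dominant, B = 0); dose 10: blue
        r, g, b = img[0, 0].astype(int)
        assert r > g > b == 0
        assert img[0, 1][2] > 0 and img[0, 1][0] == img[0, 1][1] == 0
        assert tuple(img[1, 0]) == (0, 0, 0)
        # dose 75: yellow (R == G, B = 0)
        assert img[1, 1][0] == img[1, 1][1] > img[1, 1][2] == 0

    def test_band_assignment_matches_threshold_scan(self):
        rng = np.random.default_rng(9)
        # keep doses visible: sub-percent doses quantize to black pixels
        doses = rng.uniform(2, 100, (25, 25))
        dm = make_plane(doses)
        img = render_color(dm)
        band_hues = [band.hue for band in DEFAULT_PALETTE]
        got = np.zeros((25, 25), dtype=int)
        for i in range(25):
            for j in range(25):
                h, s, _ = rgb_to_hsi(img[i, j] / 255.0)
                got[i, j] = int(np.argmin([abs(hh - h) for hh in band_hues]))
        expected = np.zeros((25, 25), dtype=int)
        for k, band in enumerate(DEFAULT_PALETTE):
            if k == 0:
                m = (doses >= band.lo) & (doses <= band.hi)
            else:
                m = (doses > band.lo) & (doses <= band.hi)
            expected[m] = k
        np.testing.assert_array_equal(got, expected)

    def test_intensity_scales_with_dose_within_band(self):
        dm = make_plane([[30.0, 40.0, 50.0, 60.0]] * 2)
        img = render_color(dm).astype(int)
        sums = img[0].sum(axis=1)
        assert np.all(np.diff(sums) > 0)

    def test_rejects_overlapping_palette(self):
        dm = make_plane([[50.0, 60.0]] * 2)
        bad = (PaletteBand(0, 30, 0.5), PaletteBand(20, 100, 0.1))
        with pytest.raises(ValueError):
            render_color(dm, palette=bad)
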