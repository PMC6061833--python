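"""Contour/mask geometry: tracing, rasterisation, resampling, curvature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphodyn.contours import (Outline, contour_to_mask, local_convexity,
                                convexity_arc_elements, mask_to_contour,
                                resample, turning_angles)
from morphodyn.errors import (ComponentCountError, OutlineInvariantError,
                              ParameterError, TooSmallComponentError)


def brute_force_shoelace(nodes):
    x, y = nodes[:, 0], nodes[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestMaskToContour:
    def test_single_pixel_gives_unit_square(self):
        m = np.zeros((10, 10), np.uint8)
        m[5, 5] = 1
        o = mask_to_contour(m)
        assert o.n_nodes == 4
        assert o.area() == pytest.approx(1.0)
        assert np.allclose(o.nodes.mean(axis=0), [5, 5])

    def test_3x3_block_area_matches_brute_force(self):
        m = np.zeros((10, 10), np.uint8)
        m[3:6, 3:6] = 1
        o = mask_to_contour(m)
        assert brute_force_shoelace(o.nodes) == pytest.approx(9.0)
        assert o.area() == pytest.approx(9.0)

    def test_disk_area_close_to_analytic(self, disk_mask):
        o = mask_to_contour(disk_mask)
        assert o.area() == pytest.approx(np.pi * 400, rel=0.02)

    def test_contour_encloses_fg_centers_only(self, finger_mask):
        o = mask_to_contour(finger_mask)
        back = contour_to_mask(o, finger_mask.shape)
        assert np.array_equal(back, finger_mask)

    def test_multiple_components_rejected(self):
        m = np.zeros((10, 10), np.uint8)
        m[1, 1] = m[8, 8] = 1
        with pytest.raises(ComponentCountError):
            mask_to_contour(m)
        with pytest.raises(ComponentCountError):
            mask_to_contour(np.zeros((5, 5), np.uint8))

    def test_two_pixel_component_degenerate(self):
        m = np.zeros((10, 10), np.uint8)
        m[5, 5:7] = 1
        with pytest.raises(TooSmallComponentError):
            mask_to_contour(m)


class TestContourToMask:
    def test_square_contour_pixel_count(self):
        sq = Outline([[2, 2], [8, 2], [8, 8], [2, 8]])
        mask = contour_to_mask(sq, (12, 12))
        # centers 2..8 inclusive in both axes: boundary ties count inside
        assert mask.sum() == 49

    def test_roundtrip_identity_on_disk(self, disk_mask):
        o = mask_to_contour(disk_mask)
        assert np.array_equal(contour_to_mask(o, disk_mask.shape), disk_mask)

    def test_subpixel_triangle_gives_empty_mask(self):
        tri = Outline([[5.1, 5.1], [5.3, 5.1], [5.2, 5.3]])
        assert contour_to_mask(tri, (10, 10)).sum() == 0

    @settings(deadline=None)
    @given(st.integers(0, 1000))
    def test_roundtrip_identity_on_random_blobs(self, seed):
        """mask -> contour -> mask is the identity on 4-connected hole-free
        masks (smoothed thresholded noise, largest component, holes filled)."""
        from scipy import ndimage
        rng = np.random.default_rng(seed)
        img = ndimage.gaussian_filter(rng.normal(size=(40, 40)), 4)
        m = img > np.percentile(img, 70)
        lab, n = ndimage.label(m, structure=np.array([[0, 1, 0], [1, 1, 1],
                                                      [0, 1, 0]]))
        if n == 0:
            return
        sizes = ndimage.sum(m, lab, range(1, n + 1))
        m = ndimage.binary_fill_holes(lab == 1 + int(np.argmax(sizes)))
        if m.sum() < 3:
            return
        o = mask_to_contour(m.astype(np.uint8))
        assert np.array_equal(contour_to_mask(o, m.shape), m.astype(np.uint8))


class TestOutlineInvariants:
    def test_orientation_normalised_to_ccw(self):
        cw = Outline([[0, 0], [0, 5], [5, 5], [5, 0]])  # given clockwise
        assert cw.area() > 0

    def test_duplicate_nodes_rejected(self):
        with pytest.raises(OutlineInvariantError):
            Outline([[0, 0], [0, 0], [5, 5], [5, 0]])

    def test_self_intersection_rejected(self):
        with pytest.raises(OutlineInvariantError):
            Outline([[0, 0], [5, 5], [5, 0], [0, 5]])


class TestResample:
    def test_unit_square_to_its_corners(self):
        sq = Outline([[0, 0], [1, 0], [1, 1], [0, 1]])
        r = resample(sq, 4)
        assert np.allclose(r.nodes, sq.nodes)

    def test_circle_equal_spacing(self):
        c = Outline.circle(25, 25, 10, 360)
        r = resample(c, 36)
        sp = r.edge_lengths()
        assert (sp.max() - sp.min()) / sp.mean() < 1e-6

    def test_perimeter_and_area_preserved_upsampling(self, circle):
        r = resample(circle, 256)
        assert r.perimeter() == pytest.approx(circle.perimeter(), rel=1e-3)
        assert r.area() == pytest.approx(circle.area(), rel=1e-2)

    def test_attribute_mass_conserved(self, circle):
        rng = np.random.default_rng(0)
        c = circle.copy()
        c.attrs["fluor"] = 10 + rng.random(c.n_nodes)

        def mass(o):
            el = o.edge_lengths()
            ds = 0.5 * (el + np.roll(el, 1))
            return float(np.sum(o.attrs["fluor"] * ds))

        r = resample(c, 200)
        assert mass(r) == pytest.approx(mass(c), rel=1e-2)

    def test_too_few_nodes_rejected(self, circle):
        with pytest.raises(ParameterError):
            resample(circle, 2)


class TestLocalConvexity:
    def test_circle_curvature_is_one_over_r(self):
        for r in (5.0, 10.0, 25.0):
            c = Outline.circle(0, 0, r, 128)
            k = local_convexity(c, window_px=4.0)
            assert np.allclose(k, 1.0 / r, rtol=2e-3)

    def test_rectangle_sides_are_flat(self):
        n = 20
        xs = np.linspace(0, 40, n)
        top = np.column_stack([xs, np.zeros(n)])
        bot = np.column_stack([xs[::-1], np.full(n, 5.0)])
        rect = Outline(np.vstack([top, [[40.5, 2.5]], bot, [[-0.5, 2.5]]]))
        k = local_convexity(rect, window_px=2.0)
        mid = k[5:n - 5]          # interior of the long straight side
        assert np.abs(mid).max() < 1e-9

    def test_dent_is_negative_with_positive_shoulders(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        r = 20 - 6 * np.exp(-((th - np.pi) / 0.25) ** 2)   # concave dent
        o = Outline(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        k = local_convexity(o, window_px=2.0)
        dent = np.abs(th - np.pi) < 0.1
        shoulder = (np.abs(th - np.pi) > 0.25) & (np.abs(th - np.pi) < 0.4)
        assert k[dent].max() < 0
        assert k[shoulder].min() > 0

    def test_window_larger_than_perimeter_degenerates_to_global(self, circle):
        k = local_convexity(circle, window_px=1e6)
        assert np.allclose(k, 2 * np.pi / circle.perimeter())

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_turning_integral_is_2pi(self, seed):
        """Windowed curvature integrates to +2pi over any simple CCW polygon
        (total turning), to floating-point accuracy on uniform resampling."""
        rng = np.random.default_rng(seed)
        th = np.sort(rng.uniform(0, 2 * np.pi, 30))
        if np.min(np.diff(th)) < 1e-3:
            return
        r = rng.uniform(5, 15, 30)
        o = resample(Outline(np.column_stack([r * np.cos(th), r * np.sin(th)])), 100)
        k = local_convexity(o, window_px=3.0)
        total = float(np.sum(k * convexity_arc_elements(o)))
        assert total == pytest.approx(2 * np.pi, abs=1e-6)
        assert float(turning_angles(o).sum()) == pytest.approx(2 * np.pi, abs=1e-9)

    def test_values_stable_under_node_density(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        r = 20 + 3 * np.cos(3 * th)
        o = Outline(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        k1 = local_convexity(resample(o, 100), window_px=6.0)
        k2 = local_convexity(resample(o, 200), window_px=6.0)[::2]
        scale = np.abs(k1).max()
        assert np.abs(k1 - k2).max() / scale < 0.05
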