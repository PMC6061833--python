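"""Cortical sampling, spatio-temporal maps, per-frame statistics."""

import numpy as np
import pytest

from morphodyn.contours import (Outline, contour_to_mask,
                                convexity_arc_elements, resample)
from morphodyn.cortex import build_maps, per_frame_stats, sample_cortex
from morphodyn.synthetic import MovieParams, generate_cell_movie


class TestSampleCortex:
    def test_uniform_image_gives_constant(self):
        o = Outline.circle(50, 50, 30, 120)
        cs = sample_cortex(np.full((100, 100), 7.0), o, 6.0)
        assert np.allclose(cs.values, 7.0)

    def test_membrane_band_recovered(self):
        yy, xx = np.mgrid[0:100, 0:100]
        r = np.hypot(xx - 50, yy - 50)
        img = np.where((r >= 20) & (r <= 32), 100.0, 0.0)
        o = Outline.circle(50, 50, 30, 120)
        cs = sample_cortex(img, o, 6.0)
        assert np.all(np.abs(cs.values - 100.0) <= 2.0)

    def test_locality_half_plane(self):
        yy, xx = np.mgrid[0:100, 0:100]
        img = np.where(xx < 50, 50.0, 0.0)
        o = Outline.circle(50, 50, 30, 120)
        cs = sample_cortex(img, o, 6.0)
        th = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        assert cs.values[np.cos(th) > 0.3].max() < 5.0
        assert cs.values[np.cos(th) < -0.3].min() > 45.0

    def test_total_signal_matches_band_integral(self):
        o = Outline.circle(50, 50, 30, 150)
        img = np.full((100, 100), 13.0)
        cs = sample_cortex(img, o, 6.0)
        analytic = 13.0 * np.pi * (30 ** 2 - 24 ** 2)
        assert cs.total_signal == pytest.approx(analytic, rel=0.03)

    def test_thin_cell_band_truncated_and_flagged(self):
        # 8-px-thick bar, cortex width 8 -> band must stop at the midline
        bar = Outline([[10, 20], [70, 20], [70, 28], [10, 28]])
        img = np.full((50, 90), 10.0)
        cs = sample_cortex(img, bar, 8.0)
        assert cs.truncated.any()
        assert np.allclose(cs.values, 10.0)


class TestBuildMaps:
    def test_static_cell_maps(self):
        yy, xx = np.mgrid[0:100, 0:100]
        img = np.where(np.hypot(xx - 50, yy - 50) <= 22, 80.0, 0.0)
        track = [Outline.circle(50, 50, 20, 120, frame_index=t) for t in range(5)]
        stack = np.tile(img, (5, 1, 1))
        ms = build_maps(track, None, stack, cortex_width_px=4.0, R=60)
        assert np.nanmax(np.abs(ms.motility.values)) < 1e-6
        assert np.allclose(ms.fluorescence.values, ms.fluorescence.values[0])
        assert np.allclose(ms.convexity.values, 1 / 20.0, rtol=5e-3)

    def test_expanding_circle_motility(self):
        track = [Outline.circle(50, 50, 20 + 2 * t, 150, frame_index=t)
                 for t in range(4)]
        ms = build_maps(track, None, None, R=90)
        assert np.all(np.abs(ms.motility.values - 2.0) <= 0.1)

    def test_convexity_rows_integrate_to_2pi(self):
        p = MovieParams(frames=3, protrusion_amp=0.3, noise_sigma=0.0)
        mv = generate_cell_movie(p, seed=2)
        ms = build_maps(mv.outlines, None, None, R=120)
        for t, rs in enumerate(ms.outlines):
            total = np.sum(ms.convexity.values[t] * convexity_arc_elements(rs))
            assert total == pytest.approx(2 * np.pi, abs=1e-6)

    def test_motility_sum_tracks_area_change(self):
        """Column sum of motility times arc element approximates dA/dt."""
        p = MovieParams(frames=8, protrusion_amp=0.2, rotation_deg_per_frame=2.0,
                        radius_growth_px_per_frame=1.0, base_radius=25.0,
                        noise_sigma=0.0)
        mv = generate_cell_movie(p, seed=5)
        ms = build_maps(mv.outlines, None, None, R=120)
        for t in range(7):
            arc = ms.outlines[t].perimeter() / 120
            s = np.nansum(ms.motility.values[t]) * arc
            dA = mv.outlines[t + 1].area() - mv.outlines[t].area()
            assert s == pytest.approx(dA, rel=0.1)

    def test_registration_pins_rotating_material_patch(self):
        """A fluorescent patch fixed to boundary material of a rotating cell
        stays in a fixed column band with ECMM origin registration, and
        drifts by the full rotation without it."""
        R = 90
        p = MovieParams(frames=20, rotation_deg_per_frame=2.0,
                        protrusion_amp=0.4, bump_width_rad=0.25,
                        noise_sigma=0.0, interior_intensity=50.0)
        mv = generate_cell_movie(p, seed=3)
        th = np.linspace(0, 2 * np.pi, p.n_boundary_nodes, endpoint=False)
        rr, cc = np.ogrid[0:p.size[0], 0:p.size[1]]
        stack = []
        for t in range(p.frames):
            o = mv.outlines[t]
            img = np.full(p.size, 10.0)
            img[contour_to_mask(o, p.size).astype(bool)] = 50.0
            rot = np.deg2rad(p.rotation_deg_per_frame) * t
            sel = ((th - rot) % (2 * np.pi)) <= 0.6   # material-fixed patch
            for x, y in o.nodes[sel][::4]:
                img[(cc - x) ** 2 + (rr - y) ** 2 <= 9] = 200.0
            stack.append(img)
        stack = np.asarray(stack)
        ms = build_maps(mv.outlines, None, stack, cortex_width_px=4.0, R=R)

        def max_drift(F):
            cols = [int(np.argmax(F[t])) for t in range(p.frames)]
            return max(abs((c - cols[0] + R // 2) % R - R // 2) for c in cols)

        assert max_drift(ms.fluorescence.values) < 2
        unreg = np.stack([sample_cortex(stack[t],
                                        resample(mv.outlines[t], R), 4.0).values
                          for t in range(p.frames)])
        assert max_drift(unreg) > 5


class TestPerFrameStats:
    def test_circle_circularity_and_area(self):
        df = per_frame_stats([Outline.circle(0, 0, 10, 200)])
        assert df.circularity[0] == pytest.approx(1.0, abs=0.02)
        assert df.area[0] == pytest.approx(np.pi * 100, rel=0.02)

    def test_square_circularity(self):
        sq = Outline([[0, 0], [5, 0], [5, 5], [0, 5]])
        assert per_frame_stats([sq]).circularity[0] == pytest.approx(np.pi / 4,
                                                                     abs=0.02)

    def test_static_cell_zero_motion(self):
        track = [Outline.circle(10, 10, 5, 60, frame_index=t) for t in range(4)]
        df = per_frame_stats(track)
        assert np.allclose(df.displacement, 0.0)
        assert np.allclose(df.distance_traveled, 0.0)
        assert np.allclose(df.speed, 0.0)

    def test_motion_accumulates(self):
        track = [Outline.circle(10 + 3 * t, 10, 5, 60, frame_index=t)
                 for t in range(4)]
        df = per_frame_stats(track)
        assert df.displacement.iloc[-1] == pytest.approx(9.0, abs=0.05)
        assert df.distance_traveled.iloc[-1] == pytest.approx(9.0, abs=0.05)
        assert df.speed.iloc[1] == pytest.approx(3.0, abs=0.05)
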