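"""Random-walker segmentation: Dirichlet solver, weights, gradient claim."""

import numpy as np
import pytest

from morphodyn.errors import SeedError
from morphodyn.metrics import dice
from morphodyn.randomwalk import (RwParams, dirichlet_residual, edge_weights,
                                  segment_rw, solve_random_walk)
from morphodyn.seeding import SeedLabels, seeds_from_mask


def chain_seeds(n=5):
    fg = np.zeros((1, n), bool)
    bg = np.zeros((1, n), bool)
    fg[0, 0] = True
    bg[0, -1] = True
    return SeedLabels(fg, bg)


class TestSolver:
    def test_five_pixel_chain_matches_hand_solution(self):
        """Uniform weights, ends seeded 1/0: interior is the harmonic ramp
        {0.75, 0.5, 0.25} (solved by hand from the 3x3 system)."""
        p = solve_random_walk(np.zeros((1, 5)), chain_seeds())
        assert np.allclose(p[0], [1.0, 0.75, 0.5, 0.25, 0.0], atol=1e-10)

    def test_all_pixels_seeded_returns_labels(self):
        fg = np.zeros((2, 2), bool)
        fg[0] = True
        seeds = SeedLabels(fg, ~fg)
        p = solve_random_walk(np.zeros((2, 2)), seeds)
        assert np.array_equal(p, fg.astype(float))

    def test_maximum_principle(self, bright_disk):
        # moderate beta keeps all weights far from underflow, so the strict
        # inequality of the discrete maximum principle is numerically visible
        seeds = seeds_from_mask((bright_disk > 100).astype(np.uint8), 5, 5)
        p = solve_random_walk(bright_disk, seeds, RwParams(beta=5.0))
        un = ~(seeds.foreground | seeds.background)
        assert np.all(p[un] > 0.0)
        assert np.all(p[un] < 1.0)

    def test_residual_below_tolerance(self, bright_disk):
        rng = np.random.default_rng(0)
        img = bright_disk + rng.normal(0, 5, bright_disk.shape)
        seeds = seeds_from_mask((bright_disk > 100).astype(np.uint8), 6, 6)
        for adaptive in (True, False):
            params = RwParams(adaptive=adaptive)
            p = solve_random_walk(img, seeds, params)
            assert dirichlet_residual(img, seeds, p, params) < 1e-8

    def test_symmetric_problem_gives_symmetric_field(self):
        yy, xx = np.mgrid[0:40, 0:40]
        img = np.where((xx - 19.5) ** 2 + (yy - 19.5) ** 2 <= 100, 200.0, 10.0)
        fg = (xx - 19.5) ** 2 + (yy - 19.5) ** 2 <= 16
        bg = (xx < 3) | (xx > 36) | (yy < 3) | (yy > 36)
        p = solve_random_walk(img, SeedLabels(fg, bg))
        assert np.abs(p - p[::-1, :]).max() < 1e-8
        assert np.abs(p - p[:, ::-1]).max() < 1e-8

    def test_affine_intensity_invariance_adaptive(self, bright_disk):
        rng = np.random.default_rng(1)
        img = bright_disk + rng.normal(0, 5, bright_disk.shape)
        seeds = seeds_from_mask((bright_disk > 100).astype(np.uint8), 6, 6)
        p1 = solve_random_walk(img, seeds, RwParams(adaptive=True))
        p2 = solve_random_walk(3.7 * img + 11.0, seeds, RwParams(adaptive=True))
        assert np.abs(p1 - p2).max() < 1e-6


class TestWeights:
    def test_flat_image_all_weights_one(self):
        wh, wv = edge_weights(np.full((8, 8), 3.0), RwParams())
        assert np.all(wh == 1.0)
        assert np.all(wv == 1.0)

    def test_two_level_plugin_value(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        p = RwParams(beta=90.0, adaptive=False)
        wh, wv = edge_weights(img, p)
        # boundary differences equal the robust range -> weight exp(-90)
        assert np.allclose(wh[:, 4], np.exp(-90.0))
        assert np.allclose(wv, 1.0)

    def test_adaptive_equalises_varying_gradient(self):
        """On a ramp whose slope varies smoothly, adaptive weights are
        near-uniform along the ramp while global-normalised ones are not."""
        x = np.arange(80, dtype=float)
        img = np.tile((x ** 2) / 40.0, (40, 1))
        pa = RwParams(adaptive=True)
        pn = RwParams(adaptive=False)
        wh_a, _ = edge_weights(img, pa)
        wh_n, _ = edge_weights(img, pn)
        interior = slice(10, -10)
        cv = lambda w: np.std(w[:, interior]) / np.mean(w[:, interior])
        assert cv(wh_a) < 0.2 * cv(wh_n)

    def test_weights_in_unit_interval(self, bright_disk):
        for adaptive in (True, False):
            wh, wv = edge_weights(bright_disk, RwParams(adaptive=adaptive))
            for w in (wh, wv):
                assert np.all(w > 0.0)
                assert np.all(w <= 1.0)


class TestSegmentRw:
    def test_noisy_disk_dice(self):
        yy, xx = np.mgrid[0:100, 0:100]
        truth = (xx - 50) ** 2 + (yy - 50) ** 2 <= 30 ** 2
        rng = np.random.default_rng(0)
        img = np.where(truth, 200.0, 10.0) + rng.normal(0, 5, truth.shape)
        seeds = seeds_from_mask(truth.astype(np.uint8), 8, 10)
        mask = segment_rw(img, seeds, RwParams())
        assert dice(mask, truth) >= 0.98

    def test_gradient_disk_adaptive_beats_plain(self):
        """Polarised cell (intensity halving across the cell, shot noise):
        the locally adaptive weights strictly beat global normalisation at
        the same beta."""
        yy, xx = np.mgrid[0:100, 0:100]
        truth = (xx - 50) ** 2 + (yy - 50) ** 2 <= 30 ** 2
        base = np.where(truth, 200.0 - (200.0 - 40.0) * (xx - 20) / 60.0, 10.0)
        rng = np.random.default_rng(0)
        img = rng.poisson(base / 8.0) * 8.0 + rng.normal(0, 2, base.shape)
        seeds = seeds_from_mask(truth.astype(np.uint8), 8, 10)
        d_ad = dice(segment_rw(img, seeds, RwParams(adaptive=True)), truth)
        d_pl = dice(segment_rw(img, seeds, RwParams(adaptive=False)), truth)
        assert d_ad > d_pl

    def test_output_contains_every_foreground_seed(self, bright_disk):
        seeds = seeds_from_mask((bright_disk > 100).astype(np.uint8), 8, 8)
        mask = segment_rw(bright_disk, seeds)
        assert np.all(mask[seeds.foreground] > 0)

    def test_idempotent_under_reseeding_noiseless(self, bright_disk):
        truth = (bright_disk > 100).astype(np.uint8)
        seeds = seeds_from_mask(truth, 6, 6)
        m1 = segment_rw(bright_disk, seeds)
        seeds2 = seeds_from_mask(m1, 6, 6)
        m2 = segment_rw(bright_disk, seeds2)
        assert np.array_equal(m1, m2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(SeedError):
            solve_random_walk(np.zeros((4, 4)), chain_seeds())
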