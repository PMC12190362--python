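"""Point projection, warp-and-merge, overlap, and alignment metrics."""

import numpy as np
import pytest

from fundusmosaic.errors import FundusMosaicError, InputError
from fundusmosaic.image_io import GrayImage
from fundusmosaic.mosaic import (alignment_metrics, overlap_percentage,
                                 project_points, warp_and_merge)


class TestProjectPoints:
    def test_identity(self, rng):
        pts = rng.uniform(0, 700, size=(10, 2))
        assert np.allclose(project_points(np.eye(3), pts), pts)

    def test_pure_translation(self, rng):
        H = np.eye(3); H[0, 2], H[1, 2] = 5.0, -3.0
        pts = rng.uniform(0, 700, size=(10, 2))
        assert np.allclose(project_points(H, pts), pts + [5.0, -3.0])

    def test_matches_scalar_loop(self, rng):
        H = np.array([[1.1, 0.02, 12.0], [-0.03, 0.95, -4.0], [1e-4, -2e-4, 1.0]])
        pts = rng.uniform(0, 700, size=(50, 2))
        out = project_points(H, pts)
        for i, (x, y) in enumerate(pts):
            v = H @ np.array([x, y, 1.0])
            assert out[i, 0] == pytest.approx(v[0] / v[2], abs=1e-12)
            assert out[i, 1] == pytest.approx(v[1] / v[2], abs=1e-12)

    def test_point_at_infinity_flagged(self):
        H = np.eye(3); H[2, 0] = -1.0 / 100.0  # w = 0 at x = 100
        with pytest.raises(FundusMosaicError, match="infinity"):
            project_points(H, np.array([[100.0, 5.0]]))


class TestOverlapPercentage:
    def test_identity_full_overlap(self):
        assert overlap_percentage(np.eye(3), (768, 768), (768, 768)) == 1.0

    def test_half_shift(self):
        H = np.eye(3); H[0, 2] = 384.0
        got = overlap_percentage(H, (768, 768), (768, 768))
        assert got == pytest.approx(0.5, abs=2 / 768)

    def test_disjoint_footprint(self):
        H = np.eye(3); H[0, 2] = 2000.0
        assert overlap_percentage(H, (768, 768), (768, 768)) == 0.0

    def test_pixel_count_oracle_on_rotation(self):
        # brute-force oracle: classify every reference pixel by its preimage
        theta = np.deg2rad(10)
        H = np.array([[np.cos(theta), -np.sin(theta), 100.0],
                      [np.sin(theta), np.cos(theta), -50.0], [0, 0, 1.0]])
        got = overlap_percentage(H, (128, 96), (96, 128))
        Minv = np.linalg.inv(H)
        count = 0
        for y in range(128):
            for x in range(96):
                v = Minv @ np.array([x, y, 1.0])
                xm, ym = v[0] / v[2], v[1] / v[2]
                if -0.5 <= xm <= 127.5 and -0.5 <= ym <= 95.5:
                    count += 1
        assert got == pytest.approx(count / (96 * 128), abs=1e-12)


class TestWarpAndMerge:
    def test_self_mosaic_identity(self, rng):
        img = GrayImage(rng.random((96, 96)))
        res = warp_and_merge(img, img, np.eye(3))
        assert res.overlap_fraction == 1.0
        assert res.canvas.pixels.shape == (96, 96)
        assert np.allclose(res.canvas.pixels, img.pixels, atol=1e-6)

    def test_full_width_translation_doubles_canvas(self, rng):
        img = GrayImage(rng.random((64, 64)))
        H = np.eye(3); H[0, 2] = 64.0
        res = warp_and_merge(img, img, H)
        assert res.overlap_fraction == 0.0
        assert res.canvas.pixels.shape[1] == 128

    def test_degenerate_h_rejected(self, rng):
        from fundusmosaic.errors import ParameterError, RegistrationFailure
        img = GrayImage(rng.random((64, 64)))
        H = np.eye(3); H[0, 0] = 1e-9; H[1, 1] = 1e-9
        with pytest.raises((RegistrationFailure, ParameterError)):
            warp_and_merge(img, img, H)

    def test_mosaic_recovers_master_scene(self, small_scene, default_pair):
        pair = default_pair
        res = warp_and_merge(pair.macula_image, pair.onh_image, pair.true_homography)
        # overlap region of the mosaic should match the macula view closely
        hm, wm = pair.macula_image.pixels.shape
        ry, rx = int(-res.offset[1]), int(-res.offset[0])
        mosaic_ref_region = res.canvas.pixels[ry:ry + hm, rx:rx + wm]
        overlap = overlap_percentage(pair.true_homography, (hm, wm), (hm, wm))
        assert overlap > 0.3
        diff = np.abs(mosaic_ref_region - pair.macula_image.pixels).mean()
        assert diff < 0.05


class TestAlignmentMetrics:
    def test_identical_points_zero(self, rng):
        pts = rng.uniform(0, 700, size=(20, 2))
        m = alignment_metrics(pts, pts)
        assert m.d_mean == 0 and m.rms_mean == 0 and m.rms_max == 0

    def test_three_four_five_triangle(self):
        m = alignment_metrics(np.array([[10.0, 10.0]]), np.array([[13.0, 14.0]]))
        assert (m.delta_x_mean, m.delta_y_mean, m.d_mean) == (3.0, 4.0, 5.0)
        assert m.rms_mean == 5.0 and m.rms_max == 5.0 and m.rms_pooled == 5.0

    def test_matches_scalar_loop(self, rng):
        a = rng.uniform(0, 700, size=(100, 2))
        b = a + rng.normal(0, 2, size=(100, 2))
        m = alignment_metrics(a, b)
        dx = [abs(p[0] - q[0]) for p, q in zip(a, b)]
        dy = [abs(p[1] - q[1]) for p, q in zip(a, b)]
        d = [np.hypot(x, y) for x, y in zip(dx, dy)]
        assert m.delta_x_mean == pytest.approx(np.mean(dx), abs=1e-12)
        assert m.delta_y_mean == pytest.approx(np.mean(dy), abs=1e-12)
        assert m.d_mean == pytest.approx(np.mean(d), abs=1e-12)
        assert m.rms_sd == pytest.approx(np.std(d), abs=1e-12)
        assert m.rms_max == pytest.approx(np.max(d), abs=1e-12)
        assert m.rms_pooled == pytest.approx(np.sqrt(np.mean(np.square(d))), abs=1e-12)

    def test_metric_inequalities(self, rng):
        a = rng.uniform(0, 700, size=(50, 2))
        b = a + rng.normal(0, 3, size=(50, 2))
        m = alignment_metrics(a, b)
        assert m.d_mean <= m.delta_x_mean + m.delta_y_mean + 1e-12
        assert m.d_mean >= max(m.delta_x_mean, m.delta_y_mean) - 1e-12
        assert m.rms_pooled >= m.d_mean - 1e-9

    def test_count_mismatch(self, rng):
        with pytest.raises(InputError):
            alignment_metrics(rng.random((5, 2)), rng.random((4, 2)))
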