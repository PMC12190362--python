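"""Block descriptors, SSD matching, and MSAC homography estimation."""

import numpy as np
import pytest

from fundusmosaic.errors import ParameterError, RegistrationFailure
from fundusmosaic.matching import (MatchSet, estimate_homography_msac,
                                   extract_block_descriptors, match_descriptors,
                                   msac_cost, refine_homography)
from fundusmosaic.vessel_segmentation import SkeletonPoints


def _apply(H, pts):
    h = np.hstack([pts, np.ones((len(pts), 1))]) @ np.asarray(H, float).T
    return h[:, :2] / h[:, 2:3]


def _random_unit(rng, n, d=529):
    v = rng.standard_normal((n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestDescriptors:
    def test_boundary_arithmetic(self, rng):
        V = rng.random((768, 768))
        pts = SkeletonPoints(points=np.array([[11, 11], [10, 11], [756, 756], [757, 400]]))
        ds = extract_block_descriptors(V, pts, block_size=23)
        assert len(ds) == 2
        assert [11, 11] in ds.valid_points.astype(int).tolist()
        assert [756, 756] in ds.valid_points.astype(int).tolist()

    def test_constant_block_uniform_unit_vector(self):
        V = np.full((64, 64), 0.3)
        ds = extract_block_descriptors(V, np.array([[32, 32]]), block_size=23)
        assert np.allclose(ds.features[0], 1.0 / 23.0, atol=1e-12)
        assert np.linalg.norm(ds.features[0]) == pytest.approx(1.0, abs=1e-12)

    def test_count_matches_direct_oracle(self, rng):
        V = rng.random((200, 200))
        pts = rng.integers(0, 200, size=(500, 2))
        ds = extract_block_descriptors(V, pts, block_size=23)
        expected = int(np.sum((pts[:, 0] >= 11) & (pts[:, 0] <= 188)
                              & (pts[:, 1] >= 11) & (pts[:, 1] <= 188)))
        assert len(ds) == expected

    def test_all_rows_unit_norm(self, rng):
        V = rng.random((100, 100))
        ds = extract_block_descriptors(V, rng.integers(12, 88, size=(50, 2)))
        assert np.allclose(np.linalg.norm(ds.features, axis=1), 1.0, atol=1e-12)


class TestMatching:
    def test_identical_sets_match_with_zero_ssd(self, rng):
        from fundusmosaic.matching import DescriptorSet
        f = _random_unit(rng, 30)
        ds = DescriptorSet(f, rng.random((30, 2)))
        ms = match_descriptors(ds, ds)
        assert len(ms) == 30
        assert np.allclose(ms.distances, 0.0, atol=1e-9)
        assert np.array_equal(ms.pairs[:, 0], ms.pairs[:, 1])

    def test_orthogonal_vectors_do_not_match(self):
        from fundusmosaic.matching import DescriptorSet
        f1 = np.zeros((1, 529)); f1[0, 0] = 1.0
        f2 = np.zeros((1, 529)); f2[0, 1] = 1.0
        ms = match_descriptors(DescriptorSet(f1, np.zeros((1, 2))),
                               DescriptorSet(f2, np.zeros((1, 2))), th2=1.0)
        assert len(ms) == 0

    def test_ssd_unit_norm_identity(self, rng):
        u = _random_unit(rng, 20)
        v = _random_unit(rng, 20)
        ssd = np.sum((u[:, None, :] - v[None, :, :]) ** 2, axis=2)
        cos = u @ v.T
        assert np.allclose(ssd, 2 - 2 * cos, atol=1e-12)

    def test_planted_correspondences_recovered(self, rng):
        from fundusmosaic.matching import DescriptorSet
        base = _random_unit(rng, 40)
        noisy = base + 0.1 * rng.standard_normal(base.shape)
        noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
        distract = _random_unit(rng, 60)
        proj = np.vstack([noisy, distract])
        ms = match_descriptors(DescriptorSet(base, np.zeros((40, 2))),
                               DescriptorSet(proj, np.zeros((100, 2))), th2=0.5)
        # brute-force oracle: nearest neighbour of each base row
        ssd_full = 2 - 2 * base @ proj.T
        expected = {(i, int(np.argmin(ssd_full[i]))) for i in range(40)
                    if ssd_full[i].min() < 0.5}
        assert {tuple(p) for p in ms.pairs.tolist()} == expected

    def test_one_to_one(self, rng):
        from fundusmosaic.matching import DescriptorSet
        f = _random_unit(rng, 50)
        ms = match_descriptors(DescriptorSet(f, np.zeros((50, 2))),
                               DescriptorSet(f[:25], np.zeros((25, 2))), th2=1.5)
        assert len(np.unique(ms.pairs[:, 0])) == len(ms)
        assert len(np.unique(ms.pairs[:, 1])) == len(ms)


def _make_matchset(n):
    return MatchSet(pairs=np.column_stack([np.arange(n), np.arange(n)]),
                    distances=np.zeros(n))


class TestMsac:
    H_TRUE = np.array([[1.02 * np.cos(0.05), -1.02 * np.sin(0.05), 30.0],
                       [1.02 * np.sin(0.05), 1.02 * np.cos(0.05), -12.0],
                       [0.0, 0.0, 1.0]])

    def test_noiseless_exact_recovery(self, rng):
        src = rng.uniform(0, 700, size=(20, 2))
        dst = _apply(self.H_TRUE, src)
        H = estimate_homography_msac(_make_matchset(20), dst, src, seed=3)
        corners = np.array([[0, 0], [767, 0], [767, 767], [0, 767]], float)
        err = np.abs(_apply(H.H, corners) - _apply(self.H_TRUE, corners)).max()
        assert err < 1e-3
        assert H.inlier_indices.size == 20

    def test_outlier_rejection_over_seeds(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            src_in = r.uniform(50, 700, size=(50, 2))
            dst_in = _apply(self.H_TRUE, src_in) + r.normal(0, 0.5, size=(50, 2))
            src_out = r.uniform(0, 767, size=(50, 2))
            dst_out = r.uniform(0, 767, size=(50, 2))
            src = np.vstack([src_in, src_out])
            dst = np.vstack([dst_in, dst_out])
            H = estimate_homography_msac(_make_matchset(100), dst, src, seed=seed)
            inl = set(H.inlier_indices.tolist())
            corners = np.array([[0, 0], [767, 0], [767, 767], [0, 767]], float)
            err = np.abs(_apply(H.H, corners) - _apply(self.H_TRUE, corners)).max()
            n_true = len(inl & set(range(50)))
            n_false = len(inl & set(range(50, 100)))
            if n_true >= 45 and n_false == 0 and err < 1.0:
                hits += 1
        assert hits >= 18  # allow occasional borderline draws

    def test_fewer_than_four_matches_fails(self, rng):
        with pytest.raises(RegistrationFailure):
            estimate_homography_msac(_make_matchset(3), rng.random((3, 2)),
                                     rng.random((3, 2)))

    def test_returned_cost_beats_truth_on_noiseless_data(self, rng):
        src = rng.uniform(0, 700, size=(30, 2))
        dst = _apply(self.H_TRUE, src)
        H = estimate_homography_msac(_make_matchset(30), dst, src, seed=0)
        assert msac_cost(H.H, src, dst) <= msac_cost(self.H_TRUE, src, dst) + 1e-6

    def test_deterministic_under_seed(self, rng):
        src = rng.uniform(0, 700, size=(60, 2))
        dst = _apply(self.H_TRUE, src) + rng.normal(0, 0.3, size=(60, 2))
        h1 = estimate_homography_msac(_make_matchset(60), dst, src, seed=11)
        h2 = estimate_homography_msac(_make_matchset(60), dst, src, seed=11)
        assert np.array_equal(h1.H, h2.H)

    def test_agrees_with_skimage_ransac_oracle(self, rng):
        from skimage.measure import ransac
        from skimage.transform import ProjectiveTransform
        src_in = rng.uniform(50, 700, size=(60, 2))
        dst_in = _apply(self.H_TRUE, src_in) + rng.normal(0, 0.4, size=(60, 2))
        src_out = rng.uniform(0, 767, size=(20, 2))
        dst_out = rng.uniform(0, 767, size=(20, 2))
        src = np.vstack([src_in, src_out]); dst = np.vstack([dst_in, dst_out])
        ours = estimate_homography_msac(_make_matchset(80), dst, src, seed=5)
        model, _ = ransac((src, dst), ProjectiveTransform, min_samples=4,
                          residual_threshold=4.5, max_trials=2000,
                          rng=np.random.default_rng(5))
        corners = np.array([[0, 0], [767, 0], [767, 767], [0, 767]], float)
        diff = np.abs(_apply(ours.H, corners) - model(corners)).max()
        assert diff < 1.0


class TestRefine:
    def test_exact_inliers_reproduce_h(self, rng):
        H_true = TestMsac.H_TRUE
        src = rng.uniform(0, 700, size=(12, 2))
        dst = _apply(H_true, src)
        H = refine_homography(dst, src)
        assert np.allclose(H.H, H_true / H_true[2, 2], rtol=1e-6, atol=1e-6)

    def test_duplicated_point_is_noop(self, rng):
        H_true = TestMsac.H_TRUE
        src = rng.uniform(0, 700, size=(10, 2))
        dst = _apply(H_true, src) + rng.normal(0, 0.2, size=(10, 2))
        base = refine_homography(dst, src)
        dup = refine_homography(np.vstack([dst, dst[:1]]), np.vstack([src, src[:1]]))
        corners = np.array([[0, 0], [767, 0], [767, 767], [0, 767]], float)
        assert np.abs(_apply(base.H, corners) - _apply(dup.H, corners)).max() < 0.3

    def test_ls_refit_no_worse_than_minimal_sample(self, rng):
        H_true = TestMsac.H_TRUE
        for trial in range(20):
            r = np.random.default_rng(trial)
            src = r.uniform(0, 700, size=(25, 2))
            dst = _apply(H_true, src) + r.normal(0, 0.6, size=(25, 2))
            refit = refine_homography(dst, src)
            minimal = refine_homography(dst[:4], src[:4])
            rms_refit = np.sqrt(np.mean(np.sum((_apply(refit.H, src) - dst) ** 2, axis=1)))
            rms_min = np.sqrt(np.mean(np.sum((_apply(minimal.H, src) - dst) ** 2, axis=1)))
            assert rms_refit <= rms_min + 1e-9

    def test_too_few_inliers(self, rng):
        with pytest.raises(RegistrationFailure):
            refine_homography(rng.random((3, 2)), rng.random((3, 2)))
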