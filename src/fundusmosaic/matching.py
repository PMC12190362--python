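"""Block descriptors at skeleton points, SSD matching, MSAC homography.

Descriptors are the raw 23x23 vesselness blocks around each skeleton
point (only blocks fully inside the image), flattened row-major and
scaled to unit Euclidean norm.  Matching is exhaustive SSD between unit
vectors — SSD(u, v) = 2 - 2<u, v> — thresholded at th2 and made
one-to-one by greedy acceptance in ascending SSD order.  The projective
transform mapping the projected (ONH-centered) image into the reference
(macula-centered) frame is estimated by MSAC over normalized-DLT
4-point hypotheses with truncated-quadratic cost, then polished by a
least-squares DLT over all inliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, RegistrationFailure
from .vessel_segmentation import SkeletonPoints


@dataclass
class DescriptorSet:
    features: np.ndarray      # (M, block_size^2), rows unit-norm
    valid_points: np.ndarray  # (M, 2) float (x, y)
    block_size: int = 23

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass
class MatchSet:
    pairs: np.ndarray      # (K, 2) int: (index_ref, index_proj)
    distances: np.ndarray  # (K,) SSD per pair
    threshold_used: float = 1.0

    def __len__(self) -> int:
        return self.pairs.shape[0]


@dataclass
class HomographyTransform:
    """3x3 projective matrix normalized to h33 = 1, mapping projected-image
    points into the reference frame (homogeneous multiply, perspective divide)."""

    H: np.ndarray
    inlier_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, float)
        if self.H.shape != (3, 3):
            raise ParameterError("H must be 3x3")
        if abs(self.H[2, 2]) < 1e-15:
            raise ParameterError("h33 must be nonzero")
        self.H = self.H / self.H[2, 2]
        if abs(np.linalg.det(self.H[:2, :2])) < 1e-15:
            raise ParameterError("upper-left 2x2 block of H is singular")


def extract_block_descriptors(V: np.ndarray, points: SkeletonPoints | np.ndarray,
                              block_size: int = 23) -> DescriptorSet:
    """Unit-normalized raster-ordered V blocks centered on each point.

    Points whose block crosses the image boundary are dropped, as are
    zero-norm blocks, so M may be smaller than the skeleton count.
    """
    if block_size % 2 == 0 or block_size < 3:
        raise ParameterError("block_size must be odd and >= 3")
    V = np.asarray(V, float)
    pts = points.points if isinstance(points, SkeletonPoints) else np.asarray(points)
    if pts.size == 0:
        return DescriptorSet(np.empty((0, block_size ** 2)), np.empty((0, 2)), block_size)
    r = block_size // 2
    h, w = V.shape
    x = pts[:, 0].astype(int)
    y = pts[:, 1].astype(int)
    inside = (x >= r) & (x <= w - 1 - r) & (y >= r) & (y <= h - 1 - r)
    x, y = x[inside], y[inside]
    if x.size == 0:
        return DescriptorSet(np.empty((0, block_size ** 2)), np.empty((0, 2)), block_size)
    windows = np.lib.stride_tricks.sliding_window_view(V, (block_size, block_size))
    feats = windows[y - r, x - r].reshape(x.size, -1)
    norms = np.linalg.norm(feats, axis=1)
    keep = norms > 0
    feats = feats[keep] / norms[keep, None]
    return DescriptorSet(features=feats,
                         valid_points=np.column_stack([x[keep], y[keep]]).astype(float),
                         block_size=block_size)


def match_descriptors(ref: DescriptorSet, proj: DescriptorSet,
                      th2: float = 1.0) -> MatchSet:
    """Exhaustive SSD matching with greedy one-to-one acceptance.

    Candidates are (ref i, nearest proj j) pairs with SSD < th2; they are
    accepted in ascending SSD order, skipping any pair whose ref or proj
    index is already taken.
    """
    if len(ref) == 0 or len(proj) == 0:
        raise ParameterError("both descriptor sets must be nonempty")
    # nearest-neighbour search in float32 (the margin between twin and
    # distractor blocks dwarfs float32 rounding); accepted distances are
    # recomputed in float64 below
    gram = ref.features.astype(np.float32) @ proj.features.astype(np.float32).T
    nearest = np.argmax(gram, axis=1)
    best = 2.0 - 2.0 * np.einsum(  # SSD of unit vectors: 2 - 2<u, v>
        "ij,ij->i", ref.features, proj.features[nearest])
    cand = np.nonzero(best < th2)[0]
    order = cand[np.argsort(best[cand], kind="stable")]
    used_ref = np.zeros(len(ref), bool)
    used_proj = np.zeros(len(proj), bool)
    pairs, dists = [], []
    for i in order:
        j = nearest[i]
        if used_ref[i] or used_proj[j]:
            continue
        used_ref[i] = used_proj[j] = True
        pairs.append((i, j))
        dists.append(best[i])
    pairs_arr = np.array(pairs, int).reshape(-1, 2)
    return MatchSet(pairs=pairs_arr, distances=np.array(dists), threshold_used=th2)


def _normalize_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: centroid at origin, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = np.sqrt(2.0) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * centroid[0]],
                  [0, s, -s * centroid[1]],
                  [0, 0, 1.0]])
    ones = np.ones((pts.shape[0], 1))
    return (np.hstack([pts, ones]) @ T.T)[:, :2], T


def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalized direct linear transform; returns H with dst ~ H src."""
    src_n, Ts = _normalize_points(src)
    dst_n, Td = _normalize_points(dst)
    n = src.shape[0]
    A = np.zeros((2 * n, 9))
    x, y = src_n[:, 0], src_n[:, 1]
    u, v = dst_n[:, 0], dst_n[:, 1]
    A[0::2, 0] = -x
    A[0::2, 1] = -y
    A[0::2, 2] = -1
    A[0::2, 6] = u * x
    A[0::2, 7] = u * y
    A[0::2, 8] = u
    A[1::2, 3] = -x
    A[1::2, 4] = -y
    A[1::2, 5] = -1
    A[1::2, 6] = v * x
    A[1::2, 7] = v * y
    A[1::2, 8] = v
    # economy SVD keeps all 9 right singular vectors only when A has >= 9 rows
    _, sv, vt = np.linalg.svd(A, full_matrices=A.shape[0] < 9)
    if n > 4 and sv[-2] < 1e-12:
        raise RegistrationFailure("rank-deficient DLT system")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    if abs(H[2, 2]) < 1e-15:
        raise RegistrationFailure("degenerate homography (h33 ~ 0)")
    return H / H[2, 2]


def _apply_h(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    p = np.hstack([pts, np.ones((pts.shape[0], 1))]) @ H.T
    return p[:, :2] / p[:, 2:3]


def _sample_degenerate(pts: np.ndarray) -> bool:
    """True if any 3 of the 4 sample points are (nearly) collinear."""
    for drop in range(4):
        a, b, c = pts[[i for i in range(4) if i != drop]]
        area = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
        if area < 1e-6:
            return True
    return False


def estimate_homography_msac(matches: MatchSet, ref_pts: np.ndarray,
                             proj_pts: np.ndarray, th3: float = 4.5,
                             max_iter: int = 2000, confidence: float = 0.99,
                             seed: int = 0) -> HomographyTransform:
    """MSAC homography from matched point pairs.

    Hypotheses come from minimal 4-point samples; the cost of a model is
    ``sum(min(residual^2, th3^2))``, so outliers contribute the threshold
    rather than their true distance.  The best model's inliers
    (residual <= th3) are refit by least-squares DLT.
    """
    n = len(matches)
    if n < 4:
        raise RegistrationFailure(f"only {n} matches; at least 4 required")
    src = np.asarray(proj_pts, float)[matches.pairs[:, 1]]
    dst = np.asarray(ref_pts, float)[matches.pairs[:, 0]]
    rng = np.random.default_rng(seed)
    th3_sq = th3 * th3
    best_cost = np.inf
    best_h = None
    needed = max_iter
    i = 0
    while i < min(needed, max_iter):
        i += 1
        idx = rng.choice(n, size=4, replace=False)
        if _sample_degenerate(src[idx]):
            continue
        try:
            H = _dlt(src[idx], dst[idx])
        except RegistrationFailure:
            continue
        r_sq = np.sum(np.square(_apply_h(H, src) - dst), axis=1)
        cost = float(np.minimum(r_sq, th3_sq).sum())
        if cost < best_cost:
            best_cost = cost
            best_h = H
            w = float((r_sq <= th3_sq).mean())
            if 0 < w < 1:
                needed = int(np.ceil(np.log(1 - confidence) / np.log(1 - w ** 4)))
            elif w >= 1:
                needed = i  # all inliers; stop
    if best_h is None:
        raise RegistrationFailure("all MSAC samples degenerate; no model found")
    r_sq = np.sum(np.square(_apply_h(best_h, src) - dst), axis=1)
    inliers = np.nonzero(r_sq <= th3_sq)[0]
    if inliers.size < 4:
        raise RegistrationFailure(f"only {inliers.size} MSAC inliers; at least 4 required")
    refined = refine_homography(dst[inliers], src[inliers])
    return HomographyTransform(H=refined.H, inlier_indices=inliers,
                               residuals=np.sqrt(np.sum(
                                   np.square(_apply_h(refined.H, src[inliers]) - dst[inliers]),
                                   axis=1)))


def refine_homography(inlier_ref: np.ndarray, inlier_proj: np.ndarray
                      ) -> HomographyTransform:
    """Least-squares normalized DLT over all inlier correspondences."""
    ref = np.asarray(inlier_ref, float)
    proj = np.asarray(inlier_proj, float)
    if ref.shape[0] < 4:
        raise RegistrationFailure(f"{ref.shape[0]} inliers; at least 4 required")
    H = _dlt(proj, ref)
    res = np.sqrt(np.sum(np.square(_apply_h(H, proj) - ref), axis=1))
    return HomographyTransform(H=H, inlier_indices=np.arange(ref.shape[0]), residuals=res)


def msac_cost(H: np.ndarray, src: np.ndarray, dst: np.ndarray, th3: float = 4.5) -> float:
    """Truncated-quadratic MSAC cost of a model on given correspondences."""
    r_sq = np.sum(np.square(_apply_h(np.asarray(H, float), np.asarray(src, float))
                            - np.asarray(dst, float)), axis=1)
    return float(np.minimum(r_sq, th3 * th3).sum())
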