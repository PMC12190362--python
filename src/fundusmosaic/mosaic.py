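"""Projection into the reference frame, mosaic merge, alignment metrics.

The macula-centered image is the reference; the ONH-centered image is
inverse-warped (bilinear) through the homography into a canvas covering
the union bounding box.  Pixels covered by both footprints are rendered
as the average of the two so the overlap is visibly distinct; the
overlap percentage is the number of overlapping pixels relative to the
pixel count of the source (moving) image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .errors import FundusMosaicError, InputError, RegistrationFailure
from .image_io import GrayImage
from .matching import HomographyTransform


@dataclass
class MosaicResult:
    canvas: GrayImage
    offset: tuple[float, float]        # reference frame -> canvas frame translation
    overlap_fraction: float
    projected_points: np.ndarray | None = None  # matched points in the global frame


@dataclass
class AlignmentMetrics:
    """Reference-vs-projected point agreement, all in pixels.

    ``rms_mean``/``rms_sd``/``rms_max`` aggregate the per-point
    reprojection distances; ``rms_pooled`` is the single scalar
    sqrt(mean squared distance) over all M points.
    """

    delta_x_mean: float
    delta_x_sd: float
    delta_y_mean: float
    delta_y_sd: float
    d_mean: float
    d_sd: float
    rms_mean: float
    rms_sd: float
    rms_max: float
    rms_pooled: float
    n_points: int


def _as_matrix(H: HomographyTransform | np.ndarray) -> np.ndarray:
    M = H.H if isinstance(H, HomographyTransform) else np.asarray(H, float)
    if M.shape != (3, 3):
        raise InputError("homography must be 3x3")
    return M / M[2, 2]


def project_points(H: HomographyTransform | np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply the homography to (N, 2) points: homogeneous multiply, divide."""
    M = _as_matrix(H)
    pts = np.atleast_2d(np.asarray(points, float))
    hom = np.hstack([pts, np.ones((pts.shape[0], 1))]) @ M.T
    w = hom[:, 2]
    bad = np.abs(w) < 1e-12
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise FundusMosaicError(
            f"point {tuple(pts[i])} maps to the plane at infinity (w={w[i]:.3e})")
    return hom[:, :2] / w[:, None]


def overlap_percentage(H: HomographyTransform | np.ndarray,
                       ref_shape: tuple[int, int],
                       mov_shape: tuple[int, int]) -> float:
    """Fraction of the moving image's pixels that land inside the reference.

    The moving footprint is rasterized in the reference frame: a
    reference pixel overlaps iff its preimage under H falls inside the
    moving image bounds.
    """
    M = _as_matrix(H)
    Minv = np.linalg.inv(M)
    hr, wr = ref_shape
    hm, wm = mov_shape
    xs, ys = np.meshgrid(np.arange(wr, dtype=float), np.arange(hr, dtype=float))
    pts = np.column_stack([xs.ravel(), ys.ravel(), np.ones(xs.size)])
    pre = pts @ Minv.T
    w = pre[:, 2]
    ok = np.abs(w) > 1e-12
    xm = np.where(ok, pre[:, 0] / np.where(ok, w, 1.0), -1.0)
    ym = np.where(ok, pre[:, 1] / np.where(ok, w, 1.0), -1.0)
    inside = ok & (xm >= -0.5) & (xm <= wm - 0.5) & (ym >= -0.5) & (ym <= hm - 0.5)
    return float(inside.sum()) / float(hm * wm)


def warp_and_merge(reference: GrayImage, moving: GrayImage,
                   H: HomographyTransform | np.ndarray,
                   projected_points: np.ndarray | None = None) -> MosaicResult:
    """Merge the moving image into the reference frame under H."""
    M = _as_matrix(H)
    if abs(np.linalg.det(M)) < 1e-12:
        raise RegistrationFailure("degenerate homography (near-zero determinant)")
    hm, wm = moving.pixels.shape
    hr, wr = reference.pixels.shape
    corners = np.array([[0, 0], [wm - 1, 0], [wm - 1, hm - 1], [0, hm - 1]], float)
    proj_corners = project_points(M, corners)
    x_min = min(0.0, proj_corners[:, 0].min())
    y_min = min(0.0, proj_corners[:, 1].min())
    x_max = max(wr - 1.0, proj_corners[:, 0].max())
    y_max = max(hr - 1.0, proj_corners[:, 1].max())
    off_x, off_y = np.floor(x_min), np.floor(y_min)
    out_w = int(np.ceil(x_max - off_x)) + 1
    out_h = int(np.ceil(y_max - off_y)) + 1
    # canvas coords -> reference coords is a pure translation by (off_x, off_y)
    T = np.array([[1, 0, off_x], [0, 1, off_y], [0, 0, 1.0]])
    # skimage's inverse_map takes output (canvas) coords to input (moving) coords
    canvas_to_moving = ProjectiveTransform(matrix=np.linalg.inv(M) @ T)
    warped = warp(moving.pixels, canvas_to_moving, output_shape=(out_h, out_w),
                  order=1, mode="constant", cval=0.0)
    mov_fp = warp(np.ones_like(moving.pixels), canvas_to_moving,
                  output_shape=(out_h, out_w), order=1, mode="constant", cval=0.0) > 0.5
    canvas = np.zeros((out_h, out_w))
    ref_fp = np.zeros((out_h, out_w), bool)
    ry, rx = int(-off_y), int(-off_x)
    canvas[ry:ry + hr, rx:rx + wr] = reference.pixels
    ref_fp[ry:ry + hr, rx:rx + wr] = True
    both = ref_fp & mov_fp
    only_mov = mov_fp & ~ref_fp
    canvas[both] = 0.5 * (canvas[both] + warped[both])
    canvas[only_mov] = warped[only_mov]
    overlap = overlap_percentage(M, reference.pixels.shape, moving.pixels.shape)
    if projected_points is not None:
        projected_points = project_points(M, projected_points)
    return MosaicResult(canvas=GrayImage(np.clip(canvas, 0.0, 1.0)),
                        offset=(float(off_x), float(off_y)),
                        overlap_fraction=overlap,
                        projected_points=projected_points)


def alignment_metrics(ref_points: np.ndarray, projected_points: np.ndarray
                      ) -> AlignmentMetrics:
    """Agreement between reference points and their projected partners.

    Delta-x/Delta-y are mean +/- sd of absolute coordinate differences,
    D the mean +/- sd Euclidean distance; the per-point distances also
    feed the RMS mean +/- sd and max, and ``rms_pooled`` pools them into
    the single scalar sqrt(mean ||p_r - p_p||^2).
    """
    ref = np.atleast_2d(np.asarray(ref_points, float))
    prj = np.atleast_2d(np.asarray(projected_points, float))
    if ref.shape != prj.shape:
        raise InputError(f"point count mismatch: {ref.shape} vs {prj.shape}")
    if ref.shape[0] < 1:
        raise InputError("at least one point pair required")
    dx = np.abs(ref[:, 0] - prj[:, 0])
    dy = np.abs(ref[:, 1] - prj[:, 1])
    d = np.hypot(dx, dy)
    return AlignmentMetrics(
        delta_x_mean=float(dx.mean()), delta_x_sd=float(dx.std()),
        delta_y_mean=float(dy.mean()), delta_y_sd=float(dy.std()),
        d_mean=float(d.mean()), d_sd=float(d.std()),
        rms_mean=float(d.mean()), rms_sd=float(d.std()),
        rms_max=float(d.max()),
        rms_pooled=float(np.sqrt(np.mean(np.square(d)))),
        n_points=int(ref.shape[0]))
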