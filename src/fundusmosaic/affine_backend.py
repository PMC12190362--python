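"""NMI-driven affine registration with the 50%-shift initialization.

A deliberately simple mutual-information backend: the ONH-centered
(moving) image starts shifted half an image width to the right of the
macula-centered (fixed) image — the anatomically expected offset — and
a derivative-free Powell search then maximizes normalized mutual
information, NMI = (H(A) + H(B)) / H(A, B), over the six affine
parameters on a three-level coarse-to-fine pyramid.  The decomposed
parameters (translations, rotation, skew, scales) together with the
final similarity, plain NMI and overlap percentage are exactly the
covariates the failure-detection model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp

from .errors import ParameterError, RegistrationFailure, UndefinedValueError
from .image_io import GrayImage


@dataclass
class AffineParams:
    tx: float = 0.0
    ty: float = 0.0
    rotation: float = 0.0   # degrees
    skew: float = 0.0       # dimensionless shear factor
    scale_x: float = 1.0
    scale_y: float = 1.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.rotation, self.skew,
                         self.scale_x, self.scale_y])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "AffineParams":
        return cls(*(float(x) for x in v))


@dataclass
class AffineTransform:
    """2x3 affine mapping moving-image (x, y) to fixed-image (x, y)."""

    matrix: np.ndarray
    params: AffineParams
    similarity: float = float("nan")  # final objective value at the optimum
    nmi: float = float("nan")         # plain NMI (64 bins) at the optimum
    overlap_pct: float = float("nan")
    levels_used: int = field(default=0, repr=False)

    def as_homography(self) -> np.ndarray:
        H = np.eye(3)
        H[:2, :] = self.matrix
        return H


def compose_affine(params: AffineParams) -> np.ndarray:
    """params -> 2x3 matrix: A = R(theta) @ [[1, k], [0, 1]] @ diag(sx, sy)."""
    th = np.deg2rad(params.rotation)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    K = np.array([[1.0, params.skew], [0.0, 1.0]])
    S = np.diag([params.scale_x, params.scale_y])
    A = R @ K @ S
    return np.column_stack([A, [params.tx, params.ty]])


def decompose_affine(matrix: np.ndarray) -> AffineParams:
    """2x3 (or 3x3) matrix -> params; exact inverse of :func:`compose_affine`."""
    M = np.asarray(matrix, float)
    if M.shape == (3, 3):
        M = M[:2, :]
    if M.shape != (2, 3):
        raise ParameterError(f"expected a 2x3 affine, got shape {M.shape}")
    A = M[:, :2]
    if abs(np.linalg.det(A)) < 1e-12:
        raise ParameterError("singular linear part")
    theta = np.arctan2(A[1, 0], A[0, 0])
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    U = R.T @ A  # upper triangular: [[sx, k*sy], [0, sy]]
    sx = U[0, 0]
    sy = U[1, 1]
    skew = U[0, 1] / sy
    return AffineParams(tx=float(M[0, 2]), ty=float(M[1, 2]),
                        rotation=float(np.rad2deg(theta)), skew=float(skew),
                        scale_x=float(sx), scale_y=float(sy))


def init_shift(fixed: GrayImage, moving: GrayImage,
               shift_fraction: float = 0.5, laterality_flip: bool = True
               ) -> AffineTransform:
    """Initial transform: identity linear part, horizontal shift of half
    the fixed image's width (sign flipped for known left eyes)."""
    sign = -1.0 if (laterality_flip and fixed.laterality == "OS") else 1.0
    params = AffineParams(tx=sign * shift_fraction * fixed.width, ty=0.0)
    return AffineTransform(matrix=compose_affine(params), params=params)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(a: np.ndarray | GrayImage, b: np.ndarray | GrayImage,
        region: np.ndarray | None = None, bins: int = 64) -> float:
    """Studholme normalized mutual information over the overlap region.

    NMI = (H(A) + H(B)) / H(A, B), in [1, 2]; invariant to bijective
    intensity relabelings of either image.
    """
    av = (a.pixels if isinstance(a, GrayImage) else np.asarray(a, float)).ravel()
    bv = (b.pixels if isinstance(b, GrayImage) else np.asarray(b, float)).ravel()
    if region is not None:
        sel = np.asarray(region, bool).ravel()
        av, bv = av[sel], bv[sel]
    if av.size == 0:
        raise UndefinedValueError("empty overlap region; NMI undefined")
    joint, _, _ = np.histogram2d(av, bv, bins=bins, range=[[0, 1], [0, 1]])
    pj = joint / joint.sum()
    h_ab = _entropy(pj.ravel())
    h_a = _entropy(pj.sum(axis=1))
    h_b = _entropy(pj.sum(axis=0))
    if h_ab == 0.0:  # both images constant on the region
        return 2.0
    return (h_a + h_b) / h_ab


def _warped_and_mask(moving: np.ndarray, matrix2x3: np.ndarray,
                     shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    H = np.eye(3)
    H[:2, :] = matrix2x3
    tf = _SkAffine(matrix=np.linalg.inv(H))  # output (fixed) -> input (moving)
    warped = warp(moving, tf, output_shape=shape, order=1, mode="constant", cval=-1.0)
    mask = warped >= 0.0
    return np.where(mask, warped, 0.0), mask


def register_affine_nmi(fixed: GrayImage, moving: GrayImage,
                        init: AffineTransform, levels: int = 3,
                        bins: int = 64) -> AffineTransform:
    """Coarse-to-fine Powell maximization of NMI over 6 affine parameters.

    Downsampling factors are 4, 2, 1; each level starts from the previous
    optimum with a fixed iteration budget, so the whole registration is
    deterministic.  A result outside the plausible box (|rotation| > 30
    degrees, scales outside [0.7, 1.4]) raises a failure signal.
    """
    factors = [2 ** (levels - 1 - k) for k in range(levels)]
    # most of the search happens on the cheap coarse levels; the finest
    # level only polishes, so its evaluation budget is small
    budgets = {4: 1500, 2: 500, 1: 150}
    params = init.params

    def to_vec(p: AffineParams) -> np.ndarray:
        # rescale so a unit Powell step means ~1 px, ~1 degree, ~1% shear/scale
        return np.array([p.tx, p.ty, p.rotation, 100.0 * p.skew,
                         100.0 * (p.scale_x - 1.0), 100.0 * (p.scale_y - 1.0)])

    def from_vec(v: np.ndarray) -> AffineParams:
        return AffineParams(tx=float(v[0]), ty=float(v[1]), rotation=float(v[2]),
                            skew=float(v[3]) / 100.0,
                            scale_x=1.0 + float(v[4]) / 100.0,
                            scale_y=1.0 + float(v[5]) / 100.0)

    for level_idx, factor in enumerate(factors):
        if factor > 1:
            fx = ndi.zoom(ndi.gaussian_filter(fixed.pixels, factor / 2.0),
                          1.0 / factor, order=1)
            mv = ndi.zoom(ndi.gaussian_filter(moving.pixels, factor / 2.0),
                          1.0 / factor, order=1)
        else:
            fx, mv = fixed.pixels, moving.pixels
        level_bins = max(16, bins // factor)

        def objective(v: np.ndarray) -> float:
            M = compose_affine(from_vec(v)).copy()
            M[:, 2] /= factor  # translations live on the level's pixel grid
            warped, mask = _warped_and_mask(mv, M, fx.shape)
            if mask.sum() < 64:
                return 0.0
            return -nmi(fx, warped, region=mask, bins=level_bins)

        if level_idx == 0:
            # the NMI peak is only a few pixels wide while the 50%-shift
            # init can be tens of pixels off: sweep translations on a
            # coarse grid first so the local optimizer starts in the basin
            v0 = to_vec(params)
            best = (objective(v0), 0.0, 0.0)
            for dx in range(-96, 97, 8):
                for dy in range(-96, 97, 8):
                    v = v0.copy()
                    v[0] += dx
                    v[1] += dy
                    f = objective(v)
                    if f < best[0]:
                        best = (f, float(dx), float(dy))
            v0[0] += best[1]
            v0[1] += best[2]
            params = from_vec(v0)

        res = minimize(objective, to_vec(params), method="Powell",
                       options={"maxiter": 40, "xtol": 0.05, "ftol": 1e-5,
                                "maxfev": budgets.get(factor, 300)})
        params = from_vec(res.x)

    if abs(params.rotation) > 30.0 or not (
            0.7 <= params.scale_x <= 1.4 and 0.7 <= params.scale_y <= 1.4):
        raise RegistrationFailure(
            f"affine optimum outside the plausible box: rotation={params.rotation:.1f} deg, "
            f"scales=({params.scale_x:.2f}, {params.scale_y:.2f})")

    matrix = compose_affine(params)
    warped, mask = _warped_and_mask(moving.pixels, matrix, fixed.pixels.shape)
    if not mask.any():
        raise RegistrationFailure("registered views do not overlap")
    similarity = nmi(fixed.pixels, warped, region=mask, bins=max(16, bins // 2))
    plain = nmi(fixed.pixels, warped, region=mask, bins=bins)
    overlap = float(mask.sum()) / float(moving.pixels.size)
    return AffineTransform(matrix=matrix, params=params, similarity=similarity,
                           nmi=plain, overlap_pct=overlap, levels_used=levels)
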