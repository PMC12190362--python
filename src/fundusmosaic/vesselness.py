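"""Hessian-eigenvalue vesselness (Frangi-type) and its gradient magnitude.

At each scale sigma the image is convolved with scale-normalized
(sigma^2-weighted) second-derivative-of-Gaussian kernels to form the
Hessian; its eigenvalues, ordered |lambda1| <= |lambda2|, yield the
blobness ratio R_B = lambda1/lambda2 and the second-order structureness
S = sqrt(lambda1^2 + lambda2^2).  The vesselness is

    V = 0                                              if lambda2 > 0
    V = exp(-R_B^2 / 2 beta^2) * (1 - exp(-S^2 / 2 c^2))  otherwise

with beta = 0.5 and c = c_fraction * max(S) of the scale.  This form
suppresses positive lambda2, i.e. detects *bright* ridges; SLO vessels
are dark, so the multi-scale driver filters the intensity complement
(1 - I).  The per-pixel maximum over scales is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError
from .image_io import GrayImage


@dataclass
class VesselnessResult:
    """Per-pixel vesselness and companion features.

    ``lambda1``/``lambda2`` are the Hessian eigenvalues at the winning
    scale, ordered by magnitude; ``s_max`` is the largest structureness
    observed over all scales.
    """

    V: np.ndarray
    grad_mag: np.ndarray
    scale_argmax: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    s_max: float


def hessian_at_scale(image: GrayImage | np.ndarray, sigma: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale-normalized Gaussian Hessian (Ixx, Ixy, Iyy) at one scale.

    Subscripts follow the (x, y) = (column, row) convention; each array
    is the convolution with the corresponding second Gaussian derivative,
    multiplied by sigma^2 so responses are comparable across scales.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    # remove the DC level: mathematically invisible to second derivatives,
    # but it suppresses the truncation leak of the finite derivative kernels
    arr = arr - arr.mean()
    s2 = sigma * sigma
    ixx = s2 * ndi.gaussian_filter(arr, sigma, order=(0, 2), mode="nearest")
    iyy = s2 * ndi.gaussian_filter(arr, sigma, order=(2, 0), mode="nearest")
    ixy = s2 * ndi.gaussian_filter(arr, sigma, order=(1, 1), mode="nearest")
    return ixx, ixy, iyy


def hessian_eigenvalues(ixx: np.ndarray, ixy: np.ndarray, iyy: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the symmetric 2x2 Hessian, ordered |l1| <= |l2|."""
    half_trace = 0.5 * (ixx + iyy)
    disc = np.sqrt(np.square(0.5 * (ixx - iyy)) + np.square(ixy))
    mu_a = half_trace + disc
    mu_b = half_trace - disc
    swap = np.abs(mu_a) > np.abs(mu_b)
    lam1 = np.where(swap, mu_b, mu_a)
    lam2 = np.where(swap, mu_a, mu_b)
    return lam1, lam2


def vesselness_measure(lambda1: np.ndarray, lambda2: np.ndarray,
                       beta: float = 0.5, c: float | None = None) -> np.ndarray:
    """Evaluate the vesselness V from ordered eigenvalue arrays.

    Pixels with lambda2 > 0 (or exactly 0, where R_B is undefined) are
    background and get V = 0.
    """
    if c is None or c <= 0:
        raise ParameterError(f"normalization constant c must be positive, got {c}")
    lam1 = np.asarray(lambda1, float)
    lam2 = np.asarray(lambda2, float)
    v = np.zeros(np.broadcast(lam1, lam2).shape, dtype=float)
    active = lam2 < 0
    if np.any(active):
        l1 = lam1[active]
        l2 = lam2[active]
        rb2 = np.square(l1 / l2)
        s2 = np.square(l1) + np.square(l2)
        v[active] = np.exp(-rb2 / (2.0 * beta * beta)) * (
            1.0 - np.exp(-s2 / (2.0 * c * c)))
    return v


def gradient_magnitude(V: np.ndarray) -> np.ndarray:
    """Euclidean gradient magnitude of V via central differences."""
    if not np.all(np.isfinite(V)):
        raise ParameterError("V contains non-finite values")
    gy, gx = np.gradient(np.asarray(V, float))
    return np.hypot(gx, gy)


def multiscale_vesselness(image: GrayImage,
                          sigma_list: tuple[float, ...] = (0.8, 1.6, 2.4, 3.2),
                          beta: float = 0.5,
                          c_fraction: float = 0.5) -> VesselnessResult:
    """Maximum vesselness over scales on the intensity complement.

    Dark vessels on a brighter background become bright ridges of
    ``1 - I``.  The normalization c is recomputed per scale as
    ``c_fraction * max(S)`` of that scale's structureness, keeping the
    S-term comparable across the scale ladder before the pixel-wise max.
    """
    if len(sigma_list) == 0:
        raise ParameterError("sigma_list must be nonempty")
    if any(s <= 0 for s in sigma_list):
        raise ParameterError("all sigmas must be positive")
    if list(sigma_list) != sorted(sigma_list):
        raise ParameterError("sigma_list must be ascending")
    comp = 1.0 - image.pixels
    shape = comp.shape
    best_v = np.zeros(shape)
    best_scale = np.full(shape, sigma_list[0], dtype=float)
    best_l1 = np.zeros(shape)
    best_l2 = np.zeros(shape)
    s_max_global = 0.0
    for k, sigma in enumerate(sigma_list):
        ixx, ixy, iyy = hessian_at_scale(comp, sigma)
        lam1, lam2 = hessian_eigenvalues(ixx, ixy, iyy)
        s = np.hypot(lam1, lam2)
        s_max = float(s.max())
        s_max_global = max(s_max_global, s_max)
        if s_max == 0.0:  # featureless at this scale
            continue
        v = vesselness_measure(lam1, lam2, beta=beta, c=c_fraction * s_max)
        better = v > best_v if k > 0 else np.ones(shape, bool)
        best_scale = np.where(better, sigma, best_scale)
        best_l1 = np.where(better, lam1, best_l1)
        best_l2 = np.where(better, lam2, best_l2)
        best_v = np.where(better, v, best_v)
    return VesselnessResult(V=best_v,
                            grad_mag=gradient_magnitude(best_v),
                            scale_argmax=best_scale,
                            lambda1=best_l1,
                            lambda2=best_l2,
                            s_max=s_max_global)
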