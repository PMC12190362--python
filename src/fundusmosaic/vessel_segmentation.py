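"""Region-growing vessel segmentation and centerline extraction.

Seeds are taken from the image's own feature histograms: strong
vesselness pixels seed the vessel class, weak-vesselness low-gradient
pixels seed the background class.  Labels then propagate to
8-neighbours in a two-stage relaxation — stage 1 grows only through
low-gradient territory (suppressing growth across edges), stage 2 drops
the gradient constraint and competes purely on vesselness — and the
vessel mask is finally thinned to one-pixel-wide centerlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import thin

from .errors import DegenerateInputError, ParameterError, RegistrationFailure

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class VesselMask:
    mask: np.ndarray  # boolean
    seed_thresholds: tuple[float, float, float]  # (t_vessel_seed, t_background_seed, t_lowgrad)


@dataclass
class SkeletonPoints:
    """Centerline pixels as (x, y) coordinates, row-major order."""

    points: np.ndarray  # (M, 2) int array of (x, y)

    @property
    def count(self) -> int:
        return int(self.points.shape[0])


def select_seeds(V: np.ndarray, grad_mag: np.ndarray,
                 q_vessel: float = 0.92, q_background: float = 0.50,
                 min_vessel_seeds: int = 50
                 ) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Histogram-derived seed masks for the two classes.

    Vessel seeds: V at or above the ``q_vessel`` quantile of *nonzero* V.
    Background seeds: V below the ``q_background`` quantile of all V and
    gradient magnitude below its median (flat, clearly non-vessel area).
    """
    V = np.asarray(V, float)
    grad_mag = np.asarray(grad_mag, float)
    if V.shape != grad_mag.shape:
        raise ParameterError("V and grad_mag shapes differ")
    nz = V[V > 0]
    if nz.size == 0:
        raise DegenerateInputError("vesselness map is identically zero")
    t_vessel = float(np.quantile(nz, q_vessel))
    t_background = float(np.quantile(V, q_background))
    t_lowgrad = float(np.median(grad_mag))
    vessel_seeds = V >= t_vessel
    # inclusive comparisons so degenerate maps (V and grad exactly zero on
    # the background) still yield background seeds; for continuous data the
    # choice of <= vs < is immaterial
    background_seeds = (V <= t_background) & (grad_mag <= t_lowgrad) & ~vessel_seeds
    if int(vessel_seeds.sum()) < min_vessel_seeds:
        raise DegenerateInputError(
            f"only {int(vessel_seeds.sum())} vessel seeds (< {min_vessel_seeds}); "
            "image appears featureless")
    return vessel_seeds, background_seeds, (t_vessel, t_background, t_lowgrad)


def _grow_stage(labels: np.ndarray, V: np.ndarray, eligible_base: np.ndarray,
                max_iter: int) -> tuple[np.ndarray, bool]:
    """Propagate the two classes to 8-neighbours until a fixed point.

    A contested pixel (frontier of both classes) goes to the class whose
    current mean vesselness is closer; ties favor the vessel class.
    Returns (labels, converged).
    """
    for _ in range(max_iter):
        unlabeled = labels == 0
        if not unlabeled.any():
            return labels, True
        eligible = unlabeled & eligible_base
        v_front = ndi.binary_dilation(labels == 1, _EIGHT) & eligible
        b_front = ndi.binary_dilation(labels == 2, _EIGHT) & eligible
        frontier = v_front | b_front
        if not frontier.any():
            return labels, True
        mean_v = V[labels == 1].mean()
        mean_b = V[labels == 2].mean() if (labels == 2).any() else 0.0
        contested = v_front & b_front
        to_vessel = (v_front & ~b_front) | (
            contested & (np.abs(V - mean_v) <= np.abs(V - mean_b)))
        labels[to_vessel] = 1
        labels[frontier & ~to_vessel] = 2
    return labels, not (labels == 0).any()


def region_grow(V: np.ndarray, grad_mag: np.ndarray,
                vessel_seeds: np.ndarray, background_seeds: np.ndarray,
                thresholds: tuple[float, float, float], max_iter: int = 100) -> VesselMask:
    """Two-stage iterative relaxation labelling from the seed masks.

    ``thresholds`` is the (t_vessel_seed, t_background_seed, t_lowgrad)
    triple from :func:`select_seeds`, recorded on the result for
    reproducibility; the growth itself uses only t_lowgrad.
    """
    t_lowgrad = thresholds[2]
    if not vessel_seeds.any() or not background_seeds.any():
        raise DegenerateInputError("both seed sets must be nonempty")
    V = np.asarray(V, float)
    labels = np.zeros(V.shape, dtype=np.uint8)
    labels[background_seeds] = 2
    labels[vessel_seeds] = 1  # vessel seeds win overlaps
    # stage 1: growth confined to low-gradient territory
    labels, _ = _grow_stage(labels, V, grad_mag < t_lowgrad, max_iter)
    # stage 2: constraint relaxed, classes compete on V alone
    labels, converged = _grow_stage(labels, V, np.ones(V.shape, bool), max_iter)
    if not converged:
        # pixels disconnected from every seed can never be reached; they
        # are background by definition, but a still-moving frontier is an error
        raise RegistrationFailure(
            f"region growing did not converge; {int((labels == 0).sum())} pixels unresolved")
    return VesselMask(mask=labels == 1, seed_thresholds=tuple(float(t) for t in thresholds))


def skeletonize(mask: VesselMask | np.ndarray) -> SkeletonPoints:
    """Thin the vessel mask to a 1-px-wide 8-connected skeleton.

    Iterative morphological thinning preserves the topology of the mask,
    so connected components survive one-to-one.  An empty mask yields an
    empty point list (the pipeline's self-report handles it downstream).
    """
    arr = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, bool)
    if not arr.any():
        return SkeletonPoints(points=np.empty((0, 2), dtype=np.int64))
    skel = thin(arr)
    rows, cols = np.nonzero(skel)  # row-major order
    return SkeletonPoints(points=np.column_stack([cols, rows]).astype(np.int64))


def extract_skeleton(V: np.ndarray, grad_mag: np.ndarray,
                     q_vessel: float = 0.92, q_background: float = 0.50,
                     max_iter: int = 100) -> tuple[VesselMask, SkeletonPoints]:
    """Seed -> grow -> thin convenience wrapper used by the pipeline."""
    vs, bs, thresholds = select_seeds(V, grad_mag, q_vessel, q_background)
    mask = region_grow(V, grad_mag, vs, bs, thresholds, max_iter=max_iter)
    return mask, skeletonize(mask)
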