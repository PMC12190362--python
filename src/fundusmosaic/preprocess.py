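"""Contrast-enhancement decision and CLAHE.

Poor-contrast SLO exports concentrate their histogram in a narrow, dark
band.  A robust location estimate of the intensity sample — the least
median of squares (LMedS) location, i.e. the midpoint of the shortest
intensity interval containing half the pixels — decides per image
whether contrast-limited adaptive histogram equalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

from .errors import ParameterError
from .image_io import GrayImage


@dataclass
class HistogramStats:
    """Robust histogram summary of one image (8-bit intensity scale)."""

    lmeds_location: float
    needs_enhancement: bool
    histogram: np.ndarray  # 256 counts

    def __post_init__(self) -> None:
        if not (0.0 <= self.lmeds_location <= 255.0):
            raise ParameterError(f"lmeds_location out of range: {self.lmeds_location}")


def lmeds_location(image: GrayImage, th1: float = 120.0) -> HistogramStats:
    """LMedS location of the pixel-intensity sample.

    For a pure-location model the LMedS estimate minimizing
    ``med_i (y_i - b)^2`` is the midpoint of the shortest window covering
    ``ceil(n/2)`` consecutive order statistics (the "shortest half").
    Computed on the 8-bit scale, so a constant image of gray level g
    returns exactly g.
    """
    sample = np.round(image.pixels.ravel() * 255.0).astype(np.int64)
    n = sample.size
    if n == 0:
        raise ParameterError("empty image")
    s = np.sort(sample)
    m = (n + 1) // 2  # ceil(50%) of the pixels
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))  # ties: leftmost window, deterministic
    loc = (float(s[i]) + float(s[i + m - 1])) / 2.0
    hist = np.bincount(sample, minlength=256)[:256]
    return HistogramStats(lmeds_location=loc,
                          needs_enhancement=loc <= th1,
                          histogram=hist)


def needs_enhancement(stats: HistogramStats, th1: float = 120.0) -> bool:
    """True iff the LMedS location is at or below ``th1`` (default 120,
    about half the 8-bit dynamic range)."""
    return stats.lmeds_location <= th1


def clahe(image: GrayImage, tiles: int = 8, clip_limit: float = 0.01) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    Local histogram equalization on a ``tiles x tiles`` grid with clipped
    histograms and bilinear inter-tile interpolation, so tile boundaries
    stay invisible.  Output intensities are in [0, 1].
    """
    h, w = image.pixels.shape
    if h < tiles or w < tiles:
        raise ParameterError(f"image {h}x{w} smaller than the {tiles}x{tiles} tile grid")
    if np.ptp(image.pixels) == 0.0:
        # no contrast to amplify; equalize_adapthist would rescale noise-free input
        return GrayImage(image.pixels.copy(), image.laterality, image.center_label)
    out = exposure.equalize_adapthist(
        image.pixels, kernel_size=(max(1, h // tiles), max(1, w // tiles)),
        clip_limit=clip_limit)
    return GrayImage(np.clip(out, 0.0, 1.0), image.laterality, image.center_label)


def enhance_if_needed(image: GrayImage, th1: float = 120.0,
                      tiles: int = 8, clip_limit: float = 0.01
                      ) -> tuple[GrayImage, HistogramStats]:
    """Apply CLAHE when the LMedS rule asks for it; decision is per image."""
    stats = lmeds_location(image, th1=th1)
    if stats.needs_enhancement:
        return clahe(image, tiles=tiles, clip_limit=clip_limit), stats
    return image, stats
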