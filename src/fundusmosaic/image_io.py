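"""Shared grayscale image representation and 8-bit TIFF round-tripping.

Pixel convention used throughout the package: 0-based coordinates,
``(x, y) = (column, row)``, x increasing rightward, y increasing
downward, pixel centers at integer coordinates.  Arrays are indexed
``pixels[y, x]``.  Intensities are floats in [0, 1] in memory and 8-bit
[0, 255] on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, ParameterError

log = logging.getLogger(__name__)

#: ITU-R BT.709 luminance weights for occasional RGB-triplicate exports.
_LUMA = np.array([0.2126, 0.7152, 0.0722])

NOMINAL_SIZE = 768


@dataclass
class GrayImage:
    """A single-channel SLO fundus image (or any grayscale raster).

    Parameters
    ----------
    pixels
        2-D float array with values in [0, 1].
    laterality
        ``"OD"`` (right eye), ``"OS"`` (left eye) or ``"unknown"``.
    center_label
        ``"macula"``, ``"onh"`` or ``"unknown"`` — which retinal landmark
        the scan is centered on.
    """

    pixels: np.ndarray
    laterality: str = "unknown"
    center_label: str = "unknown"
    source_bit_depth: int = field(default=8, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ParameterError(f"expected a 2-D raster, got ndim={self.pixels.ndim}")
        h, w = self.pixels.shape
        if h < 32 or w < 32:
            raise ParameterError(f"image too small: {h}x{w} (minimum 32x32)")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("image contains non-finite intensities")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ParameterError(f"intensities outside [0,1]: min={lo}, max={hi}")
        if self.laterality not in ("OD", "OS", "unknown"):
            raise ParameterError(f"bad laterality {self.laterality!r}")
        if self.center_label not in ("macula", "onh", "unknown"):
            raise ParameterError(f"bad center_label {self.center_label!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_slo_tiff(path: str | Path, laterality: str = "unknown",
                  center_label: str = "unknown") -> GrayImage:
    """Read a single-page grayscale (or RGB-triplicate) TIFF as a :class:`GrayImage`.

    RGB pages are collapsed to luminance; intensities are normalized to
    [0, 1] by the dtype's full scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        n_pages = len(tf.pages)
        if n_pages != 1:
            raise FormatError(f"{path}: expected a single-page TIFF, found {n_pages} pages")
        arr = tf.pages[0].asarray()
    if arr.size == 0:
        raise FormatError(f"{path}: zero-sized image")
    if np.issubdtype(arr.dtype, np.integer):
        bit_depth = np.iinfo(arr.dtype).bits
        scale = float(np.iinfo(arr.dtype).max)
    else:
        bit_depth = 8
        scale = 1.0
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise FormatError(f"{path}: unsupported channel count {arr.shape[2]}")
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    if arr.ndim != 2:
        raise FormatError(f"{path}: not a 2-D raster (shape {arr.shape})")
    pixels = np.clip(arr.astype(np.float64) / scale, 0.0, 1.0)
    if pixels.shape != (NOMINAL_SIZE, NOMINAL_SIZE):
        log.warning("%s: size %s differs from the nominal %dx%d export; proceeding unresized",
                    path, pixels.shape, NOMINAL_SIZE, NOMINAL_SIZE)
    return GrayImage(pixels, laterality=laterality, center_label=center_label,
                     source_bit_depth=bit_depth)


def write_gray_tiff(image: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` as an 8-bit single-page grayscale TIFF.

    Stored values are ``round(x * 255)``; a read-back therefore differs
    from ``image`` by at most one quantization step (1/255) per pixel.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = np.round(image.pixels * 255.0).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")
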