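"""Pipeline configuration with the published default thresholds.

The three named thresholds follow the vessel-feature method: ``th1``
gates contrast enhancement (roughly half the 8-bit dynamic range),
``th2`` bounds the SSD between unit-normalized block descriptors, and
``th3`` is the MSAC residual cutoff in pixels.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .errors import ParameterError


@dataclass(frozen=True)
class RegistrationConfig:
    # preprocess
    th1: float = 120.0            # LMedS intensity threshold, 8-bit scale
    clahe_tiles: int = 8          # tile grid (tiles x tiles)
    clahe_clip_limit: float = 0.01
    # vesselness
    sigma_list: tuple[float, ...] = (0.8, 1.6, 2.4, 3.2)
    beta: float = 0.5
    c_fraction: float = 0.5
    # segmentation
    q_vessel_seed: float = 0.92
    q_background_seed: float = 0.50
    region_grow_max_iter: int = 100
    # matching
    block_size: int = 23
    th2: float = 1.0              # descriptor SSD threshold (unit vectors)
    th3: float = 4.5              # MSAC residual threshold, pixels
    msac_max_iter: int = 2000
    msac_confidence: float = 0.99
    min_inliers: int = 4
    rng_seed: int = 0
    # affine backend
    nmi_bins: int = 64
    pyramid_levels: int = 3
    shift_fraction: float = 0.5   # initial horizontal shift, fraction of width
    laterality_flip: bool = True  # flip shift sign for left (OS) eyes
    # dual-method cross-check
    overlapdiff_flag_threshold: float = 10.0  # percentage points

    def __post_init__(self) -> None:
        if not (0.0 < self.th1 < 255.0):
            raise ParameterError(f"th1 must be in (0,255), got {self.th1}")
        if self.th2 <= 0 or self.th3 <= 0:
            raise ParameterError("th2 and th3 must be positive")
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ParameterError(f"block_size must be odd and >= 3, got {self.block_size}")
        if not self.sigma_list or any(s <= 0 for s in self.sigma_list):
            raise ParameterError("sigma_list must be nonempty with positive scales")
        if self.beta <= 0:
            raise ParameterError("beta must be positive")
        if not (0.0 < self.c_fraction <= 1.0):
            raise ParameterError(f"c_fraction must be in (0,1], got {self.c_fraction}")

    def with_(self, **kwargs) -> "RegistrationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RegistrationConfig":
        """Load a config from a flat or sectioned TOML file.

        Sections (``[preprocess]`` etc.) are flattened; unknown keys are
        rejected so typos fail loudly.
        """
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "sigma_list" in flat:
            flat["sigma_list"] = tuple(flat["sigma_list"])
        return cls(**flat)
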