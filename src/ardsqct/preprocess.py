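"""Slice preprocessing: from HU image to normalized network input.

The chain mirrors the standard quantitative-CT preparation of a lung slice
for a segmentation network:

1. clamp HU to the lung window [-1024, +100]
2. linear 8-bit quantization (-1024 -> 0, +100 -> 255)
3. binary thorax mask (threshold + particle filter + hole fill)
4. mask the 8-bit image (outside-thorax pixels -> 0)
5. normalize to [-1, +1): (p - 128) / 128

The ground-truth lung mask, when given, is mapped {0,1} -> {-1,+1} so the
network can be trained as an MSE regression onto the signed mask.

Masked-out background pixels carry 8-bit value 0 and therefore normalize to
-1.0, identical to air.  The normalization constants (128, 128) are fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

HU_MIN = -1024.0
HU_MAX = 100.0
_HU_SPAN = HU_MAX - HU_MIN  # 1124


@dataclass
class PreprocessParams:
    """Tunable preprocessing parameters (HU window is fixed by convention)."""

    body_threshold_uint8: int = 119  # ~ -500 HU; separates air from soft tissue
    min_particle_frac: float = 0.005  # components below 0.5% of slice area dropped


@dataclass
class PreprocessedSlice:
    image: np.ndarray  # float32 in [-1, 0.9921875]
    thorax_mask: np.ndarray  # uint8 {0,1}
    target: np.ndarray | None = None  # float32 in {-1, +1}


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def clamp_hu(hu_grid: np.ndarray) -> np.ndarray:
    """Clamp HU values into the lung window [-1024, +100]."""
    return np.clip(np.asarray(hu_grid, dtype=np.float64), HU_MIN, HU_MAX)


def to_uint8(clamped: np.ndarray) -> np.ndarray:
    """Quantize window-clamped HU linearly onto 0..255.

    -1024 maps to 0 and +100 to 255; ties round half away from zero.
    """
    clamped = np.asarray(clamped, dtype=np.float64)
    if clamped.size and (clamped.min() < HU_MIN or clamped.max() > HU_MAX):
        raise ValueError("input outside [-1024, +100]; clamp first")
    scaled = (clamped - HU_MIN) / _HU_SPAN * 255.0
    return _round_half_away(scaled).astype(np.uint8)


def uint8_to_hu(u: np.ndarray) -> np.ndarray:
    """Inverse of the 8-bit quantization (center of each code's HU span)."""
    return np.asarray(u, dtype=np.float64) / 255.0 * _HU_SPAN + HU_MIN


def thorax_mask(uint8_grid: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Binary body mask via threshold, particle filter and hole filling.

    Pixels at or above the body threshold form candidate body regions;
    connected components smaller than ``min_particle_frac`` of the slice are
    discarded (particle filter) and internal holes (lungs, airways, bowel
    gas) are filled.  An all-air slice yields an empty mask.
    """
    params = params or PreprocessParams()
    u = np.asarray(uint8_grid)
    body = u >= params.body_threshold_uint8
    if not body.any():
        log.info("thorax_mask: no pixels above threshold; returning empty mask")
        return np.zeros(u.shape, dtype=np.uint8)
    labels, n = ndimage.label(body)
    if n:
        min_px = params.min_particle_frac * u.size
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_px) + 1
        body = np.isin(labels, keep)
    if not body.any():
        log.info("thorax_mask: all components below particle threshold; empty mask")
        return np.zeros(u.shape, dtype=np.uint8)
    filled = ndimage.binary_fill_holes(body)
    return filled.astype(np.uint8)


def apply_mask(uint8_grid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out pixels outside the thorax mask."""
    u = np.asarray(uint8_grid)
    m = np.asarray(mask)
    if u.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    return np.where(m.astype(bool), u, 0).astype(u.dtype)


def normalize(uint8_grid: np.ndarray) -> np.ndarray:
    """Map 8-bit values onto [-1, +1): (p - 128) / 128."""
    return ((np.asarray(uint8_grid, dtype=np.float32) - 128.0) / 128.0).astype(np.float32)


def normalize_mask(binary_mask: np.ndarray) -> np.ndarray:
    """Map a binary lung mask onto the signed target {-1.0, +1.0}."""
    m = np.asarray(binary_mask)
    return np.where(m.astype(bool), 1.0, -1.0).astype(np.float32)


def preprocess_slice(
    hu_grid: np.ndarray,
    ground_truth_mask: np.ndarray | None = None,
    params: PreprocessParams | None = None,
) -> PreprocessedSlice:
    """Run the full preprocessing chain on one HU slice.

    Returns the normalized network input, the thorax mask, and (when a
    ground-truth lung mask is supplied) the signed training target.
    """
    u = to_uint8(clamp_hu(hu_grid))
    tmask = thorax_mask(u, params)
    masked = apply_mask(u, tmask)
    image = normalize(masked)
    target = None
    if ground_truth_mask is not None:
        if np.asarray(ground_truth_mask).shape != image.shape:
            raise ValueError("ground-truth mask shape differs from image")
        target = normalize_mask(ground_truth_mask)
    return PreprocessedSlice(image=image, thorax_mask=tmask, target=target)
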