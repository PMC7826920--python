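"""Water-pressure-regulator removal by color.

The regulator is the red circular fitting at the end of the drinking pipe —
a hue far from both the litter floor and the birds, so it is detected by a
wrapped HSV hue window with saturation/value floors and subtracted from the
binary target mask.  Detected regions are dilated by a small rim to cover
anti-aliased edge pixels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import disk, remove_small_objects

from .core import GeometryError, as_mask, as_rgb

__all__ = ["detect_red_region", "remove_region"]


def detect_red_region(
    image: np.ndarray,
    hue_range: tuple[float, float] = (-20.0, 20.0),
    sat_min: float = 0.5,
    val_min: float = 0.2,
    min_area: int = 20,
    dilate_px: int = 2,
) -> np.ndarray:
    """Mask of connected red regions (the regulator footprint).

    ``hue_range`` is in degrees and wraps around 0/360 (red straddles the
    hue origin).  Regions smaller than ``min_area`` px are discarded; the
    survivors are dilated by ``dilate_px`` px.  An empty mask is a valid
    result — frames without a regulator simply yield no red pixels.
    """
    hsv = rgb2hsv(as_rgb(image))
    hue = hsv[:, :, 0] * 360.0
    lo, hi = hue_range
    width = (hi - lo) % 360.0
    in_hue = ((hue - lo) % 360.0) <= width
    mask = in_hue & (hsv[:, :, 1] >= sat_min) & (hsv[:, :, 2] >= val_min)
    if min_area > 0 and mask.any():
        mask = remove_small_objects(mask, max_size=min_area - 1)
    if dilate_px > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=disk(dilate_px))
    return mask


def remove_region(mask: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Delete a detected equipment region from a mask (set difference)."""
    arr = as_mask(mask)
    reg = as_mask(region)
    if arr.shape != reg.shape:
        raise GeometryError(f"shape mismatch: mask {arr.shape} vs region {reg.shape}")
    return arr & ~reg
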