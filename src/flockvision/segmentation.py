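"""Initial bird segmentation from an RGB frame.

This is deliberately simple plumbing: the pipeline's contribution is
occlusion removal and restoration, which only need *a* plausible binary
target mask to start from.  The default method classifies each pixel by its
RGB distance to a configurable bird-color prototype with a fixed threshold
(equipment and litter colors sit far from the prototype, so painting more
equipment-colored pixels into a frame never adds foreground); setting
``threshold=None`` falls back to Otsu on the distance map.  A plain
grayscale-Otsu method is also available for high-contrast frames.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

from .core import ConfigError, as_rgb

__all__ = ["segment_targets", "color_mask"]

DEFAULT_BIRD_COLOR = (230, 228, 220)


def color_mask(image: np.ndarray, color, max_distance: float) -> np.ndarray:
    """Pixels whose Euclidean RGB distance to ``color`` is <= ``max_distance``."""
    img = as_rgb(image).astype(np.float64)
    proto = np.asarray(color, dtype=np.float64)
    dist = np.sqrt(((img - proto) ** 2).sum(axis=-1))
    return dist <= max_distance


def segment_targets(
    image: np.ndarray,
    method: str = "color_distance",
    *,
    bird_color=DEFAULT_BIRD_COLOR,
    threshold: float | None = 60.0,
    bird_brighter: bool = True,
    min_area: int = 30,
    hole_area: int = 50,
) -> np.ndarray:
    """Binary target mask of bird-like pixels.

    Parameters
    ----------
    method:
        ``"color_distance"`` (default) thresholds the per-pixel RGB distance
        to ``bird_color``; ``"otsu"`` thresholds the grayscale intensity and
        keeps the bright side when ``bird_brighter``.
    threshold:
        Fixed distance threshold for ``color_distance``; ``None`` selects it
        by Otsu on the distance map.
    min_area, hole_area:
        Specks below ``min_area`` px are removed and holes below
        ``hole_area`` px are filled.
    """
    img = as_rgb(image)
    if method == "color_distance":
        proto = np.asarray(bird_color, dtype=np.float64)
        dist = np.sqrt(((img.astype(np.float64) - proto) ** 2).sum(axis=-1))
        thr = float(threshold) if threshold is not None else float(threshold_otsu(dist))
        mask = dist <= thr
    elif method == "otsu":
        gray = img.astype(np.float64).mean(axis=-1)
        thr = float(threshold_otsu(gray))
        mask = gray > thr if bird_brighter else gray < thr
    else:
        raise ConfigError(f"unknown segmentation method {method!r}")
    if mask.any() and min_area > 0:
        mask = remove_small_objects(mask, max_size=min_area - 1)
    if mask.any() and hole_area > 0:
        mask = remove_small_holes(mask, max_size=hole_area - 1)
    return mask
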