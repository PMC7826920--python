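"""Shared raster conventions, image/mask I/O and connected-component labeling.

Conventions used throughout the package
---------------------------------------
* An **image** is an ``(H, W, 3)`` ``uint8`` numpy array in R, G, B channel
  order, row 0 at the top of the frame.
* A **binary mask** is an ``(H, W)`` boolean numpy array with the same shape
  as the image it annotates.  On disk a mask is a single-channel PNG with
  foreground = 255 and background = 0.
* Pixel coordinates are 0-based ``(row, col)``.  Conic / ellipse math uses
  Cartesian ``x = col`` and ``y = row`` in pixel units.

Top-view pen frames up to 1440 x 1080 pixels are supported; everything here
is plain vectorized numpy and scales linearly in the pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "FlockVisionError",
    "ImageIOError",
    "ConfigError",
    "DetectionError",
    "GeometryError",
    "FitError",
    "SelectionError",
    "MetricError",
    "PlacementError",
    "LabeledRegion",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "as_mask",
    "as_rgb",
    "label_components",
    "count_components",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class FlockVisionError(Exception):
    """Base class for all errors raised by this package."""


class ImageIOError(FlockVisionError):
    """An image or mask file could not be read or written."""


class ConfigError(FlockVisionError):
    """Invalid configuration value or unknown option."""


class DetectionError(FlockVisionError):
    """A detection stage (Hough line, pipe segment) found nothing usable."""


class GeometryError(FlockVisionError):
    """Degenerate or inconsistent geometry (shape mismatch, zero-length line)."""


class FitError(FlockVisionError):
    """Conic fitting failed (degenerate points, non-elliptical conic)."""


class SelectionError(FlockVisionError):
    """Boundary point selection failed (not enough free boundary)."""


class MetricError(FlockVisionError):
    """Evaluation metric undefined for the given inputs (empty reference)."""


class PlacementError(FlockVisionError):
    """The scene generator could not place an object after bounded retries."""


# ---------------------------------------------------------------------------
# Array validation helpers
# ---------------------------------------------------------------------------

def as_rgb(image: np.ndarray) -> np.ndarray:
    """Validate and return an ``(H, W, 3)`` uint8 RGB array."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise GeometryError(
            f"expected (H, W, 3) uint8 RGB array, got shape {arr.shape} dtype {arr.dtype}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise GeometryError("image must have H >= 1 and W >= 1")
    return arr


def as_mask(mask: np.ndarray) -> np.ndarray:
    """Validate and return an ``(H, W)`` boolean mask array."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise GeometryError(f"expected 2-D mask, got shape {arr.shape}")
    if arr.dtype != bool:
        arr = arr.astype(bool)
    return arr


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an ``(H, W, 3)`` uint8 RGB array.

    Grayscale input is replicated to three channels; an alpha channel is
    dropped.  Raises :class:`ImageIOError` naming the path on any failure.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of exception types
        raise ImageIOError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        if info is not None:
            arr = (arr.astype(np.float64) * (255.0 / info.max)).round().astype(np.uint8)
        else:
            arr = np.clip(np.asarray(arr, dtype=np.float64) * 255.0, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return as_rgb(arr)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write an RGB image as PNG/TIFF/JPEG (format chosen by extension)."""
    iio.imwrite(Path(path), as_rgb(image))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG (0/255) as a boolean array.

    Any nonzero channel value above 127 counts as foreground; color input is
    reduced to its first channel.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ImageIOError(f"cannot read mask file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 127


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel PNG with foreground = 255."""
    arr = as_mask(mask)
    iio.imwrite(Path(path), (arr.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

@dataclass
class LabeledRegion:
    """One connected foreground component of a binary mask.

    Attributes
    ----------
    label:
        Positive integer; labels are 1..n in order of descending area, ties
        broken by the top-left-most (row-major first) foreground pixel.
    mask:
        Full-frame boolean mask of this region alone.
    area:
        Number of foreground pixels.
    centroid:
        ``(row, col)`` mean of the foreground pixel coordinates.
    boundary:
        ``(M, 2)`` float array of ``(row, col)`` points tracing the outer
        contour at the pixel-edge iso-level (sub-pixel, closed: the point
        after the last is the first again, with no duplicated consecutive
        points).
    """

    label: int
    mask: np.ndarray
    area: int
    centroid: tuple[float, float]
    boundary: np.ndarray = field(repr=False)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.mask.shape


def _outer_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed outer contour of a single region, duplicate end dropped."""
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:  # pragma: no cover - regions always have a contour
        return np.zeros((0, 2))
    longest = max(contours, key=len)
    pts = longest - 1.0  # undo padding offset
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ConfigError(f"connectivity must be 4 or 8, got {connectivity}")


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[LabeledRegion]:
    """Split a mask into connected regions ordered by descending area.

    Diagonal-touching pixels count as connected under the default
    connectivity 8, so fragments of one bird that only touch corner-to-corner
    stay a single region.  Ties in area are broken by the top-left-most
    foreground pixel (row-major scan order).
    """
    arr = as_mask(mask)
    labels, n = ndimage.label(arr, structure=_structure(connectivity))
    if n == 0:
        return []
    flat = labels.ravel()
    areas = np.bincount(flat)[1:]
    # first row-major occurrence per label = top-left-most pixel
    uniq, first = np.unique(flat, return_index=True)
    first_index = dict(zip(uniq.tolist(), first.tolist()))
    order = sorted(range(1, n + 1), key=lambda l: (-int(areas[l - 1]), first_index[l]))
    regions = []
    for new_label, old in enumerate(order, start=1):
        m = labels == old
        rows, cols = np.nonzero(m)
        regions.append(
            LabeledRegion(
                label=new_label,
                mask=m,
                area=int(areas[old - 1]),
                centroid=(float(rows.mean()), float(cols.mean())),
                boundary=_outer_boundary(m),
            )
        )
    return regions


def count_components(mask: np.ndarray, connectivity: int = 8) -> int:
    """Number of connected foreground components (cheap, no region objects)."""
    _, n = ndimage.label(as_mask(mask), structure=_structure(connectivity))
    return int(n)
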