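"""Water-pipe detection and removal.

The drinking pipe crosses the pen as the dominant straight feature of the
frame.  It is found with a Hough transform in (rho, theta) line-normal
parameterisation, keeping only the global accumulator maximum; the centerline
is then refined by a total-least-squares fit to the pixels captured around
the peak line, the pipe span is taken as the extremal extent of the
collinear foreground runs, and the pipe footprint is the band of pixels
within ``half_width`` (default 5 px) perpendicular distance of that
centerline.  Removing the band from a target mask is a pure set difference,
so it never adds pixels and is idempotent.

Angle convention: ``theta`` is the angle of the line *normal* in degrees in
``[-90, 90)``; a pixel at ``(row, col)`` lies on the line when
``col * cos(theta) + row * sin(theta) == rho``.  A vertical line at
``col = c`` therefore has ``theta = 0`` and ``rho = c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import DetectionError, GeometryError, as_mask

__all__ = [
    "HoughAccumulator",
    "HoughPeak",
    "LineSegment",
    "PipeModel",
    "hough_accumulate",
    "max_peak",
    "pipe_segment",
    "pipe_band",
    "remove_band",
    "segment_to_rho_theta",
    "line_difference",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HoughAccumulator:
    """Vote grid over the (rho, theta) line-parameter plane.

    ``counts[i, j]`` is the number of foreground pixels lying within
    ``rho_res / 2`` of the line ``(rhos[i], thetas[j])``.
    """

    counts: np.ndarray  # (n_rho, n_theta) int
    rhos: np.ndarray    # (n_rho,) signed perpendicular distances, px
    thetas: np.ndarray  # (n_theta,) normal angles, degrees in [-90, 90)
    rho_res: float


@dataclass(frozen=True)
class HoughPeak:
    """The retained accumulator maximum."""

    rho: float
    theta: float  # degrees, normal angle in [-90, 90)
    votes: int


@dataclass(frozen=True)
class LineSegment:
    """Directed segment with ``(row, col)`` float endpoints, start != end."""

    start: tuple[float, float]
    end: tuple[float, float]

    def __post_init__(self) -> None:
        if np.allclose(self.start, self.end):
            raise GeometryError("degenerate line segment: start == end")

    @property
    def length(self) -> float:
        return float(math.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))

    @property
    def direction(self) -> tuple[float, float]:
        """Unit ``(drow, dcol)`` from start to end."""
        L = self.length
        return ((self.end[0] - self.start[0]) / L, (self.end[1] - self.start[1]) / L)


@dataclass
class PipeModel:
    """Detected pipe: centerline, half-width and the rasterized band mask.

    The band contains every pixel whose perpendicular distance to the
    centerline is at most ``half_width`` and whose projection falls within
    the segment; when an endpoint reaches the frame border the band extends
    to that border.
    """

    centerline: LineSegment
    half_width: float
    band: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Hough transform
# ---------------------------------------------------------------------------

def hough_accumulate(
    mask: np.ndarray,
    rho_res: float = 1.0,
    theta_res: float = 1.0,
) -> HoughAccumulator:
    """Accumulate straight-line votes from the foreground of ``mask``.

    Each foreground pixel votes, for every theta bin, for the single rho bin
    whose line passes within ``rho_res / 2`` of the pixel center.
    Raises :class:`DetectionError` on an empty mask.
    """
    arr = as_mask(mask)
    rows, cols = np.nonzero(arr)
    if rows.size == 0:
        raise DetectionError("empty mask: no foreground pixels to vote")
    h, w = arr.shape
    thetas = np.arange(-90.0, 90.0, theta_res)
    rho_max = math.hypot(h - 1, w - 1)
    n_rho = int(math.ceil(rho_max / rho_res)) * 2 + 1
    rhos = (np.arange(n_rho) - n_rho // 2) * rho_res

    ang = np.deg2rad(thetas)
    cos_t, sin_t = np.cos(ang), np.sin(ang)
    counts = np.zeros((n_rho, thetas.size), dtype=np.int64)
    x = cols.astype(np.float64)
    y = rows.astype(np.float64)
    for j in range(thetas.size):
        rho = x * cos_t[j] + y * sin_t[j]
        idx = np.rint(rho / rho_res).astype(np.int64) + n_rho // 2
        counts[:, j] = np.bincount(idx, minlength=n_rho)
    return HoughAccumulator(counts=counts, rhos=rhos, thetas=thetas, rho_res=rho_res)


def max_peak(acc: HoughAccumulator) -> HoughPeak:
    """Return the single global accumulator maximum.

    Ties are broken by the smallest theta, then the smallest rho, so the
    result is deterministic.
    """
    counts = acc.counts
    if counts.size == 0:
        raise DetectionError("empty accumulator")
    best = counts.max()
    ri, tj = np.nonzero(counts == best)
    # order candidates by (theta, rho); grids are ascending so indices suffice
    k = np.lexsort((ri, tj))[0]
    return HoughPeak(rho=float(acc.rhos[ri[k]]), theta=float(acc.thetas[tj[k]]), votes=int(best))


# ---------------------------------------------------------------------------
# Centerline segment extraction
# ---------------------------------------------------------------------------

def _tls_line(points_rc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points: (centroid, unit direction)."""
    c = points_rc.mean(axis=0)
    d = points_rc - c
    # principal axis of the scatter matrix
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    u = vt[0]
    # canonical sign so the result does not depend on SVD sign conventions
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    return c, u


def pipe_segment(
    mask: np.ndarray,
    peak: HoughPeak,
    fill_gap: float = 20.0,
    min_length: float = 40.0,
    capture: float = 6.0,
    refine: bool = True,
) -> LineSegment:
    """Extract the pipe centerline span from the peak line.

    Foreground pixels within ``capture`` of the peak line are collected and
    (when ``refine`` is true) the centerline is re-estimated by a
    total-least-squares fit — the accumulator maximum alone is ambiguous for
    a band several pixels wide, whereas the centroid axis of its pixels is
    not.  Projections onto the centerline are split into collinear runs:
    gaps of at most ``fill_gap`` px are merged (birds overlapping the pipe
    interrupt it), runs shorter than ``min_length`` px are dropped, and the
    returned segment spans from the first surviving start to the last
    surviving end along the line direction.
    """
    arr = as_mask(mask)
    rows, cols = np.nonzero(arr)
    if rows.size == 0:
        raise DetectionError("empty mask")
    pts = np.stack([rows, cols], axis=1).astype(np.float64)

    ang = math.radians(peak.theta)
    n = np.array([math.sin(ang), math.cos(ang)])  # normal in (row, col)
    d = pts @ n - peak.rho
    sel = np.abs(d) <= capture
    if not sel.any():
        raise DetectionError("no pipe found: no pixels near the peak line")
    centroid = pts[sel].mean(axis=0)
    u = np.array([math.cos(ang), -math.sin(ang)])  # along-line dir in (row, col)
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    if refine:
        for _ in range(2):
            centroid, u = _tls_line(pts[sel])
            perp = (pts - centroid) @ np.array([-u[1], u[0]])
            sel = np.abs(perp) <= capture

    t = (pts[sel] - centroid) @ u
    t.sort()
    # split sorted projections into runs separated by gaps > fill_gap
    breaks = np.nonzero(np.diff(t) > fill_gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    spans = [(t[s], t[e]) for s, e in zip(starts, ends) if t[e] - t[s] >= min_length]
    if not spans:
        raise DetectionError(
            f"no pipe found: no collinear run of at least {min_length} px on the peak line"
        )
    t0, t1 = spans[0][0], spans[-1][1]
    p0 = centroid + t0 * u
    p1 = centroid + t1 * u
    return LineSegment(start=(float(p0[0]), float(p0[1])), end=(float(p1[0]), float(p1[1])))


# ---------------------------------------------------------------------------
# Band construction and removal
# ---------------------------------------------------------------------------

def pipe_band(
    segment: LineSegment,
    half_width: float = 5.0,
    frame_shape: tuple[int, int] = None,
    border_snap: float = 2.0,
) -> PipeModel:
    """Rasterize the pipe footprint around the centerline.

    The band holds all pixels with perpendicular distance <= ``half_width``
    to the centerline whose projection lies within the segment; a segment
    endpoint within ``border_snap`` px of a frame border extends the band to
    that border.  On axis-aligned lines the band is exactly
    ``2 * half_width + 1`` pixels wide.
    """
    if frame_shape is None:
        raise GeometryError("frame_shape is required to rasterize the band")
    h, w = frame_shape
    p0 = np.asarray(segment.start, dtype=np.float64)
    u = np.asarray(segment.direction, dtype=np.float64)
    L = segment.length

    rr, cc = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
    dr, dc = rr - p0[0], cc - p0[1]
    along = dr * u[0] + dc * u[1]
    perp = np.abs(dr * u[1] - dc * u[0])

    def _near_border(p: np.ndarray) -> bool:
        return (
            p[0] <= border_snap
            or p[1] <= border_snap
            or p[0] >= h - 1 - border_snap
            or p[1] >= w - 1 - border_snap
        )

    lo = -np.inf if _near_border(p0) else 0.0
    hi = np.inf if _near_border(np.asarray(segment.end)) else L
    band = (perp <= half_width) & (along >= lo) & (along <= hi)
    return PipeModel(centerline=segment, half_width=float(half_width), band=band)


def remove_band(mask: np.ndarray, pipe: PipeModel) -> np.ndarray:
    """Delete the pipe band from a mask (pure set difference)."""
    arr = as_mask(mask)
    if arr.shape != pipe.band.shape:
        raise GeometryError(
            f"shape mismatch: mask {arr.shape} vs pipe band {pipe.band.shape}"
        )
    return arr & ~pipe.band


# ---------------------------------------------------------------------------
# Line comparison helpers (used by the benchmark and tests)
# ---------------------------------------------------------------------------

def segment_to_rho_theta(segment: LineSegment) -> tuple[float, float]:
    """(rho, theta_deg) of the infinite line through a segment.

    theta is the normal angle in [-90, 90); rho may be negative.
    """
    dr, dc = segment.direction
    # normal (in x, y = col, row coordinates) perpendicular to direction
    nx, ny = -dr, dc
    theta = math.degrees(math.atan2(ny, nx))
    rho = segment.start[1] * nx + segment.start[0] * ny
    if theta >= 90.0:
        theta -= 180.0
        rho = -rho
    elif theta < -90.0:
        theta += 180.0
        rho = -rho
    return float(rho), float(theta)


def line_difference(a: LineSegment, b: LineSegment) -> tuple[float, float]:
    """(delta_theta_deg, delta_rho_px) between two infinite lines.

    Angles are compared modulo 180 degrees and rho signs are aligned before
    differencing, so the result is orientation-independent.
    """
    rho_a, th_a = segment_to_rho_theta(a)
    rho_b, th_b = segment_to_rho_theta(b)
    dth = th_a - th_b
    if dth > 90.0:
        dth -= 180.0
        rho_b = -rho_b
    elif dth < -90.0:
        dth += 180.0
        rho_b = -rho_b
    return abs(dth), abs(rho_a - rho_b)
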