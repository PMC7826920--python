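"""Occlusion classification and restoration.

After equipment removal an occluded bird appears in one of two ways:

* **TA (two areas)** — the pipe band split the bird into two components.
  Restoration is a morphological closing with a *linear* structuring element
  oriented perpendicular to the pipe centerline, applied only inside the
  pipe band dilated by a margin; the closing bridges the removed band
  between the two fragments and leaves everything outside the box untouched.
* **OA (one area)** — part of the bird is missing but one component remains.
  Restoration fits the unique conic through five points chosen on the free
  (non-occluded) part of the boundary, checks that it is an ellipse, and
  unions its rasterized interior with the observed region.

Both restorers are extensive (they never delete observed bird pixels).  The
method applies only when less than half the bird is occluded and the region
is a single bird — crowded multi-bird blobs are flagged, not restored.

The conic is written ``a x^2 + b y^2 + c x + d y + e xy + f = 0`` with
``x = col`` and ``y = row``; it is an ellipse iff ``e^2 - 4ab < 0``, and the
coefficients are normalized to ``a = 1`` (always possible for an ellipse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    FitError,
    GeometryError,
    LabeledRegion,
    SelectionError,
    as_mask,
    count_components,
)
from .pipe import PipeModel, pipe_band

__all__ = [
    "ConicCoefficients",
    "OcclusionCase",
    "StructuringElement",
    "classify_occlusion",
    "restore_ta",
    "fit_ellipse_5pt",
    "select_boundary_points",
    "rasterize_ellipse",
    "restore_oa",
]

_EIGHT = ndimage.generate_binary_structure(2, 2)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConicCoefficients:
    """Coefficients of ``a x^2 + b y^2 + c x + d y + e xy + f = 0``."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @property
    def discriminant(self) -> float:
        """``e^2 - 4ab``; negative for an ellipse."""
        return self.e**2 - 4.0 * self.a * self.b

    @property
    def is_ellipse(self) -> bool:
        return self.discriminant < 0

    def __call__(self, x, y):
        """Evaluate the conic polynomial at ``(x, y)`` (arrays allowed)."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        return (
            self.a * x**2 + self.b * y**2 + self.c * x + self.d * y + self.e * x * y + self.f
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f])

    def ellipse_params(self) -> tuple[float, float, float, float, float]:
        """Geometric parameters ``(cx, cy, semi_major, semi_minor, angle_deg)``.

        ``angle_deg`` is the orientation of the major axis, measured from the
        +x (column) axis toward +y (row).  Raises :class:`GeometryError` for
        a non-elliptical conic.
        """
        if not self.is_ellipse:
            raise GeometryError("conic is not an ellipse")
        a, b, c, d, e = self.a, self.b, self.c, self.d, self.e
        center = np.linalg.solve(np.array([[2 * a, e], [e, 2 * b]]), np.array([-c, -d]))
        cx, cy = float(center[0]), float(center[1])
        f0 = float(self(cx, cy))
        m = np.array([[a, e / 2.0], [e / 2.0, b]])
        vals, vecs = np.linalg.eigh(m)
        # ellipse: f0 and the eigenvalues have opposite signs
        semis = np.sqrt(-f0 / vals)
        order = np.argsort(semis)[::-1]  # major first
        semi_major, semi_minor = float(semis[order[0]]), float(semis[order[1]])
        v = vecs[:, order[0]]
        angle = math.degrees(math.atan2(v[1], v[0])) % 180.0
        return cx, cy, semi_major, semi_minor, angle


@dataclass
class OcclusionCase:
    """One occlusion decision for a bird-region (or region pair)."""

    kind: str  # TA | OA | none | crowded | unrestorable
    components: list[LabeledRegion]
    occluder: str | None
    estimated_occluded_fraction: float

    def __post_init__(self) -> None:
        if self.kind == "TA" and len(self.components) != 2:
            raise GeometryError("TA case requires exactly 2 components")
        if self.kind in ("OA", "none", "crowded", "unrestorable") and len(self.components) != 1:
            raise GeometryError(f"{self.kind} case requires exactly 1 component")


@dataclass(frozen=True)
class StructuringElement:
    """Linear (line-shaped) structuring element of odd length >= 3."""

    length: int
    angle_deg: float

    def __post_init__(self) -> None:
        if self.length < 3 or self.length % 2 == 0:
            raise GeometryError("structuring element length must be odd and >= 3")

    def footprint(self) -> np.ndarray:
        """Boolean array of the rasterized line, symmetric about its center."""
        half = self.length // 2
        a = math.radians(self.angle_deg)
        k = np.arange(-half, half + 1, dtype=np.float64)
        dc = np.rint(k * math.cos(a)).astype(int)
        dr = np.rint(k * math.sin(a)).astype(int)
        mr, mc = int(np.abs(dr).max()), int(np.abs(dc).max())
        fp = np.zeros((2 * mr + 1, 2 * mc + 1), dtype=bool)
        fp[dr + mr, dc + mc] = True
        return fp


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _touches(region_mask: np.ndarray, equipment_mask: np.ndarray) -> bool:
    dilated = ndimage.binary_dilation(region_mask, structure=_EIGHT)
    return bool((dilated & equipment_mask).any())


def classify_occlusion(
    regions: list[LabeledRegion],
    equipment: dict[str, np.ndarray],
    pipe: PipeModel | None,
    intact_area_estimate: float,
    crowd_factor: float = 1.6,
    max_fraction: float = 0.5,
) -> list[OcclusionCase]:
    """Assign each region (or region pair) an occlusion scenario.

    A pair of regions sitting on opposite sides of the pipe band with
    overlapping spans along the band is one TA case; a single region
    touching any equipment is OA; a region touching nothing is ``none``.  A
    region larger than ``crowd_factor`` times the single-bird area estimate
    is ``crowded`` (likely several birds merged), and an OA region estimated
    to be more than half occluded is ``unrestorable`` — both are reported
    but never restored.
    """
    cases: list[OcclusionCase] = []
    used: set[int] = set()

    # --- TA pairing across the pipe band ---------------------------------
    if pipe is not None:
        u = np.asarray(pipe.centerline.direction)
        nvec = np.array([-u[1], u[0]])
        p0 = np.asarray(pipe.centerline.start)
        info = []
        for idx, reg in enumerate(regions):
            if not _touches(reg.mask, pipe.band):
                info.append(None)
                continue
            rows, cols = np.nonzero(reg.mask)
            pts = np.stack([rows, cols], axis=1) - p0
            along = pts @ u
            side = float(np.mean(pts @ nvec))
            info.append((side, float(along.min()), float(along.max())))
        order = sorted(
            (i for i, v in enumerate(info) if v is not None),
            key=lambda i: -regions[i].area,
        )
        for i in order:
            if i in used or info[i] is None:
                continue
            best_j, best_overlap = None, 0.0
            for j in order:
                if j == i or j in used or info[j] is None:
                    continue
                si, li0, li1 = info[i]
                sj, lj0, lj1 = info[j]
                if si * sj >= 0:  # same side of the band
                    continue
                overlap = min(li1, lj1) - max(li0, lj0)
                if overlap > 0 and overlap > best_overlap:
                    best_j, best_overlap = j, overlap
            if best_j is not None:
                pair_area = regions[i].area + regions[best_j].area
                frac = max(0.0, 1.0 - pair_area / intact_area_estimate)
                cases.append(
                    OcclusionCase(
                        kind="TA",
                        components=[regions[i], regions[best_j]],
                        occluder="pipe",
                        estimated_occluded_fraction=frac,
                    )
                )
                used.update({i, best_j})

    # --- singleton regions ------------------------------------------------
    for idx, reg in enumerate(regions):
        if idx in used:
            continue
        if reg.area > crowd_factor * intact_area_estimate:
            cases.append(OcclusionCase("crowded", [reg], None, 0.0))
            continue
        occluder = None
        best = 0
        for name, mask in equipment.items():
            if _touches(reg.mask, mask):
                overlap = int((ndimage.binary_dilation(reg.mask, structure=_EIGHT) & mask).sum())
                if overlap > best:
                    occluder, best = name, overlap
        if occluder is None:
            cases.append(OcclusionCase("none", [reg], None, 0.0))
            continue
        frac = max(0.0, 1.0 - reg.area / intact_area_estimate)
        kind = "unrestorable" if frac >= max_fraction else "OA"
        cases.append(OcclusionCase(kind, [reg], occluder, frac))
    return cases


# ---------------------------------------------------------------------------
# TA restoration: oriented linear closing across the pipe band
# ---------------------------------------------------------------------------

def restore_ta(
    mask: np.ndarray,
    pipe: PipeModel,
    se_margin: int = 5,
    full_output: bool = False,
):
    """Bridge pipe-split bird fragments by a linear closing across the band.

    A morphological closing with a line-shaped structuring element of length
    ``2 * (half_width + se_margin) + 1``, oriented perpendicular to the pipe
    centerline, is applied to the mask; only pixels inside the pipe band
    dilated by ``se_margin`` may be added, so the mask is unchanged outside
    that box and the operation is extensive and idempotent.  Fragments whose
    gap exceeds the element length stay separate; with ``full_output`` the
    returned info dict flags whether the component count dropped.
    """
    arr = as_mask(mask)
    if arr.shape != pipe.band.shape:
        raise GeometryError(f"shape mismatch: mask {arr.shape} vs pipe band {pipe.band.shape}")
    half_width = pipe.half_width
    length = 2 * int(round(half_width + se_margin)) + 1
    dr, dc = pipe.centerline.direction
    axis_angle = math.degrees(math.atan2(dr, dc))
    se = StructuringElement(length=length, angle_deg=axis_angle + 90.0)
    fp = se.footprint()

    box = pipe_band(pipe.centerline, half_width + se_margin, arr.shape).band
    pad = max(fp.shape)
    padded = np.pad(arr, pad)
    closed = ndimage.binary_closing(padded, structure=fp)[pad:-pad, pad:-pad]
    out = arr | (closed & box)
    if not full_output:
        return out
    n_before = count_components(arr)
    n_after = count_components(out)
    info = {
        "components_before": n_before,
        "components_after": n_after,
        "reconnected": n_after < n_before,
        "se_length": length,
        "se_angle_deg": se.angle_deg,
    }
    return out, info


# ---------------------------------------------------------------------------
# Five-point exact conic fit
# ---------------------------------------------------------------------------

def fit_ellipse_5pt(points) -> ConicCoefficients:
    """Exact conic through 5 distinct points, validated as an ellipse.

    The conic is the null space of the 5 x 6 design matrix on the monomials
    ``(x^2, y^2, x, y, xy, 1)``.  Raises :class:`FitError` for a
    rank-deficient point set ("degenerate point set") or when the unique
    conic is not an ellipse ("not an ellipse").  Coefficients are returned
    in ``a = 1`` normalization.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape != (5, 2):
        raise FitError(f"exactly 5 (x, y) points required, got shape {pts.shape}")
    x, y = pts[:, 0], pts[:, 1]
    m = np.column_stack([x**2, y**2, x, y, x * y, np.ones(5)])
    _, s, vt = np.linalg.svd(m)
    if s[0] == 0 or s[4] <= 1e-10 * s[0]:
        raise FitError("degenerate point set")
    coef = vt[-1]
    a, b, c, d, e, f = coef
    if e**2 - 4.0 * a * b >= 0:
        raise FitError("not an ellipse")
    coef = coef / a  # ellipse implies a != 0
    return ConicCoefficients(*map(float, coef))


# ---------------------------------------------------------------------------
# Boundary point selection
# ---------------------------------------------------------------------------

def _arc_interpolate(poly: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Points at the given arc-length positions along an open polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty((targets.size, 2))
    for k, t in enumerate(targets):
        j = int(np.searchsorted(cum, t, side="right")) - 1
        j = min(max(j, 0), len(poly) - 2)
        denom = cum[j + 1] - cum[j]
        w = 0.0 if denom <= 0 else (t - cum[j]) / denom
        out[k] = poly[j] * (1 - w) + poly[j + 1] * w
    return out


def _admissible_boundary(
    region: LabeledRegion, occluder: np.ndarray, exclusion_px: float
) -> np.ndarray:
    """Boolean flag per boundary vertex: farther than exclusion_px from occluder."""
    boundary = region.boundary
    occ = as_mask(occluder)
    if not occ.any():
        return np.ones(len(boundary), dtype=bool)
    dist = ndimage.distance_transform_edt(~occ)
    rr = np.clip(np.rint(boundary[:, 0]).astype(int), 0, occ.shape[0] - 1)
    cc = np.clip(np.rint(boundary[:, 1]).astype(int), 0, occ.shape[1] - 1)
    return dist[rr, cc] > exclusion_px


def select_boundary_points(
    region: LabeledRegion,
    occluder: np.ndarray,
    n: int = 5,
    exclusion_px: float = 3.0,
) -> np.ndarray:
    """Deterministic equal-arc-length points on the free boundary.

    Returns an ``(n, 2)`` array of ``(x, y)`` = ``(col, row)`` points.  On a
    fully free boundary the points are spaced one n-th of the perimeter
    apart; otherwise the longest boundary arc farther than ``exclusion_px``
    from the occluder is used and points sit at ``(i + 1/2) / n`` of its
    length.  Raises :class:`SelectionError` when the free arc is too short.
    """
    boundary = region.boundary
    if len(boundary) < n:
        raise SelectionError("insufficient free boundary")
    ok = _admissible_boundary(region, occluder, exclusion_px)
    if int(ok.sum()) < n:
        raise SelectionError("insufficient free boundary")

    if ok.all():
        closed = np.vstack([boundary, boundary[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        perimeter = float(seg.sum())
        targets = np.arange(n) * perimeter / n
        pts_rc = _arc_interpolate(closed, targets)
    else:
        # rotate so the cyclic sequence starts just after an occluded stretch
        start = int(np.nonzero(~ok)[0][0])
        order = np.roll(np.arange(len(boundary)), -start)
        ok_r = ok[order]
        b_r = boundary[order]
        # contiguous admissible runs in the rotated (now non-cyclic) order
        runs = []
        i = 0
        while i < len(ok_r):
            if ok_r[i]:
                j = i
                while j < len(ok_r) and ok_r[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        def _run_length(run):
            i0, j0 = run
            arc = b_r[i0:j0]
            return float(np.linalg.norm(np.diff(arc, axis=0), axis=1).sum())
        best = max(runs, key=_run_length)
        arc = b_r[best[0]: best[1]]
        if len(arc) < n:
            raise SelectionError("insufficient free boundary")
        total = _run_length(best)
        if total <= 0:
            raise SelectionError("insufficient free boundary")
        targets = (np.arange(n) + 0.5) * total / n
        pts_rc = _arc_interpolate(arc, targets)
    return pts_rc[:, ::-1].copy()  # (row, col) -> (x, y)


# ---------------------------------------------------------------------------
# Ellipse rasterization and OA restoration
# ---------------------------------------------------------------------------

def rasterize_ellipse(conic: ConicCoefficients, frame_shape: tuple[int, int]) -> np.ndarray:
    """Interior mask of an ellipse conic, clipped to the frame.

    A pixel belongs to the interior when the conic polynomial evaluated at
    its center is <= 0 (with the leading coefficient made positive).
    """
    if not conic.is_ellipse:
        raise GeometryError("conic is not an ellipse")
    coef = conic.as_array()
    if coef[0] < 0:
        coef = -coef
    q = ConicCoefficients(*coef)
    cx, cy, smaj, _, _ = q.ellipse_params()
    h, w = frame_shape
    r0 = max(0, int(math.floor(cy - smaj - 1)))
    r1 = min(h, int(math.ceil(cy + smaj + 1)) + 1)
    c0 = max(0, int(math.floor(cx - smaj - 1)))
    c1 = min(w, int(math.ceil(cx + smaj + 1)) + 1)
    out = np.zeros((h, w), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    rr, cc = np.meshgrid(np.arange(r0, r1, dtype=np.float64),
                         np.arange(c0, c1, dtype=np.float64), indexing="ij")
    out[r0:r1, c0:c1] = q(cc, rr) <= 0
    return out


def restore_oa(
    region: LabeledRegion,
    occluder: np.ndarray,
    frame_shape: tuple[int, int],
    *,
    n_points: int = 5,
    exclusion_px: float = 3.0,
    mode: str = "deterministic",
    m_subsets: int = 25,
    subset_seed: int = 0,
    max_area_ratio: float = 2.5,
    full_output: bool = False,
):
    """Complete a partially occluded bird with a fitted ellipse.

    The output is the union of the observed region and the rasterized fitted
    ellipse — restoration never deletes observed bird pixels.  ``mode``
    selects the point choice: ``"deterministic"`` uses equal-arc-length
    points on the free boundary; ``"robust"`` draws ``m_subsets`` seeded
    5-point subsets of the free boundary and keeps the ellipse with the
    smallest mean absolute conic residual over the whole free boundary.

    Because less than half the bird may be occluded, a fitted ellipse larger
    than ``max_area_ratio`` times the observed region is geometrically
    implausible and rejected with :class:`FitError` (callers downgrade the
    case to unrestorable).
    """
    if mode not in ("deterministic", "robust"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "deterministic":
        pts = select_boundary_points(region, occluder, n=n_points, exclusion_px=exclusion_px)
        conic = fit_ellipse_5pt(pts)
    else:
        ok = _admissible_boundary(region, occluder, exclusion_px)
        idx = np.nonzero(ok)[0]
        if idx.size < n_points:
            raise SelectionError("insufficient free boundary")
        free = region.boundary[idx][:, ::-1]  # (x, y)
        rng = np.random.default_rng(subset_seed)
        best_conic, best_score = None, np.inf
        for _ in range(m_subsets):
            sub = free[np.sort(rng.choice(idx.size, size=n_points, replace=False))]
            try:
                cand = fit_ellipse_5pt(sub)
            except FitError:
                continue
            coef = cand.as_array()
            coef = coef / np.linalg.norm(coef)
            resid = np.abs(
                coef[0] * free[:, 0] ** 2 + coef[1] * free[:, 1] ** 2 + coef[2] * free[:, 0]
                + coef[3] * free[:, 1] + coef[4] * free[:, 0] * free[:, 1] + coef[5]
            ).mean()
            if resid < best_score:
                best_conic, best_score = cand, resid
        if best_conic is None:
            raise FitError("no valid ellipse among sampled subsets")
        conic = best_conic

    ellipse = rasterize_ellipse(conic, frame_shape)
    if int(ellipse.sum()) > max_area_ratio * region.area:
        raise FitError(
            "implausible ellipse: fitted area exceeds "
            f"{max_area_ratio:g}x the observed region"
        )
    out = region.mask | ellipse
    if full_output:
        return out, conic
    return out
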