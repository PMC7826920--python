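"""Shared fixtures and independent brute-force oracles for the test suite.

The oracles here deliberately avoid the package's own code paths (and the
vectorized numpy tricks they use), so that agreement between the two is
meaningful.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[set]:
    """BFS connected components; returns a list of sets of (row, col)."""
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    rr, cc = q.popleft()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            q.append((nr, nc))
                comps.append(comp)
    return comps


def brute_hough_votes(mask: np.ndarray, rho: float, theta_deg: float,
                      rho_res: float = 1.0) -> int:
    """Count foreground pixels within rho_res/2 of the line (rho, theta)."""
    votes = 0
    a = math.radians(theta_deg)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                d = c * math.cos(a) + r * math.sin(a) - rho
                if abs(d) <= rho_res / 2.0 + 1e-12:
                    votes += 1
    return votes


def conic_from_params(cx: float, cy: float, a_semi: float, b_semi: float,
                      angle_deg: float) -> np.ndarray:
    """Closed-form implicit conic (a, b, c, d, e, f) of a parametric ellipse.

    Expansion of ((x-cx) cos p + (y-cy) sin p)^2 / A^2
               + (-(x-cx) sin p + (y-cy) cos p)^2 / B^2 = 1,
    normalized to a = 1.  Independent of the package's SVD fit.
    """
    p = math.radians(angle_deg)
    ca, sa = math.cos(p), math.sin(p)
    ia, ib = 1.0 / a_semi**2, 1.0 / b_semi**2
    a = ca**2 * ia + sa**2 * ib
    b = sa**2 * ia + ca**2 * ib
    e = 2.0 * ca * sa * (ia - ib)
    c = -2.0 * a * cx - e * cy
    d = -2.0 * b * cy - e * cx
    f = a * cx**2 + b * cy**2 + e * cx * cy - 1.0
    coef = np.array([a, b, c, d, e, f])
    return coef / coef[0]


def ellipse_points(cx, cy, a_semi, b_semi, angle_deg, param_angles_deg) -> np.ndarray:
    """(n, 2) (x, y) points on the parametric ellipse at given parameter angles."""
    p = math.radians(angle_deg)
    t = np.deg2rad(np.asarray(param_angles_deg, dtype=float))
    x0, y0 = a_semi * np.cos(t), b_semi * np.sin(t)
    x = cx + x0 * math.cos(p) - y0 * math.sin(p)
    y = cy + x0 * math.sin(p) + y0 * math.cos(p)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
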