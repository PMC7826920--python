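"""Seeded synthetic pen scenes with pixel-perfect ground truth.

The generator emulates the top-view broiler-pen setting the pipeline is built
for: elliptical birds with irregular outlines on a litter-colored floor, a
straight drinking pipe crossing the frame, a red water-pressure regulator
disk at the pipe end, and circular feeders.  Equipment is drawn on top of the
birds, and every bird carries both its intact (pre-occlusion) mask and its
occluded mask, so restoration stages can be scored against exact ground
truth without any recorded video.

Bird outlines are ellipses perturbed by a smooth low-order radial Fourier
series (amplitude ``boundary_noise_px``), because real bird silhouettes are
not exact ellipses and a perfect-ellipse fixture would make the ellipse-fit
restoration trivially perfect.

Occlusion labels follow the component count of the occluded mask: a bird
split into two areas by the pipe is **TA**, a bird with one remaining area
and nonzero occluded area is **OA**, an untouched bird is **none**.
Everything is a pure function of the configuration (including its seed), so
scenes are bit-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import ConfigError, PlacementError, count_components, save_image, save_mask
from .pipe import LineSegment, PipeModel, pipe_band

__all__ = [
    "SceneConfig",
    "SceneGroundTruth",
    "generate_scene",
    "make_ta_fixture",
    "make_oa_fixture",
    "export_scene",
]

_EIGHT = ndimage.generate_binary_structure(2, 2)


# ---------------------------------------------------------------------------
# Configuration and ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Parameters of one synthetic pen scene.

    Geometry is in pixels; colors are RGB triples.  ``frame_shape`` is
    ``(H, W)``; the default is a half-scale pen frame (the recording setup
    this emulates used 1440 x 1080 frames, i.e. ``(1080, 1440)`` as
    ``(H, W)``, which is also supported).
    """

    frame_shape: tuple[int, int] = (540, 720)
    n_birds: int = 8
    bird_semiaxes_range: tuple[float, float] = (25.0, 60.0)  # semi-major axis
    bird_aspect_range: tuple[float, float] = (0.5, 0.8)
    boundary_noise_px: float = 2.0
    pipe_present: bool = True
    pipe_angle_deg: float | None = None  # None -> random orientation
    pipe_half_width: float = 5.0
    regulator_present: bool = True
    regulator_radius: float = 12.0
    feeders: tuple = (((135.0, 180.0), 36.0), ((405.0, 540.0), 36.0))
    floor_color: tuple[int, int, int] = (150, 120, 90)
    bird_color: tuple[int, int, int] = (230, 228, 220)
    pipe_color: tuple[int, int, int] = (90, 90, 95)
    regulator_color: tuple[int, int, int] = (200, 30, 30)
    feeder_color: tuple[int, int, int] = (120, 120, 125)
    crowding_allowed: bool = False
    seed: int = 0

    def validate(self) -> None:
        h, w = self.frame_shape
        if h < 1 or w < 1:
            raise ConfigError("frame_shape must be positive")
        lo, hi = self.bird_semiaxes_range
        alo, ahi = self.bird_aspect_range
        if not (0 < lo <= hi) or not (0 < alo <= ahi <= 1):
            raise ConfigError("bird size/aspect ranges must be positive and ordered")
        if self.boundary_noise_px < 0 or self.pipe_half_width <= 0:
            raise ConfigError("noise amplitude and pipe half-width must be non-negative")
        if self.n_birds < 0:
            raise ConfigError("n_birds must be >= 0")
        margin = hi + self.boundary_noise_px + 2
        if min(h, w) <= 2 * margin and self.n_birds > 0:
            raise ConfigError("frame too small for the requested bird sizes")


@dataclass
class SceneGroundTruth:
    """Rendered scene plus exact per-bird and per-equipment masks."""

    image: np.ndarray
    intact_bird_masks: list[np.ndarray]
    equipment_masks: dict[str, np.ndarray]
    occluded_bird_masks: list[np.ndarray]
    occlusion_labels: list[str]  # per bird: none | TA | OA | crowded
    pipe_truth: PipeModel | None
    config: SceneConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _noisy_ellipse_mask(
    frame_shape: tuple[int, int],
    center: tuple[float, float],
    a_semi: float,
    b_semi: float,
    angle_deg: float,
    noise_amp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ellipse with a smooth radial boundary perturbation, as a frame mask."""
    h, w = frame_shape
    # perturbation: low-order Fourier series with total amplitude noise_amp
    raw = rng.uniform(0.3, 1.0, size=3)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=3)
    amps = raw / raw.sum() * noise_amp if noise_amp > 0 else np.zeros(3)

    reach = max(a_semi, b_semi) + noise_amp + 1.0
    r0 = max(0, int(math.floor(center[0] - reach)))
    r1 = min(h, int(math.ceil(center[0] + reach)) + 1)
    c0 = max(0, int(math.floor(center[1] - reach)))
    c1 = min(w, int(math.ceil(center[1] + reach)) + 1)

    rr, cc = np.meshgrid(np.arange(r0, r1, dtype=np.float64),
                         np.arange(c0, c1, dtype=np.float64), indexing="ij")
    y = rr - center[0]
    x = cc - center[1]
    phi_rot = math.radians(angle_deg)
    xr = x * math.cos(phi_rot) + y * math.sin(phi_rot)
    yr = -x * math.sin(phi_rot) + y * math.cos(phi_rot)
    rho = np.hypot(xr / a_semi, yr / b_semi)
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    delta = np.zeros_like(r)
    for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
        delta += amp * np.cos(k * phi + ph)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ell = np.where(rho > 0, r / rho, np.inf)  # ellipse radius along phi
    window = r <= r_ell + delta
    out = np.zeros((h, w), dtype=bool)
    out[r0:r1, c0:c1] = window
    return out


def _clip_line_to_frame(
    anchor: tuple[float, float], angle_deg: float, frame_shape: tuple[int, int]
) -> LineSegment:
    """Segment of the infinite line (through anchor, at the pipe-axis angle)
    clipped to the frame rectangle."""
    h, w = frame_shape
    a = math.radians(angle_deg)
    d = np.array([math.sin(a), math.cos(a)])  # (drow, dcol); 0 deg -> horizontal
    p = np.asarray(anchor, dtype=np.float64)
    ts = []
    for axis, bound in ((0, 0.0), (0, h - 1.0), (1, 0.0), (1, w - 1.0)):
        if abs(d[axis]) > 1e-12:
            t = (bound - p[axis]) / d[axis]
            q = p + t * d
            if -1e-9 <= q[0] <= h - 1 + 1e-9 and -1e-9 <= q[1] <= w - 1 + 1e-9:
                ts.append(t)
    if len(ts) < 2:
        raise PlacementError("pipe line does not cross the frame")
    t0, t1 = min(ts), max(ts)
    if t1 - t0 < 1e-9:
        raise PlacementError("pipe line degenerate within the frame")
    q0, q1 = p + t0 * d, p + t1 * d
    q0 = np.clip(q0, [0, 0], [h - 1, w - 1])
    q1 = np.clip(q1, [0, 0], [h - 1, w - 1])
    return LineSegment(start=(float(q0[0]), float(q0[1])), end=(float(q1[0]), float(q1[1])))


def _disk(frame_shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    h, w = frame_shape
    r0 = max(0, int(math.floor(center[0] - radius)))
    r1 = min(h, int(math.ceil(center[0] + radius)) + 1)
    c0 = max(0, int(math.floor(center[1] - radius)))
    c1 = min(w, int(math.ceil(center[1] + radius)) + 1)
    out = np.zeros((h, w), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    rr, cc = np.meshgrid(np.arange(r0, r1, dtype=np.float64),
                         np.arange(c0, c1, dtype=np.float64), indexing="ij")
    out[r0:r1, c0:c1] = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return out


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    from .core import _outer_boundary

    return _outer_boundary(mask)


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def generate_scene(config: SceneConfig) -> SceneGroundTruth:
    """Render a pen scene and its exact ground truth.

    Deterministic function of the config (including its seed).  Raises
    :class:`PlacementError` naming the bird index when rejection sampling
    cannot place a bird after 1000 attempts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_shape
    frame = (h, w)

    # --- equipment -------------------------------------------------------
    equipment: dict[str, np.ndarray] = {}
    pipe_truth = None
    if config.pipe_present:
        angle = (
            float(rng.uniform(0.0, 180.0))
            if config.pipe_angle_deg is None
            else float(config.pipe_angle_deg)
        )
        anchor = (
            float(rng.uniform(0.3 * h, 0.7 * h)),
            float(rng.uniform(0.3 * w, 0.7 * w)),
        )
        seg = _clip_line_to_frame(anchor, angle, frame)
        pipe_truth = pipe_band(seg, config.pipe_half_width, frame)
        equipment["pipe"] = pipe_truth.band
        if config.regulator_present:
            u = np.asarray(seg.direction)
            center = np.asarray(seg.end) - u * (config.regulator_radius + 2.0)
            equipment["regulator"] = _disk(frame, tuple(center), config.regulator_radius)
    elif config.regulator_present:
        center = (float(rng.uniform(0.2 * h, 0.8 * h)), float(rng.uniform(0.2 * w, 0.8 * w)))
        equipment["regulator"] = _disk(frame, center, config.regulator_radius)
    for i, (center, radius) in enumerate(config.feeders):
        equipment[f"feeder_{i}"] = _disk(frame, tuple(center), float(radius))

    equip_union = np.zeros(frame, dtype=bool)
    for m in equipment.values():
        equip_union |= m

    # --- birds (rejection sampling) --------------------------------------
    intact: list[np.ndarray] = []
    occupied = np.zeros(frame, dtype=bool)  # union of intact masks, dilated
    for i in range(config.n_birds):
        placed = False
        for _ in range(1000):
            a_semi = float(rng.uniform(*config.bird_semiaxes_range))
            aspect = float(rng.uniform(*config.bird_aspect_range))
            b_semi = a_semi * aspect
            phi = float(rng.uniform(0.0, 180.0))
            reach = a_semi + config.boundary_noise_px + 2.0
            cr = float(rng.uniform(reach, h - 1 - reach))
            cc = float(rng.uniform(reach, w - 1 - reach))
            m = _noisy_ellipse_mask(frame, (cr, cc), a_semi, b_semi, phi,
                                    config.boundary_noise_px, rng)
            if not config.crowding_allowed and (m & occupied).any():
                continue
            intact.append(m)
            if not config.crowding_allowed:
                occupied |= ndimage.binary_dilation(m, structure=_EIGHT, iterations=2)
            else:
                occupied |= m
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place bird {i} after 1000 attempts")

    # --- occlusion ground truth ------------------------------------------
    occluded = [m & ~equip_union for m in intact]
    labels: list[str] = []
    for i, (m, occ) in enumerate(zip(intact, occluded)):
        others = [intact[j] for j in range(len(intact)) if j != i]
        if config.crowding_allowed and any((m & o).any() for o in others):
            labels.append("crowded")
        elif occ.sum() == m.sum():
            labels.append("none")
        elif count_components(occ) == 1:
            labels.append("OA")
        else:
            labels.append("TA")

    # --- rendering --------------------------------------------------------
    img = np.empty((h, w, 3), dtype=np.int16)
    floor_noise = rng.integers(-6, 7, size=frame, dtype=np.int16)
    for ch in range(3):
        img[:, :, ch] = int(config.floor_color[ch]) + floor_noise
    bird_noise = rng.integers(-8, 9, size=frame, dtype=np.int16)
    for m in intact:
        for ch in range(3):
            img[:, :, ch][m] = int(config.bird_color[ch]) + bird_noise[m]
    draw_order = [k for k in equipment if k.startswith("feeder")]
    if "pipe" in equipment:
        draw_order.append("pipe")
    if "regulator" in equipment:
        draw_order.append("regulator")
    colors = {
        "pipe": config.pipe_color,
        "regulator": config.regulator_color,
    }
    for name in draw_order:
        color = colors.get(name, config.feeder_color)
        for ch in range(3):
            img[:, :, ch][equipment[name]] = int(color[ch])
    image = np.clip(img, 0, 255).astype(np.uint8)

    return SceneGroundTruth(
        image=image,
        intact_bird_masks=intact,
        equipment_masks=equipment,
        occluded_bird_masks=occluded,
        occlusion_labels=labels,
        pipe_truth=pipe_truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Benchmark fixtures
# ---------------------------------------------------------------------------

def _default_fixture_frame(semiaxes_range, boundary_noise_px, extra=40.0) -> tuple[int, int]:
    side = int(math.ceil(2.0 * (semiaxes_range[1] + boundary_noise_px) + extra))
    return (side, side)


def _sample_bird(
    frame: tuple[int, int],
    rng: np.random.Generator,
    semiaxes_range,
    aspect_range,
    boundary_noise_px,
) -> tuple[np.ndarray, float, float]:
    h, w = frame
    a_semi = float(rng.uniform(*semiaxes_range))
    aspect = float(rng.uniform(*aspect_range))
    b_semi = a_semi * aspect
    phi = float(rng.uniform(0.0, 180.0))
    center = (h / 2.0 + float(rng.uniform(-5, 5)), w / 2.0 + float(rng.uniform(-5, 5)))
    mask = _noisy_ellipse_mask(frame, center, a_semi, b_semi, phi, boundary_noise_px, rng)
    return mask, b_semi, phi


def make_ta_fixture(
    seed,
    n: int,
    *,
    semiaxes_range: tuple[float, float] = (25.0, 60.0),
    aspect_range: tuple[float, float] = (0.5, 0.8),
    boundary_noise_px: float = 2.0,
    half_width: float = 5.0,
    frame_shape: tuple[int, int] | None = None,
    max_attempts: int = 200,
) -> list[tuple[np.ndarray, np.ndarray, PipeModel]]:
    """Fixtures where one bird is split into exactly two areas by the pipe.

    Returns ``n`` tuples ``(intact_mask, occluded_mask, pipe_truth)``.  The
    pipe band passes through the bird interior; samples where the band fails
    to produce two components of at least 10 px each (band too close to the
    rim, or wider than the bird) are rejected and redrawn, so the two-area
    postcondition always holds.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    frame = frame_shape or _default_fixture_frame(semiaxes_range, boundary_noise_px,
                                                  extra=4.0 * half_width + 24.0)
    fixtures = []
    for i in range(n):
        for _ in range(max_attempts):
            bird, b_semi, _ = _sample_bird(frame, rng, semiaxes_range, aspect_range,
                                           boundary_noise_px)
            rows, cols = np.nonzero(bird)
            center = np.array([rows.mean(), cols.mean()])
            psi = float(rng.uniform(0.0, 180.0))
            a = math.radians(psi)
            normal = np.array([math.cos(a), -math.sin(a)])  # perp to pipe axis
            offset = float(rng.uniform(-0.6, 0.6)) * b_semi
            anchor = center + offset * normal
            seg = _clip_line_to_frame(tuple(anchor), psi, frame)
            model = pipe_band(seg, half_width, frame)
            occ = bird & ~model.band
            lab, k = ndimage.label(occ, structure=_EIGHT)
            if k == 2 and np.bincount(lab.ravel())[1:].min() >= 10:
                fixtures.append((bird, occ, model))
                break
        else:
            raise PlacementError(f"could not build TA fixture {i} after {max_attempts} attempts")
    return fixtures


def make_oa_fixture(
    seed,
    n: int,
    occluded_fraction_range: tuple[float, float] = (0.05, 0.45),
    *,
    semiaxes_range: tuple[float, float] = (25.0, 60.0),
    aspect_range: tuple[float, float] = (0.5, 0.8),
    boundary_noise_px: float = 2.0,
    frame_shape: tuple[int, int] | None = None,
    max_fraction: float = 0.5,
    max_attempts: int = 200,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Fixtures where a single-area bite is removed from an intact bird.

    Emulates the artificial-occlusion evaluation protocol: a disk-shaped
    bite centered on a random boundary point removes a controlled fraction
    of the bird's area, leaving one connected component.  Returns ``n``
    tuples ``(intact_mask, occluded_mask, bite_mask)`` with the removed
    fraction ``1 - |occluded| / |intact|`` inside ``occluded_fraction_range``.

    ``max_fraction`` (default 0.5) enforces the method's applicability rule
    that less than half the bird may be occluded; pass a larger value to
    lift it deliberately.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    lo, hi = occluded_fraction_range
    if hi >= 1.0:
        raise ConfigError(f"occluded fraction upper bound {hi} must be < 1")
    if lo < 0 or lo > hi:
        raise ConfigError(f"invalid occluded_fraction_range {occluded_fraction_range}")
    if hi > max_fraction:
        raise ConfigError(
            f"occluded fraction upper bound {hi} exceeds the applicability rule "
            f"(< {max_fraction:.0%} of the bird area may be occluded)"
        )
    rng = np.random.default_rng(seed)
    frame = frame_shape or _default_fixture_frame(semiaxes_range, boundary_noise_px, extra=12.0)
    fixtures = []
    for i in range(n):
        for _ in range(max_attempts):
            bird, _, _ = _sample_bird(frame, rng, semiaxes_range, aspect_range,
                                      boundary_noise_px)
            area = float(bird.sum())
            if hi <= 0.0:
                fixtures.append((bird, bird.copy(), np.zeros(frame, dtype=bool)))
                break
            pad = min(0.02, (hi - lo) / 4.0)
            target = float(rng.uniform(lo + pad, hi - pad)) if hi > lo else lo
            boundary = _boundary_points(bird)
            bc = boundary[int(rng.integers(len(boundary)))]
            r_lo, r_hi = 1.0, 2.0 * semiaxes_range[1]
            bite = None
            for _ in range(40):
                r_mid = 0.5 * (r_lo + r_hi)
                d = _disk(frame, (float(bc[0]), float(bc[1])), r_mid)
                frac = float((bird & d).sum()) / area
                if abs(frac - target) <= 0.01:
                    bite = bird & d
                    break
                if frac < target:
                    r_lo = r_mid
                else:
                    r_hi = r_mid
            if bite is None:
                continue
            occ = bird & ~bite
            frac = 1.0 - float(occ.sum()) / area
            if lo < frac < hi and count_components(occ) == 1:
                fixtures.append((bird, occ, bite))
                break
        else:
            raise PlacementError(f"could not build OA fixture {i} after {max_attempts} attempts")
    return fixtures


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_scene(scene: SceneGroundTruth, out_dir: str | Path) -> Path:
    """Write a scene as PNG image + per-mask PNGs + a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_image(scene.image, out / "scene.png")
    for i, m in enumerate(scene.intact_bird_masks):
        save_mask(m, out / f"bird_{i}_intact.png")
    for i, m in enumerate(scene.occluded_bird_masks):
        save_mask(m, out / f"bird_{i}_occluded.png")
    for name, m in scene.equipment_masks.items():
        save_mask(m, out / f"equipment_{name}.png")
    manifest = {
        "frame_shape": list(scene.image.shape[:2]),
        "n_birds": len(scene.intact_bird_masks),
        "occlusion_labels": scene.occlusion_labels,
        "equipment": sorted(scene.equipment_masks),
        "config": asdict(scene.config) if scene.config is not None else None,
    }
    if scene.pipe_truth is not None:
        manifest["pipe"] = {
            "start": list(scene.pipe_truth.centerline.start),
            "end": list(scene.pipe_truth.centerline.end),
            "half_width": scene.pipe_truth.half_width,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
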