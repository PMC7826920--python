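"""Occlusion classification, TA closing, five-point conic fit, OA restoration."""

import math

import numpy as np
import pytest
from conftest import conic_from_params, ellipse_points
from scipy import ndimage

from flockvision import (
    FitError,
    GeometryError,
    SelectionError,
    classify_occlusion,
    count_components,
    fit_ellipse_5pt,
    label_components,
    make_oa_fixture,
    make_ta_fixture,
    pipe_band,
    rasterize_ellipse,
    restore_oa,
    restore_ta,
    select_boundary_points,
)
from flockvision.pipe import LineSegment
from flockvision.restoration import ConicCoefficients, StructuringElement
from flockvision.scenes import _disk, _noisy_ellipse_mask

FRAME = (160, 160)


def _horizontal_pipe(row=80.0, half_width=5.0, frame=FRAME):
    seg = LineSegment(start=(row, 0.0), end=(row, frame[1] - 1.0))
    return pipe_band(seg, half_width, frame)


def _ellipse_mask(center=(80.0, 80.0), a=40.0, b=26.0, angle=90.0, noise=0.0, seed=0,
                  frame=FRAME):
    return _noisy_ellipse_mask(frame, center, a, b, angle, noise,
                               np.random.default_rng(seed))


class TestClassifyOcclusion:
    def test_pipe_split_pair_is_ta(self):
        pipe = _horizontal_pipe()
        bird = _ellipse_mask()
        cleaned = bird & ~pipe.band
        regions = label_components(cleaned)
        cases = classify_occlusion(regions, {"pipe": pipe.band}, pipe,
                                   intact_area_estimate=float(bird.sum()))
        assert [c.kind for c in cases] == ["TA"]
        assert len(cases[0].components) == 2
        assert cases[0].occluder == "pipe"

    def test_feeder_overlap_is_oa(self):
        feeder = _disk(FRAME, (40.0, 120.0), 22.0)
        bird = _ellipse_mask(center=(60.0, 100.0))
        region = label_components(bird & ~feeder)[0]
        cases = classify_occlusion([region], {"feeder_0": feeder}, None,
                                   intact_area_estimate=float(bird.sum()))
        assert cases[0].kind == "OA"
        assert cases[0].occluder == "feeder_0"
        assert 0.0 < cases[0].estimated_occluded_fraction < 0.5

    def test_untouched_region_is_none(self):
        bird = _ellipse_mask(center=(40.0, 40.0), a=20.0, b=14.0)
        feeder = _disk(FRAME, (130.0, 130.0), 15.0)
        region = label_components(bird)[0]
        cases = classify_occlusion([region], {"feeder_0": feeder}, None,
                                   intact_area_estimate=float(bird.sum()))
        assert cases[0].kind == "none"

    def test_oversized_blob_is_crowded(self):
        blob = _ellipse_mask(a=50.0, b=40.0)
        region = label_components(blob)[0]
        cases = classify_occlusion([region], {}, None,
                                   intact_area_estimate=region.area / 2.0)
        assert cases[0].kind == "crowded"

    def test_majority_occluded_region_is_unrestorable(self):
        feeder = _disk(FRAME, (80.0, 60.0), 34.0)
        bird = _ellipse_mask()
        region = label_components(bird & ~feeder)[0]
        cases = classify_occlusion([region], {"feeder_0": feeder}, None,
                                   intact_area_estimate=float(bird.sum()))
        assert cases[0].kind == "unrestorable"
        assert cases[0].estimated_occluded_fraction >= 0.5


class TestRestoreTA:
    def test_band_split_merges_into_one_component(self):
        pipe = _horizontal_pipe()
        bird = _ellipse_mask()
        cleaned = bird & ~pipe.band
        assert count_components(cleaned) == 2
        restored, info = restore_ta(cleaned, pipe, full_output=True)
        assert info["reconnected"]
        assert count_components(restored) == 1
        # covers nearly the whole intact bird on an exact-ellipse fixture
        assert (restored & bird).sum() >= 0.95 * bird.sum()

    def test_mask_away_from_band_unchanged(self):
        pipe = _horizontal_pipe()
        mask = np.zeros(FRAME, dtype=bool)
        mask[10:30, 10:30] = True
        assert np.array_equal(restore_ta(mask, pipe), mask)

    def test_gap_wider_than_element_stays_split(self):
        pipe = _horizontal_pipe(row=80.0, half_width=5.0)
        mask = np.zeros(FRAME, dtype=bool)
        mask[30:50, 60:100] = True   # 30 px above the band edge
        mask[110:130, 60:100] = True
        restored, info = restore_ta(mask, pipe, full_output=True)
        assert not info["reconnected"]
        assert count_components(restored) == 2

    def test_extensive_and_idempotent(self):
        pipe = _horizontal_pipe()
        for seed in range(3):
            bird = _ellipse_mask(noise=2.0, seed=seed)
            cleaned = bird & ~pipe.band
            restored = restore_ta(cleaned, pipe)
            assert not (cleaned & ~restored).any()  # output ⊇ input
            assert np.array_equal(restore_ta(restored, pipe), restored)

    def test_structuring_element_validation(self):
        with pytest.raises(GeometryError):
            StructuringElement(length=4, angle_deg=0.0)
        with pytest.raises(GeometryError):
            StructuringElement(length=1, angle_deg=0.0)
        fp = StructuringElement(length=11, angle_deg=0.0).footprint()
        assert fp.sum() == 11 and fp.shape == (1, 11)
        fp45 = StructuringElement(length=11, angle_deg=45.0).footprint()
        # rasterized diagonal line: point-symmetric with full Euclidean reach
        assert np.array_equal(fp45, fp45[::-1, ::-1])
        rr, cc = np.nonzero(fp45)
        reach = np.hypot(rr - fp45.shape[0] // 2, cc - fp45.shape[1] // 2).max()
        assert reach >= 0.9 * (11 // 2)


class TestFitEllipse5pt:
    def test_unit_circle(self):
        pts = [(1, 0), (0, 1), (-1, 0), (0, -1), (math.sqrt(2) / 2, math.sqrt(2) / 2)]
        conic = fit_ellipse_5pt(pts)
        assert conic.as_array() == pytest.approx([1, 1, 0, 0, 0, -1], abs=1e-9)
        assert conic.is_ellipse

    def test_recovers_known_ellipse_conic(self):
        # sample at fixed parameter angles from a rotated, offset ellipse
        pts = ellipse_points(100.0, 80.0, 40.0, 20.0, 30.0, [0, 50, 130, 200, 290])
        conic = fit_ellipse_5pt(pts)
        want = conic_from_params(100.0, 80.0, 40.0, 20.0, 30.0)
        np.testing.assert_allclose(conic.as_array(), want, rtol=1e-6, atol=1e-6)

    def test_collinear_points_rejected(self):
        pts = [(i, i) for i in range(5)]
        with pytest.raises(FitError, match="degenerate"):
            fit_ellipse_5pt(pts)

    def test_hyperbola_rejected(self):
        xs = [0.5, 1.0, 2.0, -1.0, -2.0]
        pts = [(x, 1.0 / x) for x in xs]  # on x*y = 1
        with pytest.raises(FitError, match="not an ellipse"):
            fit_ellipse_5pt(pts)

    def test_residual_vanishes_at_input_points(self, rng):
        for _ in range(10):
            cx, cy = rng.uniform(20, 200, 2)
            a = rng.uniform(15, 60)
            b = a * rng.uniform(0.4, 0.9)
            ang = rng.uniform(0, 180)
            t = np.sort(rng.choice(np.arange(0, 360, 10), 5, replace=False))
            pts = ellipse_points(cx, cy, a, b, ang, t)
            conic = fit_ellipse_5pt(pts)
            coef = conic.as_array()
            coef = coef / np.linalg.norm(coef)
            q = ConicCoefficients(*coef)
            assert np.abs(q(pts[:, 0], pts[:, 1])).max() <= 1e-9

    def test_translation_equivariance(self):
        base = ellipse_points(50.0, 60.0, 30.0, 18.0, 20.0, [10, 80, 150, 220, 300])
        shift = np.array([13.0, -7.0])
        conic = fit_ellipse_5pt(base + shift)
        want = conic_from_params(50.0 + shift[0], 60.0 + shift[1], 30.0, 18.0, 20.0)
        np.testing.assert_allclose(conic.as_array(), want, rtol=1e-6, atol=1e-6)

    def test_parameter_recovery_noise_free(self, rng):
        """Center within 0.5 px and semi-axes within 1% over 100 random ellipses."""
        for _ in range(100):
            cx, cy = rng.uniform(50, 400, 2)
            a = rng.uniform(20, 70)
            b = a * rng.uniform(0.4, 0.95)
            ang = rng.uniform(0, 180)
            t0 = rng.uniform(0, 72)
            pts = ellipse_points(cx, cy, a, b, ang, t0 + np.array([0, 72, 144, 216, 288]))
            got = fit_ellipse_5pt(pts).ellipse_params()
            assert abs(got[0] - cx) <= 0.5 and abs(got[1] - cy) <= 0.5
            assert abs(got[2] - a) / a <= 0.01
            assert abs(got[3] - b) / b <= 0.01


class TestSelectBoundaryPoints:
    def test_free_boundary_equal_spacing(self):
        bird = _ellipse_mask()
        region = label_components(bird)[0]
        pts = select_boundary_points(region, np.zeros(FRAME, dtype=bool))
        assert pts.shape == (5, 2)
        # consecutive arc gaps close to one fifth of the perimeter
        closed = np.vstack([region.boundary, region.boundary[:1]])
        perimeter = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        d = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        # chord lengths are bounded by arcs; just check rough uniformity
        assert d.max() / d.min() < 2.0
        assert perimeter / 5.0 > d.min()

    def test_points_avoid_the_occluder(self):
        ((intact, occ, bite),) = make_oa_fixture(5, 1, (0.25, 0.35))
        region = label_components(occ)[0]
        pts = select_boundary_points(region, bite, exclusion_px=3.0)
        dist = ndimage.distance_transform_edt(~bite)
        for x, y in pts:
            assert dist[int(round(y)), int(round(x))] > 3.0

    def test_nearly_covered_boundary_raises(self):
        bird = _ellipse_mask()
        region = label_components(bird)[0]
        occluder = np.ones(FRAME, dtype=bool)
        occluder[78:83, 118:123] = False  # only a 5x5 window is occluder-free
        with pytest.raises(SelectionError, match="insufficient free boundary"):
            select_boundary_points(region, occluder)

    def test_deterministic(self):
        bird = _ellipse_mask(noise=2.0, seed=3)
        region = label_components(bird)[0]
        occ = _disk(FRAME, (80.0, 115.0), 15.0)
        a = select_boundary_points(region, occ)
        b = select_boundary_points(region, occ)
        assert np.array_equal(a, b)


class TestRasterizeEllipse:
    def test_circle_area_within_three_percent(self):
        conic = ConicCoefficients(1.0, 1.0, -100.0, -100.0, 0.0, 50.0**2 + 50.0**2 - 100.0)
        mask = rasterize_ellipse(conic, (120, 120))
        assert mask.sum() == pytest.approx(math.pi * 100.0, rel=0.03)

    def test_ellipse_outside_frame_is_empty(self):
        coef = conic_from_params(-100.0, -100.0, 10.0, 6.0, 0.0)
        assert not rasterize_ellipse(ConicCoefficients(*coef), (50, 50)).any()

    def test_non_ellipse_rejected(self):
        hyperbola = ConicCoefficients(1.0, -1.0, 0.0, 0.0, 0.0, -1.0)
        with pytest.raises(GeometryError):
            rasterize_ellipse(hyperbola, (50, 50))


class TestRestoreOA:
    def test_bite_restored_on_low_noise_fixture(self):
        fixtures = make_oa_fixture(11, 3, (0.25, 0.35), boundary_noise_px=0.5)
        for intact, occ, bite in fixtures:
            region = label_components(occ)[0]
            restored = restore_oa(region, bite, occ.shape)
            assert (restored & intact).sum() >= 0.95 * intact.sum()
            assert count_components(restored) == 1

    def test_zero_occlusion_is_near_noop(self):
        bird = _ellipse_mask(noise=2.0, seed=8)
        region = label_components(bird)[0]
        restored = restore_oa(region, np.zeros(FRAME, dtype=bool), FRAME)
        assert not (bird & ~restored).any()  # extensive
        added = restored & ~bird
        assert added.sum() <= 0.08 * bird.sum()  # only boundary-tolerance pixels

    def test_extensive_always(self):
        fixtures = make_oa_fixture(13, 5, (0.05, 0.45))
        for _, occ, bite in fixtures:
            region = label_components(occ)[0]
            try:
                restored = restore_oa(region, bite, occ.shape)
            except (FitError, SelectionError):
                continue
            assert not (occ & ~restored).any()

    def test_robust_mode_matches_ground_truth(self):
        fixtures = make_oa_fixture(17, 3, (0.2, 0.4))
        for intact, occ, bite in fixtures:
            region = label_components(occ)[0]
            restored = restore_oa(region, bite, occ.shape, mode="robust")
            assert (restored & intact).sum() >= 0.9 * intact.sum()

    def test_implausibility_guard_raises_fit_error(self):
        # with the plausibility bound tightened below 1, every fitted ellipse
        # is "too large" relative to the region and the guard must fire
        ((_, occ, bite),) = make_oa_fixture(11, 1, (0.25, 0.35))
        region = label_components(occ)[0]
        with pytest.raises(FitError, match="implausible"):
            restore_oa(region, bite, occ.shape, max_area_ratio=0.5)
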