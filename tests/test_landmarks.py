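"""Tests for axis finding, alignment and automatic landmark placement."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from zebreg.io_core import BinaryMask, Contour, Raster
from zebreg.landmarks import (
    AxisEndpoints,
    CorrespondenceError,
    ExclusionZones,
    TooManyLandmarksError,
    align_horizontal,
    correspond,
    find_axis_endpoints,
    place_landmarks,
)
from zebreg.segmentation import segment_embryo, trace_boundary


def circle_contour(radius=50, center=(60, 60)) -> Contour:
    mask = np.zeros((130, 130), dtype=bool)
    rr, cc = np.mgrid[0:130, 0:130]
    mask[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = True
    return trace_boundary(BinaryMask(mask))


def ellipse_contour(a=30, b=100) -> Contour:
    mask = np.zeros((100, 300), dtype=bool)
    rr, cc = np.mgrid[0:100, 0:300]
    mask[((rr - 50) / a) ** 2 + ((cc - 150) / b) ** 2 <= 1.0] = True
    return trace_boundary(BinaryMask(mask))


class TestAxisEndpoints:
    def test_ellipse_axis_is_major_diameter(self):
        contour = ellipse_contour(a=30, b=100)
        ep = find_axis_endpoints(contour)
        assert ep.length == pytest.approx(200, abs=2)
        for pt in (ep.head, ep.tail):
            assert abs(pt[0] - 50) <= 2  # on the major axis row

    def test_circle_gives_antipodal_pair_deterministically(self):
        contour = circle_contour()
        ep1 = find_axis_endpoints(contour)
        ep2 = find_axis_endpoints(Contour(np.roll(contour.points, 17, axis=0)))
        assert ep1.length == pytest.approx(100, abs=2)
        assert (ep1.head, ep1.tail) == (ep2.head, ep2.tail)  # tie rule is stable

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_on_random_blobs(self, seed):
        from conftest import random_blob_mask

        rng = np.random.default_rng(seed)
        blob = random_blob_mask(rng)
        from scipy import ndimage

        labels, n = ndimage.label(blob, structure=np.ones((3, 3)))
        if n == 0:
            pytest.skip("empty blob")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        blob = labels == (1 + np.argmax(sizes))
        contour = trace_boundary(BinaryMask(blob))
        ep = find_axis_endpoints(contour)
        d = cdist(contour.points.astype(float), contour.points.astype(float))
        assert ep.length == d.max()

    def test_phantom_head_is_the_wide_end(self, small_reference):
        green, _ = small_reference
        _, contour = segment_embryo(green)
        ep = find_axis_endpoints(contour)
        # head (wide ellipse end) is on the left, tail tip on the right
        assert ep.head[1] < ep.tail[1]


class TestAlignHorizontal:
    def test_already_horizontal_fish_angle_zero(self, small_reference):
        green, _ = small_reference
        body, contour = segment_embryo(green)
        ep = find_axis_endpoints(contour)
        _, _, angle = align_horizontal(green, body, ep)
        assert abs(angle) <= 0.5

    def test_rotated_fish_round_trip(self, small_reference):
        from scipy import ndimage

        green, _ = small_reference
        body, _ = segment_embryo(green)
        # rotate body and intensities by -30 degrees (content axis -> +30)
        rot_img = Raster(ndimage.rotate(green.pixels, -30, reshape=True, order=1))
        rot_body = BinaryMask(
            ndimage.rotate(body.pixels, -30, reshape=True, order=0)
        )
        ep = find_axis_endpoints(trace_boundary(rot_body))
        aligned_img, aligned_body, angle = align_horizontal(rot_img, rot_body, ep)
        assert angle == pytest.approx(30, abs=1.0)
        # after alignment the major axis is horizontal again, head left
        ep2 = find_axis_endpoints(trace_boundary(aligned_body))
        dr = abs(ep2.head[0] - ep2.tail[0])
        dc = abs(ep2.head[1] - ep2.tail[1])
        assert dr / dc < 0.05  # endpoint jitter on the round head allows ~1-2 deg
        assert ep2.head[1] < ep2.tail[1]
        # the aligned body matches the original up to translation
        def centered(mask, canvas=(700, 900)):
            rows, cols = np.nonzero(mask.pixels)
            out = np.zeros(canvas, dtype=bool)
            r0 = canvas[0] // 2 - int(rows.mean())
            c0 = canvas[1] // 2 - int(cols.mean())
            out[rows + r0, cols + c0] = True
            return out

        a, b = centered(body), centered(aligned_body)
        assert (a & b).sum() / (a | b).sum() >= 0.98

    def test_head_right_fish_flips(self, small_reference):
        green, _ = small_reference
        body, _ = segment_embryo(green)
        flipped_img = Raster(green.pixels[:, ::-1].copy())
        flipped_body = BinaryMask(body.pixels[:, ::-1].copy())
        ep = find_axis_endpoints(trace_boundary(flipped_body))
        _, _, angle = align_horizontal(flipped_img, flipped_body, ep)
        assert abs(abs(angle) - 180) <= 0.5


class TestPlaceLandmarks:
    def test_circle_equal_spacing(self):
        contour = circle_contour()
        ep = find_axis_endpoints(contour)
        marks = place_landmarks(contour, ep, n_auto=8, zones=ExclusionZones(0.0, 0.0))
        assert len(marks) == 8
        perimeter = contour.perimeter()
        # consecutive arc gaps close to C/8
        d = np.linalg.norm(np.diff(np.vstack([marks, marks[:1]]), axis=0).astype(float), axis=1)
        # chord length is a lower bound on arc length; spacing samples the circle evenly
        assert d.std() / d.mean() < 0.1
        assert np.all(d > 0.5 * perimeter / 8)

    def test_phantom_17_landmarks_avoid_exclusion_zones(self, small_reference):
        green, _ = small_reference
        _, contour = segment_embryo(green)
        ep = find_axis_endpoints(contour)
        zones = ExclusionZones(tail_fraction=0.15, yolk_fraction=0.10)
        marks = place_landmarks(contour, ep, n_auto=17, zones=zones)
        assert len(marks) == 17
        # no landmark except the tail endpoint is close to the tail tip
        tail = np.array(ep.tail, dtype=float)
        dists = np.linalg.norm(marks - tail, axis=1)
        assert np.sum(dists < 20) == 1
        # ventral-most contour point (yolk) has no nearby landmark
        ventral = contour.points[np.argmax(contour.points[:, 0])].astype(float)
        assert np.min(np.linalg.norm(marks - ventral, axis=1)) > 10

    def test_zones_covering_contour_raise(self):
        contour = circle_contour()
        ep = find_axis_endpoints(contour)
        with pytest.raises(TooManyLandmarksError):
            place_landmarks(contour, ep, n_auto=200, zones=ExclusionZones(0.45, 0.45))

    def test_deterministic_bit_exact(self, small_reference):
        green, _ = small_reference
        _, contour = segment_embryo(green)
        ep = find_axis_endpoints(contour)
        a = place_landmarks(contour, ep)
        b = place_landmarks(contour, ep)
        np.testing.assert_array_equal(a, b)

    def test_arc_spacing_cv_below_5_percent(self, small_reference):
        green, _ = small_reference
        _, contour = segment_embryo(green)
        ep = find_axis_endpoints(contour)
        zones = ExclusionZones(0.15, 0.10)
        marks = place_landmarks(contour, ep, n_auto=17, zones=zones)
        # measure spacing in admissible arc length (excluded arcs collapse)
        pts = contour.points
        head_idx = np.flatnonzero((pts[:, 0] == ep.head[0]) & (pts[:, 1] == ep.head[1]))[0]
        rolled = np.roll(pts, -head_idx, axis=0)
        steps = Contour(rolled, closed=True).arc_steps()
        is_mark = np.zeros(len(rolled), dtype=bool)
        for m in marks:
            is_mark |= (rolled[:, 0] == m[0]) & (rolled[:, 1] == m[1])
        # admissible = not within the tail/yolk exclusion arcs; approximate by
        # dropping the two largest full-arc gaps (the zone skips)
        s = np.concatenate([[0.0], np.cumsum(steps)[:-1]])
        mark_s = np.sort(s[is_mark])
        gaps = np.diff(np.concatenate([mark_s, [mark_s[0] + steps.sum()]]))
        # 3 gaps span excluded arcs (two tail-zone halves flanking the tail
        # anchor, one yolk zone); the rest measure the actual spacing
        gaps = np.sort(gaps)[:-3]
        assert gaps.std() / gaps.mean() < 0.05

    def test_rotation_round_trip_within_2px(self):
        contour = ellipse_contour()
        ep = find_axis_endpoints(contour)
        zones = ExclusionZones(tail_fraction=0.1, yolk_fraction=0.0)
        marks = place_landmarks(contour, ep, n_auto=12, zones=zones)

        h = 100  # rotate (r, c) -> (c, h - 1 - r): 90 degrees, orientation-preserving
        rot_pts = np.column_stack([contour.points[:, 1], h - 1 - contour.points[:, 0]])
        rot_contour = Contour(rot_pts, closed=True)
        rot_ep = AxisEndpoints(
            head=(ep.head[1], h - 1 - ep.head[0]), tail=(ep.tail[1], h - 1 - ep.tail[0])
        )
        rot_marks = place_landmarks(rot_contour, rot_ep, n_auto=12, zones=zones)
        back = np.column_stack([h - 1 - rot_marks[:, 1], rot_marks[:, 0]])
        assert np.max(np.linalg.norm(back - marks, axis=1)) <= 2.0


class TestCorrespond:
    def test_17_auto_plus_3_manual_gives_20(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0, 100, (17, 2))
        tgt = rng.uniform(0, 100, (17, 2))
        manual = [((1.0, 2.0), (3.0, 4.0)), ((5.0, 6.0), (7.0, 8.0)), ((9.0, 1.0), (2.0, 3.0))]
        pairs = correspond(ref, tgt, manual)
        assert pairs.n == 20
        np.testing.assert_array_equal(pairs.sigma, np.ones(20))
        np.testing.assert_array_equal(pairs.p[:17], tgt)
        np.testing.assert_array_equal(pairs.q[:17], ref)
        assert tuple(pairs.p[17]) == (1.0, 2.0)
        assert tuple(pairs.q[17]) == (3.0, 4.0)

    def test_no_manual_pairs(self):
        rng = np.random.default_rng(1)
        pairs = correspond(rng.uniform(0, 9, (17, 2)), rng.uniform(0, 9, (17, 2)))
        assert pairs.n == 17

    def test_count_mismatch_raises(self):
        rng = np.random.default_rng(2)
        with pytest.raises(CorrespondenceError):
            correspond(rng.uniform(0, 9, (17, 2)), rng.uniform(0, 9, (16, 2)))
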