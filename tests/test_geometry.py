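import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hyphamorph.exceptions import InvalidGeometryError, InvalidTraceError
from hyphamorph.geometry import (
    PolylineTrace,
    arc_length,
    deflection_angle,
    detect_kinks,
    junction_angle,
    simplify_trace,
)


def _point_segment_dist(p, a, b):
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom == 0:
        return float(np.linalg.norm(p - a))
    t = float(np.dot(p - a, ab)) / denom
    if t <= 0:
        return float(np.linalg.norm(p - a))
    if t >= 1:
        return float(np.linalg.norm(p - b))
    return float(np.linalg.norm(p - (a + t * ab)))


def brute_rdp(points, tol):
    """Independent recursive maximum-deviation (Douglas-Peucker)
    simplification, deviation = distance to the chord segment."""
    pts = np.asarray(points, float)
    if len(pts) <= 2:
        return pts
    d = np.array([_point_segment_dist(p, pts[0], pts[-1])
                  for p in pts[1:-1]])
    i = int(np.argmax(d)) + 1
    if d[i - 1] > tol:
        left = brute_rdp(pts[: i + 1], tol)
        right = brute_rdp(pts[i:], tol)
        return np.vstack([left[:-1], right])
    return np.vstack([pts[0], pts[-1]])


class TestArcLength:
    @pytest.mark.parametrize("pts,expected", [
        ([(0, 0), (3, 4)], 5.0),
        ([(0, 0), (1, 0), (1, 1)], 2.0),
    ])
    def test_known_lengths(self, pts, expected):
        assert arc_length(PolylineTrace(np.array(pts, float))) == pytest.approx(expected)

    def test_matches_pairwise_sum_oracle(self, rng):
        pts = rng.uniform(-10, 10, size=(50, 2))
        expected = sum(float(np.hypot(*(pts[i + 1] - pts[i])))
                       for i in range(49))
        assert arc_length(PolylineTrace(pts)) == pytest.approx(expected, abs=1e-12)

    def test_rejects_single_point(self):
        with pytest.raises(InvalidTraceError):
            arc_length(np.array([[0.0, 0.0]]))


class TestDeflectionAngle:
    @pytest.mark.parametrize("a,b,c,expected", [
        ((0, 0), (1, 0), (2, 0), 0.0),
        ((0, 0), (1, 0), (1, 1), 90.0),
        ((0, 0), (1, 0), (0, 1), 135.0),
    ])
    def test_reference_turns(self, a, b, c, expected):
        assert deflection_angle(a, b, c) == pytest.approx(expected, abs=1e-6)

    def test_near_collinear_matches_atan2_oracle(self):
        ang = deflection_angle((0, 0), (1, 0), (2, 0.01))
        expected = np.degrees(np.arctan2(0.01, 1.0))
        assert ang == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6))
    def test_range_and_oracle(self, coords):
        a, b, c = np.array(coords[:2]), np.array(coords[2:4]), np.array(coords[4:])
        if np.allclose(a, b) or np.allclose(b, c):
            return
        ang = deflection_angle(a, b, c)
        assert 0.0 <= ang <= 180.0
        v1, v2 = b - a, c - b
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        # compare cosines: arccos itself is ill-conditioned near 0 and 180
        assert np.cos(np.radians(ang)) == pytest.approx(
            np.clip(cosang, -1, 1), abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(InvalidGeometryError):
            deflection_angle((0, 0), (0, 0), (1, 1))


class TestJunctionAngle:
    def body(self):
        return PolylineTrace(np.array([[0.0, 0.0], [2.0, 0.0]]),
                             role="body_axis")

    def test_collinear_emergence_is_zero(self):
        hy = PolylineTrace(np.array([[2.0, 0.0], [4.0, 0.0]]), role="hypha")
        assert junction_angle(self.body(), hy) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_emergence(self):
        hy = PolylineTrace(np.array([[2.0, 0.0], [2.0, 2.0]]), role="hypha")
        assert junction_angle(self.body(), hy) == pytest.approx(90.0, abs=1e-9)

    def test_orients_axis_toward_attachment_pole(self):
        # hypha attached at the (0,0) pole: axis direction must flip
        hy = PolylineTrace(np.array([[0.0, 0.0], [-2.0, 0.0]]), role="hypha")
        assert junction_angle(self.body(), hy) == pytest.approx(0.0, abs=1e-12)

    def test_random_orientations_match_deflection_oracle(self, rng):
        for _ in range(50):
            th_a, th_h = rng.uniform(0, 2 * np.pi, 2)
            da = np.array([np.cos(th_a), np.sin(th_a)])
            dh = np.array([np.cos(th_h), np.sin(th_h)])
            pole = rng.uniform(-5, 5, 2)
            body = PolylineTrace(np.vstack([pole - 2 * da, pole]),
                                 role="body_axis")
            hy = PolylineTrace(np.vstack([pole, pole + 1.5 * dh]), role="hypha")
            expected = deflection_angle(pole - da, pole, pole + dh)
            assert junction_angle(body, hy) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_body_axis_rejected(self):
        body = PolylineTrace(np.array([[0.0, 0.0], [1e-4, 0.0]]),
                             role="body_axis")
        hy = PolylineTrace(np.array([[0.0, 0.0], [1.0, 0.0]]), role="hypha")
        with pytest.raises(InvalidGeometryError):
            junction_angle(body, hy)


class TestDetectKinks:
    def test_exact_zigzag(self):
        tr = PolylineTrace(np.array([[0, 0], [1, 0], [1, 1], [2, 1]], float))
        kinks = detect_kinks(tr, simplify_tol_um=0.0, min_kink_deg=10.0)
        assert [(i, pytest.approx(a)) for i, a in kinks] == \
            [(1, pytest.approx(90.0)), (2, pytest.approx(90.0))]

    def test_jittered_straight_line_has_no_kinks(self, rng):
        x = np.linspace(0, 5, 100)
        y = rng.uniform(-0.02, 0.02, size=100)
        tr = PolylineTrace(np.column_stack([x, y]))
        assert detect_kinks(tr, simplify_tol_um=0.05, min_kink_deg=10.0) == []

    def test_sub_threshold_bend_ignored(self):
        ang = np.radians(5.0)
        pts = np.array([[0, 0], [1, 0],
                        [1 + np.cos(ang), np.sin(ang)]])
        tr = PolylineTrace(pts)
        assert detect_kinks(tr, simplify_tol_um=0.0, min_kink_deg=10.0) == []

    def test_simplification_matches_brute_force_rdp(self, rng):
        for _ in range(25):
            n = rng.integers(5, 40)
            pts = np.cumsum(rng.normal(0, 0.5, size=(n, 2)), axis=0)
            tol = float(rng.uniform(0.01, 0.5))
            ours = simplify_trace(pts, tol)
            theirs = brute_rdp(pts, tol)
            assert np.allclose(ours, theirs), "Douglas-Peucker mismatch"

    def test_invalid_threshold_rejected(self):
        tr = PolylineTrace(np.array([[0, 0], [1, 0]], float))
        with pytest.raises(InvalidGeometryError):
            detect_kinks(tr, simplify_tol_um=-1.0)
        with pytest.raises(InvalidGeometryError):
            detect_kinks(tr, min_kink_deg=180.0)


class TestPolylineTrace:
    def test_rejects_duplicate_consecutive_points(self):
        with pytest.raises(InvalidTraceError):
            PolylineTrace(np.array([[0, 0], [0, 0], [1, 1]], float))

    def test_rejects_too_few_points(self):
        with pytest.raises(InvalidTraceError):
            PolylineTrace(np.array([[0.0, 0.0]]))

    def test_self_intersection_is_allowed(self):
        pts = np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, -1]], float)
        tr = PolylineTrace(pts)  # crosses its own first segment
        assert arc_length(tr) > 0
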