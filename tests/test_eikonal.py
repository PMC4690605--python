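"""Constant-speed model: closed forms, grid solver, marker paths."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangefront.environments import Environment, make_circle, make_rhombus
from rangefront.eikonal import (
    circle_axis_lag,
    front_from_arrival,
    front_rhombus,
    indent_rhombus,
    indent_series_rhombus,
    kink_distance_rhombus,
    kink_metrics_rhombus,
    marker_path,
    path_length,
    solve_arrival,
    tilted_bar_kink_axis,
)
from rangefront.errors import InvalidGeometryError, NotYetFormedError
from rangefront.frontstats import indent_from_front

from conftest import V_FRONT


class TestIndentRhombus:
    def test_at_arc_meeting_distance(self):
        assert indent_rhombus(1.0, 1.0) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert indent_rhombus(2.0, 1.0) == pytest.approx(2.0 * (1 - math.sqrt(3) / 2))

    def test_far_field_healing_law(self):
        # Delta * d -> w^2/2
        d = 100.0
        assert indent_rhombus(d, 1.0) * d == pytest.approx(0.5, rel=1e-4)

    def test_domain_error_below_w(self):
        with pytest.raises(InvalidGeometryError):
            indent_rhombus(0.5, 1.0)


class TestKink:
    @pytest.mark.parametrize(
        "w,h,expected",
        [(1.2, 0.9, 1.5), (1.0, 1.0, math.sqrt(2.0)), (2.0, 0.0, 2.0)],
    )
    def test_kink_distance(self, w, h, expected):
        assert kink_distance_rhombus(w, h) == pytest.approx(expected)

    def test_kink_metrics_opening_angle(self):
        m = kink_metrics_rhombus(1.0, 1.0)
        # arcs meet along the 45-degree obstacle edges -> opening 90 degrees
        assert m.phi == pytest.approx(90.0)
        assert m.d_kink == pytest.approx(math.sqrt(2.0))


class TestFrontRhombus:
    def test_straight_line_before_contact(self):
        fc = front_rhombus(-1.8, 1.2, 0.9)
        assert len(fc.segments) == 1
        assert np.allclose(fc.segments[0][:, 1], -1.8)

    def test_interrupted_during_passage(self):
        fc = front_rhombus(-0.45, 1.2, 0.9)
        assert len(fc.segments) == 2
        gap_lo = fc.segments[0][-1, 0]
        gap_hi = fc.segments[1][0, 0]
        assert gap_hi - gap_lo == pytest.approx(2 * 1.2 * 0.5, rel=1e-9)

    def test_indent_matches_closed_form_post_kink(self):
        w, h = 1.2, 0.9
        ob = make_rhombus(w, h)
        for d in (1.6, 2.5, 5.0):
            fc = front_rhombus(d, w, h)
            assert indent_from_front(fc, ob) == pytest.approx(
                indent_rhombus(d, w), abs=2e-4
            )

    def test_height_independence_beyond_kink(self):
        # doubling h leaves the post-kink front unchanged
        d = 4.0
        a = front_rhombus(d, 1.2, 0.9)
        b = front_rhombus(d, 1.2, 1.8)
        np.testing.assert_allclose(a.vertices, b.vertices, atol=1e-12)

    def test_continuity_post_kink(self):
        fc = front_rhombus(2.0, 1.2, 0.9)
        assert len(fc.segments) == 1
        v = fc.vertices
        gaps = np.hypot(*np.diff(v, axis=0).T)
        # all junctions (line->arc, arc->arc) are tight; only the two outer
        # straight edges are long
        assert gaps[1:-1].max() < 0.05

    def test_scale_covariance(self):
        s = 2.5
        a = front_rhombus(2.0, 1.0, 0.8)
        b = front_rhombus(2.0 * s, 1.0 * s, 0.8 * s)
        np.testing.assert_allclose(b.vertices, s * a.vertices, rtol=1e-9, atol=1e-9)


class TestCircleAxisLag:
    def test_cusp_formation_value(self):
        # at d = pi r/2 the most lagging point is the disk top: Delta = pi/2 - 1
        assert circle_axis_lag(math.pi / 2.0, 1.0) == pytest.approx(math.pi / 2 - 1)

    def test_against_huygens_brute_force(self):
        # dense envelope of circular wavelets seeded on the upper disk
        # boundary; a source at angle theta from the top is reached by the
        # front wrapping from the equator, arc length r*(pi/2 - theta)
        r, d = 1.0, 2.0
        theta = np.linspace(0.0, math.pi / 2, 2001)
        bx, by = r * np.sin(theta), r * np.cos(theta)
        travel_to_src = r * (math.pi / 2 - theta)
        ys = np.linspace(r, d + r, 4001)
        sx = np.broadcast_to(bx[None, :], (len(ys), len(theta)))
        sy = np.broadcast_to(by[None, :], (len(ys), len(theta)))
        px, py = 0.0, ys[:, None]
        dx, dy = px - sx, py - sy
        seg2 = dx * dx + dy * dy
        # exclude chords that dip inside the disk (not a valid wavelet path)
        with np.errstate(invalid="ignore"):
            t = np.clip(-(sx * dx + sy * dy) / seg2, 0.0, 1.0)
        closest2 = (sx + t * dx) ** 2 + (sy + t * dy) ** 2
        dist = np.sqrt(seg2)
        dist[closest2 < r * r - 1e-9] = np.inf
        arrivals = (travel_to_src[None, :] + dist).min(axis=1)
        y_f = float(np.interp(d, arrivals, ys))
        assert circle_axis_lag(d, r) == pytest.approx(d - y_f, abs=5e-4)

    def test_far_field_universal_healing(self):
        d = 500.0
        assert circle_axis_lag(d, 1.0) * d == pytest.approx(0.5, rel=1e-3)

    def test_zero_radius(self):
        assert circle_axis_lag(3.0, 0.0) == 0.0

    def test_pre_cusp_raises_with_formation_distance(self):
        with pytest.raises(NotYetFormedError) as exc:
            circle_axis_lag(1.0, 1.0)
        assert exc.value.d_kink == pytest.approx(math.pi / 2)


class TestTiltedBar:
    def test_symmetric_bar_kink_on_axis(self):
        for d in (1.5, 3.0, 10.0):
            assert tilted_bar_kink_axis(d, 1.0, 0.0) == 0.0

    def test_tip_approaches_bisecting_normal_monotonically(self):
        ds = np.linspace(2.0, 50.0, 40)
        xs = np.array([tilted_bar_kink_axis(d, 1.0, 30.0) for d in ds])
        assert np.all(xs > 0)  # trailing-edge side
        assert np.all(np.diff(xs) < 0)
        assert xs[-1] < 0.05

    def test_against_brute_force_circle_intersection(self):
        L, tilt, d = 1.0, 25.0, 2.2
        h = L * math.tan(math.radians(tilt))
        # upper intersection of circles ((-L,-h), d+h) and ((L,h), d-h)
        from scipy.optimize import brentq

        def f(x):
            # y from circle 1 (upper branch), plug into circle 2
            y1 = -h + math.sqrt((d + h) ** 2 - (x + L) ** 2)
            return (x - L) ** 2 + (y1 - h) ** 2 - (d - h) ** 2

        x_tip = brentq(f, 0.0, L, xtol=1e-12)
        assert tilted_bar_kink_axis(d, L, tilt) == pytest.approx(x_tip, abs=1e-9)

    def test_pre_kink_raises(self):
        with pytest.raises(NotYetFormedError):
            tilted_bar_kink_axis(0.5, 1.0, 20.0)


class TestArrivalField:
    def test_planar_wave_exact(self):
        env = Environment(2.0, 5.0)
        f = solve_arrival(env, v=V_FRONT, a_eik=0.05)
        expected = (f.y[:, None] - 0.0) / V_FRONT
        np.testing.assert_allclose(f.T, np.broadcast_to(expected, f.T.shape), rtol=1e-6)

    def test_monotone_along_propagation_in_free_columns(self, rhombus_fields):
        f = rhombus_fields[(1.2, 0.9)]
        edge = f.T[:, 2]
        assert np.all(np.diff(edge) > 0)

    def test_infinite_inside_obstacle(self, rhombus_fields):
        f = rhombus_fields[(1.2, 0.9)]
        assert np.isinf(f.T[f.blocked]).all()

    def test_upwind_residual_near_unity(self, rhombus_fields):
        """|grad T| * v = 1 away from the source, kink line and obstacle."""
        f = rhombus_fields[(1.2, 0.9)]
        T, a = f.T, f.a
        gy, gx = np.gradient(T, a)
        res = np.hypot(gx, gy) * f.v
        ny, nx = T.shape
        ys, xs = np.meshgrid(f.y, f.x, indexing="ij")
        ob = f.env.obstacles[0]
        cx, cy = ob.center
        mask = (
            (ys > 0.5)
            & (np.abs(xs - cx) > 0.05)  # kink line on the axis
            & (np.hypot(xs - cx, ys - cy) > ob.w_half + 0.2)
        )
        assert np.nanmax(np.abs(res[mask] - 1.0)) < 0.05

    def test_indent_matches_closed_form_within_two_cells(self, rhombus_fields):
        w, h = 1.2, 0.9
        f = rhombus_fields[(w, h)]
        ob = f.env.obstacles[0]
        for d in np.linspace(1.5 * w, 10 * w, 8):
            fc = front_from_arrival(f, d)
            delta = indent_from_front(fc, ob)
            assert delta == pytest.approx(indent_rhombus(d, w), abs=2 * f.a)

    def test_circle_axis_lag_within_two_cells(self):
        r = 1.0
        a = r / 100.0
        env = Environment(8.0, 8.0, (make_circle(r, (4.0, 2.5)),))
        f = solve_arrival(env, v=V_FRONT, a_eik=a)
        ob = env.obstacles[0]
        for d in (2.0, 3.0, 5.0):
            delta = indent_from_front(front_from_arrival(f, d), ob)
            assert delta == pytest.approx(circle_axis_lag(d, r), abs=2 * a)

    def test_coarse_grid_warns(self):
        env = Environment(4.0, 4.0, (make_rhombus(0.5, 0.5, (2.0, 2.0)),))
        with pytest.warns(UserWarning, match="coarser"):
            solve_arrival(env, v=V_FRONT, a_eik=0.1)


class TestFrontFromArrival:
    def test_planar_level_is_straight(self):
        env = Environment(2.0, 5.0)
        f = solve_arrival(env, v=V_FRONT, a_eik=0.05)
        fc = front_from_arrival(f, 3.0, y_ref=0.0)
        assert np.allclose(fc.vertices[:, 1], 3.0, atol=1e-6)

    def test_mirror_symmetry(self, rhombus_fields):
        f = rhombus_fields[(1.2, 0.9)]
        cx = f.env.obstacles[0].center[0]
        fc = front_from_arrival(f, 2.0)
        v = fc.vertices
        left = v[v[:, 0] < cx]
        right = v[v[:, 0] > cx]
        y_left = np.interp(cx - np.linspace(0.1, 2.0, 50), *_sorted(left))
        y_right = np.interp(cx - np.linspace(0.1, 2.0, 50), *_sorted_mirror(right, cx))
        np.testing.assert_allclose(y_left, y_right, atol=f.a)

    def test_kink_location_and_opening_angle_on_grid(self, rhombus_fields):
        """Before d_kink = sqrt(w^2 + h^2) the most lagging front points sit
        off-axis (the arcs have not met); after, the axis minimum is a wedge
        whose opening angle matches 180 - 2*asin(w/d)."""
        from rangefront.eikonal import kink_opening_angle_rhombus

        w, h = 1.2, 0.9
        f = rhombus_fields[(w, h)]
        ob = f.env.obstacles[0]
        cx = ob.center[0]
        # pre-kink: the deepest points lie near the obstacle, away from the axis
        x_min_pre = _axis_min_x(f, 1.2, cx)
        assert abs(x_min_pre - cx) > 0.15
        # post-kink: the same discrete turning-angle estimator applied to the
        # grid contour and to the closed-form construction must agree
        for d in (2.0, 3.0):
            grid_angle = _axis_opening_angle(front_from_arrival(f, d), cx)
            ref = front_rhombus(d, w, h, center=(cx, ob.y_maxwidth))
            ref_angle = _axis_opening_angle(ref, cx)
            assert grid_angle == pytest.approx(ref_angle, abs=6.0)
            # and both are clearly kinked, in the ballpark of the exact angle
            assert grid_angle == pytest.approx(
                kink_opening_angle_rhombus(d, w), abs=15.0
            )


def _sorted(pts):
    o = np.argsort(pts[:, 0])
    return pts[o, 0], pts[o, 1]


def _sorted_mirror(pts, cx):
    x = 2 * cx - pts[:, 0]
    o = np.argsort(x)
    return x[o], pts[o, 1]


def _axis_window_vertices(curve, cx, half=0.8):
    v = np.vstack(curve.segments)
    sub = v[np.abs(v[:, 0] - cx) < half]
    return sub[np.argsort(sub[:, 0])]


def _axis_min_x(field, d, cx):
    sub = _axis_window_vertices(front_from_arrival(field, d), cx)
    return float(sub[np.argmin(sub[:, 1]), 0])


def _axis_opening_angle(curve, cx, chord_s=0.1):
    """Discrete turning angle at the curve's axis minimum (180 = smooth):
    chords to the points at arc length ``chord_s`` on either side of the tip."""
    sub = _axis_window_vertices(curve, cx)
    i = int(np.argmin(sub[:, 1]))

    def point_at_arc(direction):
        s = 0.0
        j = i
        while 0 < j < len(sub) - 1:
            nxt = j + direction
            s += float(np.hypot(*(sub[nxt] - sub[j])))
            j = nxt
            if s >= chord_s:
                break
        return sub[j]

    u1 = point_at_arc(-1) - sub[i]
    u2 = point_at_arc(+1) - sub[i]
    c = np.dot(u1, u2) / np.linalg.norm(u1) / np.linalg.norm(u2)
    return math.degrees(math.acos(np.clip(c, -1, 1)))


class TestMarkerPath:
    def test_homogeneous_field_gives_vertical_segment(self):
        env = Environment(4.0, 6.0)
        f = solve_arrival(env, v=V_FRONT, a_eik=0.05)
        p = marker_path(f, (2.0, 5.0))
        assert np.ptp(p[:, 0]) <= f.a
        assert path_length(p) == pytest.approx(5.0, abs=2 * f.a)

    def test_bends_once_at_max_width_corner(self):
        env = Environment(8.0, 10.0, (make_rhombus(1.0, 1.0, (4.0, 3.0)),))
        f = solve_arrival(env, v=V_FRONT, a_eik=0.02)
        p = marker_path(f, (4.0, 8.0))
        steps = np.diff(p, axis=0)
        dirs = np.unique(np.round(np.degrees(np.arctan2(steps[:, 1], steps[:, 0])), 0))
        assert len(dirs) <= 2  # vertical + one oblique leg
        i, j = round((8.0 - f.a / 2) / f.a), round((4.0 - f.a / 2) / f.a)
        assert path_length(p) <= f.v * f.T[i, j] * 1.1

    def test_second_obstacle_lengthens_path(self):
        w, h = 1.0, 0.8
        one = Environment(12.0, 12.0, (make_rhombus(w, h, (5.0, 3.0)),))
        two = Environment(
            12.0, 12.0,
            (make_rhombus(w, h, (5.0, 3.0)), make_rhombus(w, h, (7.0, 5.0)),),
        )
        end = (6.3, 9.0)  # between/behind the pair
        p1 = marker_path(solve_arrival(one, v=V_FRONT, a_eik=0.025), end)
        p2 = marker_path(solve_arrival(two, v=V_FRONT, a_eik=0.025), end)
        assert path_length(p2) > path_length(p1)

    def test_end_inside_obstacle_rejected(self, rhombus_fields):
        f = rhombus_fields[(1.2, 0.9)]
        cx, cy = f.env.obstacles[0].center
        with pytest.raises(InvalidGeometryError):
            marker_path(f, (cx, cy))


@settings(deadline=None, max_examples=40)
@given(
    w=st.floats(0.3, 2.0),
    h=st.floats(0.3, 2.0),
    dfac=st.floats(1.01, 20.0),
)
def test_indent_independent_of_height_property(w, h, dfac):
    """Eq-independence: Delta(d; w) does not involve h, and rescaling
    d and w together rescales Delta exactly (collapse in units of w)."""
    d = w * dfac
    delta = indent_rhombus(d, w)
    assert delta == pytest.approx(w * indent_rhombus(dfac, 1.0), rel=1e-9)
    assert 0.0 <= delta <= w + 1e-12


def test_indent_series_collapse_exact():
    d_over_w = np.linspace(1.6, 8.0, 50)
    curves = [
        indent_series_rhombus(w, h, d_over_w * w)
        for (w, h) in [(0.9, 0.9), (0.9, 1.2), (1.2, 0.9), (1.2, 1.2)]
    ]
    base = curves[0].delta / curves[0].w_half
    for c in curves[1:]:
        np.testing.assert_allclose(c.delta / c.w_half, base, rtol=1e-12)
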