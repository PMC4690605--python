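"""Constant-speed (eikonal) front model.

In the constant-speed picture a population front advances at fixed speed v
normal to itself; growth-free obstacles simply delete the overlapping front
segments (Huygens construction).  Behind a convex obstacle the front is built
from circular arcs centered on the obstacle's widest points, which meet the
obstacle boundary at 90 degrees and collide on the symmetry axis to form a
kink that heals downstream as Delta ~ w^2/(2 d).

This module provides

* closed-form constructions for rhombi (front shape, indent Delta(d), kink
  distance and opening angle), circles (axis lag after cusp formation) and
  tilted thin bars (kink-tip trajectory);
* a general grid solver for the first-arrival time |grad T| = 1/v around
  arbitrary obstacle fields (first-order upwind, 8-neighbour multistencil,
  Gauss-Seidel fast sweeping, numba-jitted);
* level-set extraction and steepest-descent marker (geodesic) paths.

Front positions d follow the shared convention: d = 0 when the unperturbed
front passes the obstacle's point of maximal width (y_maxwidth).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from numba import njit
from scipy.optimize import brentq
from skimage import measure

from .environments import Environment
from .errors import (
    EmptyFrontError,
    InvalidGeometryError,
    NotYetFormedError,
)

__all__ = [
    "FrontCurve",
    "IndentSeries",
    "ArrivalField",
    "KinkMetrics",
    "indent_rhombus",
    "kink_distance_rhombus",
    "kink_opening_angle_rhombus",
    "kink_metrics_rhombus",
    "front_rhombus",
    "circle_axis_lag",
    "tilted_bar_kink_axis",
    "solve_arrival",
    "front_from_arrival",
    "marker_path",
    "indent_series_rhombus",
    "rasterize_blocked",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FrontCurve:
    """Ordered front polyline(s) at front position d.

    ``segments`` is a tuple of (n, 2) vertex arrays ordered by x; a front
    interrupted by an obstacle has more than one segment.  ``arcs`` carries
    the analytic arc metadata (center, radius, angular range, whether the arc
    terminates on the obstacle boundary) for closed-form fronts, enabling
    exact tangent computations downstream.
    """

    segments: tuple
    d: float
    provenance: str  # closed-form | grid | pde | eden
    arcs: list = field(default_factory=list)

    @property
    def vertices(self) -> np.ndarray:
        return np.vstack(self.segments)

    def to_csv(self, path) -> None:
        v = self.vertices
        pd.DataFrame({"x_mm": v[:, 0], "y_mm": v[:, 1], "d_mm": self.d}).to_csv(
            path, index=False, float_format="%.9g"
        )


@dataclass
class IndentSeries:
    """(d, Delta) lag measurements with the obstacle half-width for rescaling."""

    d: np.ndarray
    delta: np.ndarray
    w_half: float
    h_half: float | None = None
    provenance: str = "closed-form"

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"d_mm": self.d, "delta_mm": self.delta, "w_half_mm": self.w_half}
        ).to_csv(path, index=False, float_format="%.9g")


@dataclass
class KinkMetrics:
    """Front position and opening angle (degrees) at kink formation."""

    d_kink: float
    phi: float


@dataclass
class ArrivalField:
    """First-arrival time T (hours) on a rectangular grid.

    T solves |grad T| = 1/v with T = (y - y0_front)/v on the founder line;
    blocked (obstacle) cells carry T = +inf.  Cell centers sit at
    x = a/2 + j*a, y = a/2 + i*a for T[i, j].
    """

    T: np.ndarray
    blocked: np.ndarray
    a: float
    v: float
    y0_front: float
    env: Environment

    @property
    def x(self) -> np.ndarray:
        return self.a / 2.0 + self.a * np.arange(self.T.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.a / 2.0 + self.a * np.arange(self.T.shape[0])

    def save(self, path) -> None:
        """Portable array container (.npz) with grid metadata embedded."""
        np.savez_compressed(
            path, T=self.T, blocked=self.blocked,
            a=self.a, v=self.v, y0_front=self.y0_front,
        )


# ---------------------------------------------------------------------------
# closed forms: rhombus
# ---------------------------------------------------------------------------

def indent_rhombus(d, w_half: float):
    """Indent size Delta(d) behind a rhombus of half-width w_half.

    Delta = d * (1 - sqrt(1 - w^2/d^2)); independent of the obstacle height.
    Valid once the two arcs have met on the axis (d >= w_half); for large d
    the indent heals as Delta ~ w^2/(2 d).
    """
    if w_half <= 0:
        raise InvalidGeometryError("w_half must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < w_half):
        raise InvalidGeometryError("indent formula requires d >= w_half")
    out = d * (1.0 - np.sqrt(1.0 - (w_half / d) ** 2))
    return float(out) if out.ndim == 0 else out


def kink_distance_rhombus(w_half: float, h_half: float) -> float:
    """Front travel distance beyond the widest point at which the kink forms.

    d_kink = sqrt(w_half^2 + h_half^2); a degenerate slit (h_half = 0) gives
    d_kink = w_half.
    """
    if w_half <= 0 or h_half < 0:
        raise InvalidGeometryError("rhombus dimensions must be positive (h_half >= 0)")
    return math.hypot(w_half, h_half)


def kink_opening_angle_rhombus(d: float, w_half: float) -> float:
    """Opening angle (degrees) of the axis kink at front position d.

    The two arcs meet at angle phi = 180 - 2*asin(w/d); phi grows toward 180
    as the kink heals.
    """
    if d < w_half:
        raise NotYetFormedError("arcs have not met on the axis yet", d_kink=w_half)
    return 180.0 - 2.0 * math.degrees(math.asin(w_half / d))


def kink_metrics_rhombus(w_half: float, h_half: float) -> KinkMetrics:
    d_kink = kink_distance_rhombus(w_half, h_half)
    return KinkMetrics(d_kink=d_kink, phi=kink_opening_angle_rhombus(d_kink, w_half))


def front_rhombus(
    d: float,
    w_half: float,
    h_half: float,
    center: tuple[float, float] = (0.0, 0.0),
    x_half_span: float | None = None,
    arc_step_deg: float = 0.5,
) -> FrontCurve:
    """Closed-form constant-speed front around an axis-centered rhombus.

    Piecewise construction (y measured via the unperturbed front y = cy + d):

    * d < -h_half: a single straight line (obstacle not yet reached);
    * -h_half <= d < 0: straight line interrupted over the obstacle
      cross-section at that height;
    * d >= 0: straight outer segments plus circular arcs of radius d centered
      at the widest points (cx +- w_half, cy), truncated where they hit the
      obstacle edge (at 90 degrees, pre-kink) or each other (post-kink).
    """
    if w_half <= 0 or h_half <= 0:
        raise InvalidGeometryError("rhombus half-dimensions must be positive")
    cx, cy = center
    X = x_half_span if x_half_span is not None else w_half + max(3.0 * w_half, d)
    yf = cy + d

    if d < -h_half:
        seg = np.array([[cx - X, yf], [cx + X, yf]])
        return FrontCurve((seg,), d, "closed-form")

    if d < 0:
        g = w_half * (1.0 + d / h_half)  # obstacle half-width at this height
        left = np.array([[cx - X, yf], [cx - g, yf]])
        right = np.array([[cx + g, yf], [cx + X, yf]])
        return FrontCurve((left, right), d, "closed-form")

    # d >= 0: arcs of radius d centered at the widest points
    alpha = math.atan2(w_half, h_half)  # edge direction angle from +y
    d_kink = math.hypot(w_half, h_half)
    if d >= d_kink and d > 0:
        phi_end = math.asin(min(1.0, w_half / d))
        contact = False
    else:
        phi_end = alpha
        contact = True

    n_arc = max(2, int(math.degrees(phi_end) / arc_step_deg) + 1)
    phi = np.linspace(0.0, phi_end, n_arc)
    # left arc: center (cx - w, cy), sweeping from the top toward the axis
    lx = cx - w_half + d * np.sin(phi)
    ly = cy + d * np.cos(phi)
    left_arc = np.column_stack([lx, ly])
    right_arc = np.column_stack([2 * cx - lx, ly])[::-1]

    left_line = np.array([[cx - X, yf], [cx - w_half, yf]])
    right_line = np.array([[cx + w_half, yf], [cx + X, yf]])

    arcs = [
        {"center": (cx - w_half, cy), "radius": d, "phi": (0.0, phi_end),
         "side": "left", "ends_on_obstacle": contact},
        {"center": (cx + w_half, cy), "radius": d, "phi": (0.0, phi_end),
         "side": "right", "ends_on_obstacle": contact},
    ]
    if contact and d > 0:
        # arc ends on the obstacle edge; front has a gap across the apex region
        segs = (
            np.vstack([left_line, left_arc]),
            np.vstack([right_arc, right_line]),
        )
    else:
        merged = np.vstack([left_line, left_arc, right_arc[1:], right_line])
        segs = (merged,)
    return FrontCurve(segs, d, "closed-form", arcs=arcs)


def indent_series_rhombus(w_half: float, h_half: float, d: np.ndarray) -> IndentSeries:
    """Closed-form Delta(d) series for a rhombus, tagged with both half-sizes."""
    d = np.asarray(d, dtype=float)
    return IndentSeries(d, indent_rhombus(d, w_half), w_half, h_half, "closed-form")


# ---------------------------------------------------------------------------
# closed forms: circle and tilted bar
# ---------------------------------------------------------------------------

def circle_axis_lag(d: float, r: float) -> float:
    """Axis lag Delta behind a circular obstacle of radius r, after the cusp.

    The most-lagging axis point y_f is reached by the shortest path grazing
    the disk (vertical tangent, arc, tangent segment), so y_f solves

        d = r * asin(r / y_f) + sqrt(y_f^2 - r^2),

    and Delta = d - y_f.  The cusp forms at y_f = r, i.e. d = pi*r/2, with
    vanishing opening angle; far downstream Delta -> r^2/(2 d), the same
    universal healing law as for a rhombus of equal width.
    """
    if r < 0:
        raise InvalidGeometryError("radius must be non-negative")
    if r == 0:
        return 0.0
    d_cusp = math.pi * r / 2.0
    if d < d_cusp - 1e-12:
        raise NotYetFormedError(
            f"cusp has not formed yet (d < pi*r/2 = {d_cusp:.6g})", d_kink=d_cusp
        )

    def g(y):
        return r * math.asin(min(1.0, r / y)) + math.sqrt(max(0.0, y * y - r * r)) - d

    if g(r) >= 0:  # d == d_cusp (within tolerance)
        return d - r
    y_f = brentq(g, r, r + d, xtol=1e-13, rtol=1e-14)
    return d - y_f


def tilted_bar_kink_axis(d: float, L_proj_half: float, tilt_deg: float) -> float:
    """Lateral kink-tip coordinate behind a tilted thin bar (relative to center).

    The bar's endpoints sit at (-L, -h) and (+L, +h) with h = L*tan(tilt); the
    front wraps them with arcs of radius d + h (leading end, passed first) and
    d - h (trailing end).  Intersecting the two circles gives the kink tip at

        x_tip = (h / L) * s,   s = L^2 * (d - sqrt(d^2 - L^2 - h^2)) / (L^2 + h^2),

    which lies on the trailing-edge side and approaches the bisecting normal
    (x = 0) monotonically as d grows.
    """
    if L_proj_half <= 0:
        raise InvalidGeometryError("projected half-width must be positive")
    if not (0 <= tilt_deg < 90):
        raise InvalidGeometryError("tilt must be in [0, 90) degrees")
    L = L_proj_half
    h = L * math.tan(math.radians(tilt_deg))
    d_kink = math.hypot(L, h)
    if d < d_kink:
        raise NotYetFormedError("kink has not formed yet", d_kink=d_kink)
    s = L * L * (d - math.sqrt(d * d - L * L - h * h)) / (L * L + h * h)
    return h * s / L


# ---------------------------------------------------------------------------
# grid solver: first-order upwind fast sweeping (8-neighbour multistencil)
# ---------------------------------------------------------------------------

_INF = 1e30


@njit(cache=False)
def _dir_coeffs(T1, T2, h):
    """Upwind coefficients (alpha, aval) for one direction.

    Second-order one-sided difference (3T - 4T1 + T2)/(2h) when the second
    neighbour is usable and causal (T2 <= T1), else first order (T - T1)/h.
    The derivative term is alpha*(T - aval).
    """
    if T1 >= _INF:
        return 0.0, _INF
    if T2 < _INF and T2 <= T1:
        return 1.5 / h, (4.0 * T1 - T2) / 3.0
    return 1.0 / h, T1


@njit(cache=False)
def _pair_update(a1, v1, a2, v2, f):
    """Solve sum over active directions of (alpha*(T - aval))^2 = f^2."""
    # order so that v1 <= v2
    if v1 > v2:
        a1, v1, a2, v2 = a2, v2, a1, v1
    if v1 >= _INF:
        return _INF
    t1 = v1 + f / a1  # single-direction solution
    if v2 >= _INF or t1 <= v2:
        return t1
    A = a1 * a1 + a2 * a2
    B = -2.0 * (a1 * a1 * v1 + a2 * a2 * v2)
    C = a1 * a1 * v1 * v1 + a2 * a2 * v2 * v2 - f * f
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        return t1
    t = (-B + math.sqrt(disc)) / (2.0 * A)
    if t < v2:
        return t1
    return t


@njit(cache=False)
def _sweep(T, frozen, h, f, i0, i1, istep, j0, j1, jstep):
    """One Gauss-Seidel sweep over the padded grid; returns the max update."""
    sq2 = math.sqrt(2.0)
    maxdiff = 0.0
    for i in range(i0, i1, istep):
        for j in range(j0, j1, jstep):
            if frozen[i, j]:
                continue
            # x direction: best of left/right, each up to second order
            if T[i, j - 1] <= T[i, j + 1]:
                ax, vx = _dir_coeffs(T[i, j - 1], T[i, j - 2], h)
            else:
                ax, vx = _dir_coeffs(T[i, j + 1], T[i, j + 2], h)
            if T[i - 1, j] <= T[i + 1, j]:
                ay, vy = _dir_coeffs(T[i - 1, j], T[i - 2, j], h)
            else:
                ay, vy = _dir_coeffs(T[i + 1, j], T[i + 2, j], h)
            t = _pair_update(ax, vx, ay, vy, f)
            # diagonal stencil (rotated axes, spacing h*sqrt(2))
            hd = h * sq2
            if T[i - 1, j - 1] <= T[i + 1, j + 1]:
                ad, vd = _dir_coeffs(T[i - 1, j - 1], T[i - 2, j - 2], hd)
            else:
                ad, vd = _dir_coeffs(T[i + 1, j + 1], T[i + 2, j + 2], hd)
            if T[i - 1, j + 1] <= T[i + 1, j - 1]:
                ae, ve = _dir_coeffs(T[i - 1, j + 1], T[i - 2, j + 2], hd)
            else:
                ae, ve = _dir_coeffs(T[i + 1, j - 1], T[i + 2, j - 2], hd)
            t2 = _pair_update(ad, vd, ae, ve, f)
            if t2 < t:
                t = t2
            if t < T[i, j]:
                diff = T[i, j] - t
                if diff > maxdiff:
                    maxdiff = diff
                T[i, j] = t
    return maxdiff


@njit(cache=False)
def _sweep_until_converged(T, frozen, h, f, tol, max_cycles):
    for _ in range(max_cycles):
        ny, nx = T.shape
        m = 0.0
        m = max(m, _sweep(T, frozen, h, f, 2, ny - 2, 1, 2, nx - 2, 1))
        m = max(m, _sweep(T, frozen, h, f, 2, ny - 2, 1, nx - 3, 1, -1))
        m = max(m, _sweep(T, frozen, h, f, ny - 3, 1, -1, 2, nx - 2, 1))
        m = max(m, _sweep(T, frozen, h, f, ny - 3, 1, -1, nx - 3, 1, -1))
        if m < tol:
            break


def rasterize_blocked(env: Environment, a: float) -> np.ndarray:
    """Cell-center obstacle mask shared by the eikonal and PDE engines.

    A cell is blocked iff its center lies in the closed region of an obstacle
    polygon (boundary counts as obstacle).
    """
    nx = int(round(env.Lx / a))
    ny = int(round(env.Ly / a))
    xs = a / 2.0 + a * np.arange(nx)
    ys = a / 2.0 + a * np.arange(ny)
    X, Y = np.meshgrid(xs, ys)
    blocked = np.zeros((ny, nx), dtype=bool)
    for ob in env.obstacles:
        blocked |= shapely.intersects_xy(ob.polygon, X.ravel(), Y.ravel()).reshape(ny, nx)
    return blocked


def solve_arrival(
    env: Environment,
    v: float,
    a_eik: float | None = None,
    y0_front: float = 0.0,
    tol_factor: float = 1e-7,
    max_cycles: int = 200,
) -> ArrivalField:
    """First-arrival time around the environment's obstacles.

    Solves |grad T| = 1/v by first-order upwind fast sweeping with an
    8-neighbour multistencil.  The founder line y = y0_front carries
    T = 0; cells at or below it are frozen at their planar value
    (y - y0_front)/v so that obstacle-free columns stay exactly planar.
    """
    if v <= 0:
        raise InvalidGeometryError("front speed must be positive")
    w_min = min((o.w_half for o in env.obstacles), default=None)
    if a_eik is None:
        a_eik = (w_min / 100.0) if w_min is not None else env.Lx / 200.0
    if w_min is not None and a_eik > w_min / 20.0:
        warnings.warn(
            f"grid spacing {a_eik:.4g} coarser than w_half/20 = {w_min / 20.0:.4g}; "
            "arrival times may be under-resolved",
            stacklevel=2,
        )
    for ob in env.obstacles:
        ymin = ob.vertices[:, 1].min()
        if ymin <= y0_front:
            raise InvalidGeometryError("y0_front must lie below every obstacle")

    blocked = rasterize_blocked(env, a_eik)
    ny, nx = blocked.shape
    ys = a_eik / 2.0 + a_eik * np.arange(ny)

    pad = 2  # second-order one-sided differences need two ghost layers
    Tp = np.full((ny + 2 * pad, nx + 2 * pad), _INF)
    frozen = np.ones_like(Tp, dtype=np.bool_)  # border stays frozen at INF
    frozen[pad:-pad, pad:-pad] = blocked
    src = ys <= y0_front
    if not src.any():
        src[0] = True  # founder line below the grid: seed the first row
    src2d = np.broadcast_to(src[:, None], (ny, nx)) & ~blocked
    planar2d = np.broadcast_to(((ys - y0_front) / v)[:, None], (ny, nx))
    interior = Tp[pad:-pad, pad:-pad]
    interior[src2d] = planar2d[src2d]
    frozen[pad:-pad, pad:-pad] |= src2d

    fh = a_eik / v
    _sweep_until_converged(Tp, frozen, a_eik, 1.0 / v, tol_factor * fh, max_cycles)

    T = Tp[pad:-pad, pad:-pad].copy()
    T[blocked] = np.inf
    return ArrivalField(T=T, blocked=blocked, a=a_eik, v=v, y0_front=y0_front, env=env)


def front_from_arrival(field: ArrivalField, d: float, y_ref: float | None = None) -> FrontCurve:
    """Sub-cell interpolated level set of T at front position d.

    The level is tau = (y_ref + d - y0_front)/v, where y_ref is the reference
    obstacle's y_maxwidth (d labels use the unperturbed lateral-edge columns,
    which advance exactly at speed v).
    """
    if y_ref is None:
        if len(field.env.obstacles) != 1:
            raise EmptyFrontError("y_ref required unless the environment has exactly one obstacle")
        y_ref = field.env.obstacles[0].y_maxwidth
    tau = (y_ref + d - field.y0_front) / field.v
    Tm = np.where(field.blocked, np.nan, field.T)
    contours = measure.find_contours(Tm, tau)
    if not contours:
        raise EmptyFrontError(f"level T = {tau:.6g} does not intersect the grid interior")
    a = field.a
    segs = []
    for c in contours:
        xy = np.column_stack([a / 2.0 + a * c[:, 1], a / 2.0 + a * c[:, 0]])
        if xy[0, 0] > xy[-1, 0]:
            xy = xy[::-1]
        segs.append(xy)
    segs.sort(key=lambda s: s[:, 0].mean())
    return FrontCurve(tuple(segs), d, "grid")


def marker_path(field: ArrivalField, end: tuple[float, float]) -> np.ndarray:
    """Steepest-descent backtrace of T from ``end`` to the founder line.

    Returns an (n, 2) polyline from the founder line to ``end``.  The discrete
    descent moves between 8-neighbour cell centers choosing the direction of
    steepest descent per unit length; exact ties resolve toward smaller |x|
    relative to the end point's column for reproducibility.
    """
    a = field.a
    j = int(np.clip(round((end[0] - a / 2.0) / a), 0, field.T.shape[1] - 1))
    i = int(np.clip(round((end[1] - a / 2.0) / a), 0, field.T.shape[0] - 1))
    if field.blocked[i, j] or not np.isfinite(field.T[i, j]):
        raise InvalidGeometryError("marker end point lies inside an obstacle")
    ny, nx = field.T.shape
    path = [(a / 2.0 + a * j, a / 2.0 + a * i)]
    T = field.T
    steps = 0
    max_steps = 4 * (ny + nx)
    min_rate = 1e-6 * a / field.v  # a move must strictly descend
    j_end = (end[0] - a / 2.0) / a
    while T[i, j] > 0 and steps < max_steps:
        best = None
        best_rate = 0.0
        best_absx = np.inf
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                ii, jj = i + di, j + dj
                if not (0 <= ii < ny and 0 <= jj < nx) or field.blocked[ii, jj]:
                    continue
                rate = (T[i, j] - T[ii, jj]) / math.hypot(di, dj)
                if rate < min_rate:
                    continue
                absx = abs(jj - j_end)
                if (
                    best is None
                    or rate > best_rate * (1 + 1e-9)
                    or (rate >= best_rate * (1 - 1e-9) and absx < best_absx)
                ):
                    best, best_rate, best_absx = (ii, jj), max(best_rate, rate), absx
        if best is None:
            break
        i, j = best
        path.append((a / 2.0 + a * j, a / 2.0 + a * i))
        steps += 1
    return np.asarray(path[::-1])


def path_length(path: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(path, axis=0).T)))
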