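"""Engine-agnostic front measurements.

The measurement operators mirror the image-analysis definitions used for
experimental fronts: the indent Delta is the distance between the most lagging
part of the front (in a window around the symmetry axis) and the unperturbed
front position d; the collapse check rescales indent curves by each obstacle's
half-width w and reports the maximum pairwise sup-distance.  All operators are
invariant under rigid translation of front + obstacle and equivariant under
uniform scaling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .eikonal import FrontCurve, IndentSeries
from .environments import Obstacle
from .errors import AlignmentError, MeasurementError, NotApplicableError

__all__ = [
    "CollapseReport",
    "indent_from_front",
    "contact_angle",
    "collapse_check",
]


@dataclass
class CollapseReport:
    """Rescaled indent curves and their maximum pairwise sup-distance."""

    d_over_w: np.ndarray
    curves: list  # rescaled delta/w arrays, one per series
    max_sup_distance: float
    rescale_by: str  # "w" or "h"
    tolerance: float
    passed: bool

    def to_json(self, path=None) -> str:
        payload = {
            "rescale_by": self.rescale_by,
            "max_sup_distance": self.max_sup_distance,
            "tolerance": self.tolerance,
            "passed": self.passed,
            "d_over_w": self.d_over_w.tolist(),
            "curves": [c.tolist() for c in self.curves],
        }
        s = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _windowed_min_y(front: FrontCurve, x_axis: float, window_half: float) -> float:
    """Minimum y of the polyline restricted to |x - x_axis| <= window_half,
    interpolating along edges that cross the window boundary."""
    lo, hi = x_axis - window_half, x_axis + window_half
    best = np.inf
    for seg in front.segments:
        m = (seg[:, 0] >= lo) & (seg[:, 0] <= hi)
        if m.any():
            best = min(best, float(seg[m, 1].min()))
        # edges crossing the window boundaries contribute interpolated points
        for xb in (lo, hi):
            x0, x1 = seg[:-1, 0], seg[1:, 0]
            cross = ((x0 - xb) * (x1 - xb) < 0)
            if cross.any():
                t = (xb - x0[cross]) / (x1[cross] - x0[cross])
                yb = seg[:-1, 1][cross] + t * (seg[1:, 1][cross] - seg[:-1, 1][cross])
                best = min(best, float(yb.min()))
    if not np.isfinite(best):
        raise MeasurementError(
            f"front does not enter the window +-{window_half:.3g} around x = {x_axis:.3g}"
        )
    return best


def indent_from_front(
    front: FrontCurve,
    obstacle: Obstacle,
    d: float | None = None,
    window_half: float | None = None,
) -> float:
    """Indent Delta = d - (most lagging y in the axis window, relative to
    y_maxwidth).

    The window defaults to +-w_half around the obstacle's symmetry axis.
    A front that overshoots the unperturbed position clamps to 0.
    """
    d = front.d if d is None else d
    if d is None:
        raise MeasurementError("front carries no d label and none was given")
    window_half = window_half if window_half is not None else obstacle.w_half
    cx = obstacle.center[0]
    y_min = _windowed_min_y(front, cx, window_half)
    delta = (obstacle.y_maxwidth + d) - y_min
    return max(0.0, float(delta))


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Undirected angle between two line directions, in [0, 90] degrees."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = abs(float(np.dot(u, v)))
    return math.degrees(math.acos(min(1.0, c)))


def _nearest_edge_tangent(obstacle: Obstacle, p: np.ndarray) -> np.ndarray:
    verts = obstacle.vertices
    n = len(verts)
    best, best_dist = None, np.inf
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        dist = np.linalg.norm(p - (a + t * ab))
        if dist < best_dist:
            best, best_dist = ab, dist
    return best


def contact_angle(front: FrontCurve, obstacle: Obstacle, contact_tol: float | None = None) -> float:
    """Angle (degrees) between the front and the obstacle edge at contact.

    For closed-form fronts the arc metadata gives the exact tangents: the arc
    tangent at the contact point is perpendicular to the radius, which runs
    along the obstacle edge, so the constant-speed front meets the edge at
    exactly 90 degrees.  For discretized (grid/PDE) fronts the tangents are
    estimated by local line fits near the point of closest approach.
    """
    if front.arcs:
        arcs = [a for a in front.arcs if a.get("ends_on_obstacle")]
        if not arcs:
            raise NotApplicableError("closed-form front does not touch the obstacle")
        arc = arcs[0]
        cx, cy = arc["center"]
        r, (_, phi1) = arc["radius"], arc["phi"]
        sgn = 1.0 if arc.get("side") == "left" else -1.0
        radial = np.array([sgn * math.sin(phi1), math.cos(phi1)])
        tangent = np.array([-radial[1], radial[0]])
        contact = np.array([cx, cy]) + r * radial
        edge = _nearest_edge_tangent(obstacle, contact)
        return _angle_between(tangent, edge)

    poly = obstacle.polygon
    boundary = poly.exterior
    from shapely.geometry import Point

    best_seg, best_i, best_dist, best_dists = None, None, np.inf, None
    for seg in front.segments:
        dists = np.array([boundary.distance(Point(p)) for p in seg])
        i = int(np.argmin(dists))
        if dists[i] < best_dist:
            best_seg, best_i, best_dist, best_dists = seg, i, dists[i], dists
    if contact_tol is None:
        span = np.ptp(np.vstack(front.segments), axis=0).max()
        contact_tol = 0.05 * span
    if best_dist > contact_tol:
        raise NotApplicableError(
            f"front does not contact the obstacle (closest approach {best_dist:.3g})"
        )
    p0 = best_seg[best_i]
    # tangent from a circle (Kasa) fit near the contact — exact for the
    # circular-arc fronts of the constant-speed model.  Contour vertices
    # within ~3 cells of the obstacle are distorted by the obstacle mask and
    # are excluded; the fitted circle is then intersected with the edge line
    # so the tangent is evaluated at the contact itself.
    step = max(float(np.median(np.hypot(*np.diff(best_seg, axis=0).T))), 1e-12)
    # first-order arrival fields drag a numerical boundary layer (~10 cells)
    # along blocked walls; fit outside it and extrapolate to the edge
    ok = best_dists >= 12 * step
    if ok.sum() >= 5:
        cands = np.nonzero(ok)[0]
        i1 = int(cands[np.argmin(best_dists[cands])])
    else:
        ok = np.ones(len(best_seg), dtype=bool)
        i1 = best_i
    p1 = best_seg[i1]
    near = (np.hypot(*(best_seg - p1).T) <= 60 * step) & ok
    pts = best_seg[near]
    if len(pts) < 3:
        pts = best_seg[max(0, best_i - 3): best_i + 4]
    front_tan = _tangent_at_edge(pts, p1, obstacle, p0)
    edge = _nearest_edge_tangent(obstacle, p0)
    return _angle_between(front_tan, edge)


def _tangent_at_edge(pts: np.ndarray, p1: np.ndarray, obstacle: Obstacle,
                     p0: np.ndarray) -> np.ndarray:
    """Front tangent at the obstacle contact: circle-fit through ``pts``,
    evaluated where the fitted circle crosses the nearest obstacle edge."""
    fit = _fit_circle(pts)
    if fit is None:
        return _local_tangent(pts, p1)
    center, r = fit
    verts = obstacle.vertices
    n = len(verts)
    dists = []
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        ab = b - a
        t = np.clip(np.dot(p0 - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        dists.append((np.linalg.norm(p0 - (a + t * ab)), a, ab))
    _, a, ab = min(dists, key=lambda x: x[0])
    # intersect line a + t*ab with the fitted circle
    f = a - center
    A = np.dot(ab, ab)
    B = 2 * np.dot(f, ab)
    C = np.dot(f, f) - r * r
    disc = B * B - 4 * A * C
    if disc < 0:
        radial = p1 - center
    else:
        ts = [(-B - math.sqrt(disc)) / (2 * A), (-B + math.sqrt(disc)) / (2 * A)]
        cands = [a + t * ab for t in ts]
        contact = min(cands, key=lambda q: np.linalg.norm(q - p0))
        radial = contact - center
    nr = np.linalg.norm(radial)
    if nr < 1e-12:
        return _local_tangent(pts, p1)
    radial /= nr
    return np.array([-radial[1], radial[0]])


def _fit_circle(pts: np.ndarray):
    """Algebraic (Kasa) circle fit; None if degenerate or nearly straight."""
    ctr = pts.mean(axis=0)
    q = pts - ctr
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    span = float(np.ptp(q @ vt[0]))
    A = np.column_stack([2 * q[:, 0], 2 * q[:, 1], np.ones(len(q))])
    b = (q ** 2).sum(axis=1)
    try:
        (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    r = math.sqrt(max(c + cx * cx + cy * cy, 0.0))
    if not np.isfinite(r) or r > 50 * max(span, 1e-12):
        return None
    return ctr + np.array([cx, cy]), r


def _local_tangent(pts: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Total-least-squares line direction of a local point cloud."""
    q = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    return vt[0]


def collapse_check(
    series: list[IndentSeries],
    tolerance: float = 1e-9,
    n_grid: int = 200,
    rescale_by: str = "w",
) -> CollapseReport:
    """Rescale indent curves and measure how well they collapse.

    With ``rescale_by='w'`` each curve is plotted as Delta/w vs d/w (the
    constant-speed prediction makes these identical for all rhombi);
    ``rescale_by='h'`` uses the half-height instead, the negative control that
    demonstrably collapses worse.  Curves are interpolated onto a common
    rescaled-d grid spanning the shared range.
    """
    if len(series) < 2:
        raise AlignmentError("collapse check needs at least two series")
    scales = []
    for s in series:
        if rescale_by == "w":
            scales.append(s.w_half)
        elif rescale_by == "h":
            if s.h_half is None:
                raise AlignmentError("h-rescaling requires h_half on every series")
            scales.append(s.h_half)
        else:
            raise AlignmentError(f"unknown rescaling {rescale_by!r}")
    lo = max(s.d.min() / sc for s, sc in zip(series, scales))
    hi = min(s.d.max() / sc for s, sc in zip(series, scales))
    if hi <= lo:
        raise AlignmentError("series do not share a common rescaled d range")
    grid = np.linspace(lo, hi, n_grid)
    curves = [np.interp(grid, s.d / sc, s.delta / sc) for s, sc in zip(series, scales)]
    sup = 0.0
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            sup = max(sup, float(np.max(np.abs(curves[i] - curves[j]))))
    return CollapseReport(
        d_over_w=grid, curves=curves, max_sup_distance=sup,
        rescale_by=rescale_by, tolerance=tolerance, passed=sup <= tolerance,
    )
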