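"""Growth-permitting / growth-free habitat geometry.

A habitat is an axis-aligned rectangle ``[0, Lx] x [0, Ly]`` (mm) in which a
population front propagates along +y.  Compact *obstacles* — regions where the
growth rate is zero — are stored as simple polygons in continuous coordinates
and shared by all three propagation engines (constant-speed, reaction-diffusion,
stochastic lattice).  Obstacle polygons are closed sets: the boundary counts as
obstacle, which makes downstream rasterization deterministic.

Conventions
-----------
* x is the lateral coordinate, +y the propagation direction.
* ``y_maxwidth`` is the y coordinate of an obstacle's point(s) of maximal
  lateral extent; front positions *d* are measured from it (d = 0 when the
  unperturbed front passes the widest point).
* Circles are stored as fine regular polygons (default 360 vertices) so that
  every engine consumes a single geometry representation; the polygonal area
  deficit is O(n^-2) and ``w_half`` is reported as the nominal radius r.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .errors import InvalidGeometryError, OutOfDomainError, PackingError

__all__ = [
    "Obstacle",
    "Environment",
    "make_rhombus",
    "make_circle",
    "make_square",
    "make_tilted_bar",
    "make_two_obstacle_config",
    "make_random_field",
    "contains",
    "contains_many",
]

_GEOM_RTOL = 1e-9


@dataclass(frozen=True)
class Obstacle:
    """A simple, counterclockwise polygonal growth-free region (mm).

    ``w_half`` is half the maximal extent perpendicular to propagation;
    ``h_half`` half the extent along propagation for rhombi; ``r`` the nominal
    radius for circle approximations; ``L_proj_half``/``tilt_deg`` describe
    tilted thin bars by their projected half-width and tilt angle.
    """

    vertices: np.ndarray
    kind: str  # rhombus | circle-approx | tilted-bar | polygon
    w_half: float
    y_maxwidth: float
    h_half: float | None = None
    r: float | None = None
    L_proj_half: float | None = None
    tilt_deg: float | None = None

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidGeometryError("vertices must be an (n>=3, 2) array")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise InvalidGeometryError("obstacle polygon must be simple with positive area")
        if self.w_half <= 0:
            raise InvalidGeometryError("w_half must be positive")
        if self.kind == "circle-approx" and self.r is not None:
            c = np.asarray(poly.centroid.coords[0])
            rad = np.hypot(*(v - c).T)
            if not np.allclose(rad, self.r, rtol=1e-6, atol=0):
                raise InvalidGeometryError("circle-approx vertices must lie on a circle of radius r")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def center(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    def translated(self, dx: float, dy: float) -> "Obstacle":
        return replace(self, vertices=self.vertices + [dx, dy], y_maxwidth=self.y_maxwidth + dy)

    def scaled(self, s: float, origin: tuple[float, float] = (0.0, 0.0)) -> "Obstacle":
        """Uniform scaling about ``origin``; all stored lengths scale by s."""
        if s <= 0:
            raise InvalidGeometryError("scale factor must be positive")
        o = np.asarray(origin, dtype=float)
        return replace(
            self,
            vertices=o + s * (self.vertices - o),
            w_half=s * self.w_half,
            y_maxwidth=origin[1] + s * (self.y_maxwidth - origin[1]),
            h_half=None if self.h_half is None else s * self.h_half,
            r=None if self.r is None else s * self.r,
            L_proj_half=None if self.L_proj_half is None else s * self.L_proj_half,
        )

    def covers(self, x: float, y: float) -> bool:
        """Closed-set membership: boundary points count as obstacle."""
        return bool(self.polygon.covers(Point(x, y)))


def make_rhombus(w_half: float, h_half: float, center: tuple[float, float] = (0.0, 0.0)) -> Obstacle:
    """Rhombus of lateral half-width ``w_half`` and half-height ``h_half`` (mm).

    Vertices sit at center +- (w_half, 0) and center +- (0, h_half); the point
    of maximal width is the center row, so ``y_maxwidth = center_y``.
    """
    if w_half <= 0 or h_half <= 0:
        raise InvalidGeometryError("rhombus half-dimensions must be positive")
    cx, cy = center
    verts = np.array(
        [[cx + w_half, cy], [cx, cy + h_half], [cx - w_half, cy], [cx, cy - h_half]]
    )
    return Obstacle(verts, "rhombus", w_half=w_half, h_half=h_half, y_maxwidth=cy)


def make_circle(r: float, center: tuple[float, float] = (0.0, 0.0), n_vertices: int = 360) -> Obstacle:
    """Circle of radius r approximated by a regular n-gon (counterclockwise).

    ``w_half`` is reported as the nominal radius r; the inscribed polygon's
    half-width is r*cos(pi/n) and its area deficit relative to pi r^2 is
    O(n^-2), negligible at the default n = 360.
    """
    if r <= 0:
        raise InvalidGeometryError("radius must be positive")
    if n_vertices < 16:
        raise InvalidGeometryError("circle approximation needs at least 16 vertices")
    cx, cy = center
    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    verts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    return Obstacle(verts, "circle-approx", w_half=r, y_maxwidth=cy, r=r)


def make_square(side: float, center: tuple[float, float] = (0.0, 0.0)) -> Obstacle:
    """Axis-aligned square feature of linear size ``side`` (random fields)."""
    if side <= 0:
        raise InvalidGeometryError("square side must be positive")
    cx, cy = center
    h = side / 2.0
    verts = np.array([[cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h], [cx - h, cy - h]])
    return Obstacle(verts, "polygon", w_half=h, y_maxwidth=cy + h, h_half=h)


def make_tilted_bar(
    L_proj_half: float,
    tilt_deg: float,
    center: tuple[float, float] = (0.0, 0.0),
    thickness: float | None = None,
) -> Obstacle:
    """Thin bar of projected half-width ``L_proj_half``, tilted by ``tilt_deg``.

    The bar's endpoints project onto +-L_proj_half on the x axis; the tilt
    raises the trailing endpoint by L_proj_half*tan(tilt).  A small finite
    thickness (default L_proj_half/50) makes the polygon non-degenerate.
    ``y_maxwidth`` is the mid-height of the bar (0 relative to center): for a
    thin tilted bar the extremes of lateral extent are the two endpoints and
    the conventional reference is their mean.
    """
    if L_proj_half <= 0:
        raise InvalidGeometryError("projected half-width must be positive")
    if not (0 <= tilt_deg < 90):
        raise InvalidGeometryError("tilt must be in [0, 90) degrees")
    t = thickness if thickness is not None else L_proj_half / 50.0
    cx, cy = center
    tan = math.tan(math.radians(tilt_deg))
    a = np.array([cx - L_proj_half, cy - L_proj_half * tan])
    b = np.array([cx + L_proj_half, cy + L_proj_half * tan])
    axis = (b - a) / np.linalg.norm(b - a)
    n = np.array([-axis[1], axis[0]]) * (t / 2.0)
    verts = np.array([a - n, b - n, b + n, a + n])
    return Obstacle(
        verts, "tilted-bar", w_half=L_proj_half, y_maxwidth=cy,
        L_proj_half=L_proj_half, tilt_deg=tilt_deg,
    )


@dataclass(frozen=True)
class Environment:
    """Rectangular habitat ``[0, Lx] x [0, Ly]`` with disjoint obstacles (mm)."""

    Lx: float
    Ly: float
    obstacles: tuple[Obstacle, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "obstacles", tuple(self.obstacles))
        if self.Lx <= 0 or self.Ly <= 0:
            raise InvalidGeometryError("domain dimensions must be positive")
        polys = [o.polygon for o in self.obstacles]
        box = shapely.box(0, 0, self.Lx, self.Ly)
        for p in polys:
            if not box.contains(p):
                raise InvalidGeometryError("every obstacle must lie strictly inside the domain")
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                if polys[i].intersects(polys[j]):
                    raise InvalidGeometryError(f"obstacles {i} and {j} overlap or touch")

    @property
    def domain_area(self) -> float:
        return self.Lx * self.Ly

    @property
    def obstacle_area(self) -> float:
        return sum(o.area for o in self.obstacles)

    @property
    def rho(self) -> float:
        """Growth-permitting area fraction, 1 - (obstacle area)/(domain area)."""
        return 1.0 - self.obstacle_area / self.domain_area

    @property
    def n_obstacles(self) -> int:
        return len(self.obstacles)

    def scaled(self, s: float) -> "Environment":
        return Environment(
            self.Lx * s, self.Ly * s,
            tuple(o.scaled(s) for o in self.obstacles),
            dict(self.metadata),
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": "rangefront-env-1",
            "domain_mm": [self.Lx, self.Ly],
            "obstacles": [
                {
                    "kind": o.kind,
                    "vertices_mm": np.asarray(o.vertices).tolist(),
                    "w_half_mm": o.w_half,
                    "y_maxwidth_mm": o.y_maxwidth,
                    "h_half_mm": o.h_half,
                    "r_mm": o.r,
                    "L_proj_half_mm": o.L_proj_half,
                    "tilt_deg": o.tilt_deg,
                }
                for o in self.obstacles
            ],
            "metadata": self.metadata,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        if d.get("schema") != "rangefront-env-1":
            raise InvalidGeometryError(f"unsupported environment schema: {d.get('schema')!r}")
        obstacles = tuple(
            Obstacle(
                np.asarray(ob["vertices_mm"], dtype=float),
                ob["kind"],
                w_half=ob["w_half_mm"],
                y_maxwidth=ob["y_maxwidth_mm"],
                h_half=ob.get("h_half_mm"),
                r=ob.get("r_mm"),
                L_proj_half=ob.get("L_proj_half_mm"),
                tilt_deg=ob.get("tilt_deg"),
            )
            for ob in d["obstacles"]
        )
        return cls(d["domain_mm"][0], d["domain_mm"][1], obstacles, d.get("metadata", {}))

    @classmethod
    def from_json(cls, path) -> "Environment":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def contains(env: Environment, p: tuple[float, float]) -> bool:
    """True iff p lies in the closed region of some obstacle.

    Raises OutOfDomainError for points outside the habitat rectangle.
    """
    x, y = p
    if not (0 <= x <= env.Lx and 0 <= y <= env.Ly):
        raise OutOfDomainError(f"point {p} lies outside the domain [0,{env.Lx}]x[0,{env.Ly}]")
    return any(o.covers(x, y) for o in env.obstacles)


def contains_many(env: Environment, pts: np.ndarray) -> np.ndarray:
    """Vectorized closed-set obstacle membership for an (n, 2) point array."""
    pts = np.asarray(pts, dtype=float)
    if ((pts[:, 0] < 0) | (pts[:, 0] > env.Lx) | (pts[:, 1] < 0) | (pts[:, 1] > env.Ly)).any():
        raise OutOfDomainError("some points lie outside the domain")
    inside = np.zeros(len(pts), dtype=bool)
    for ob in env.obstacles:
        inside |= shapely.intersects_xy(ob.polygon, pts[:, 0], pts[:, 1])
    return inside


def make_two_obstacle_config(
    engine: str,
    w_half: float = 1.2,
    h_half: float = 0.9,
    R: float = 80.0,
    W: float | None = None,
) -> Environment:
    """The two staggered-obstacle configurations used by the PDE and lattice engines.

    ``engine='pde'``: two rhombi (w = 1.2 mm, h = 0.9 mm by default) whose
    centers are offset by 2 mm horizontally and 2 mm vertically.

    ``engine='eden'``: two circular obstacles of radius R (lattice units) with
    center-to-center offset (5/3*R, 5/2*R); the system width W defaults to
    7.5*R (the printed width-to-radius ratio) and the first obstacle center
    sits one third of the system width ahead of the founder row (y = 0 line),
    laterally centered.
    """
    if engine == "pde":
        c1 = (6.0, 2.6)
        c2 = (c1[0] + 2.0, c1[1] + 2.0)
        obs = (make_rhombus(w_half, h_half, c1), make_rhombus(w_half, h_half, c2))
        return Environment(16.0, 12.0, obs, {"config": "two-obstacle-pde", "offset_mm": [2.0, 2.0]})
    if engine == "eden":
        if R <= 0:
            raise InvalidGeometryError("obstacle radius must be positive")
        W = 7.5 * R if W is None else W
        c1 = (W / 2.0, W / 3.0)
        c2 = (c1[0] + 5.0 / 3.0 * R, c1[1] + 5.0 / 2.0 * R)
        depth = c2[1] + R + 3.0 * R + 10.0
        obs = (make_circle(R, c1), make_circle(R, c2))
        return Environment(
            W, depth, obs,
            {"config": "two-obstacle-eden", "offset_lattice": [5.0 / 3.0 * R, 5.0 / 2.0 * R]},
        )
    raise InvalidGeometryError(f"unknown engine tag {engine!r}; expected 'pde' or 'eden'")


def make_random_field(
    rho: float,
    N: int,
    L: float,
    domain: tuple[float, float],
    seed: int,
    shape: str = "square",
    max_attempts: int = 20000,
) -> Environment:
    """Random field of N non-overlapping features of linear size L (mm).

    Features (axis-aligned squares of side L by default, circles of diameter L
    with ``shape='circle'``) are placed by rejection sampling with the given
    seed.  The realized growth-permitting fraction 1 - N*L^2/(Lx*Ly) (exact
    polygon area) must agree with the target ``rho`` to within 2% (relative),
    otherwise the request is rejected as inconsistent.  Infeasible packings
    raise PackingError naming the attempted count.
    """
    Lx, Ly = domain
    if not (0 < rho < 1):
        raise InvalidGeometryError("rho must lie strictly between 0 and 1")
    if N < 1:
        raise InvalidGeometryError("N must be at least 1")
    if L <= 0:
        raise InvalidGeometryError("feature size L must be positive")
    feature_area = L * L if shape == "square" else math.pi * (L / 2.0) ** 2
    total = N * feature_area
    if total >= Lx * Ly:
        raise PackingError(
            f"{N} features of size {L} cannot fit in a {Lx}x{Ly} domain "
            f"(obstacle area {total:.3g} >= domain area {Lx * Ly:.3g})",
            attempts=0,
        )
    realized_rho = 1.0 - total / (Lx * Ly)
    if abs(realized_rho - rho) > 0.02 * rho:
        raise InvalidGeometryError(
            f"N={N} features of size L={L} give growth fraction {realized_rho:.4f}, "
            f"more than 2% away from the target rho={rho}"
        )
    rng = np.random.default_rng(seed)
    placed: list[Obstacle] = []
    polys: list[Polygon] = []
    margin = L / 2.0 * (math.sqrt(2) if shape == "square" else 1.0) + 1e-9
    attempts = 0
    while len(placed) < N:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed only {len(placed)}/{N} features after {attempts} attempts",
                attempts=attempts,
            )
        attempts += 1
        cx = rng.uniform(margin, Lx - margin)
        cy = rng.uniform(margin, Ly - margin)
        ob = (
            make_square(L, (cx, cy))
            if shape == "square"
            else make_circle(L / 2.0, (cx, cy))
        )
        p = ob.polygon
        if any(p.intersects(q) for q in polys):
            continue
        placed.append(ob)
        polys.append(p)
    return Environment(
        Lx, Ly, tuple(placed),
        {"config": "random-field", "rho": rho, "N": N, "L": L, "seed": seed, "shape": shape},
    )
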