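"""Generalized FKPP reaction-diffusion engine.

Solves

    du/dt = D_eff * laplacian(u) + k_eff(x) * u * (K - u),      K = 1,

on a rectangular grid, with k_eff = k_hat in growth-permitting territory and
k_eff = 0 inside obstacles (dispersal continues inside them, so obstacles act
as partially absorbing regions).  An unimpeded front travels at the pulled
speed v = 2*sqrt(D_eff*k_hat) with width parameter xi = sqrt(D_eff/k_hat).

Discretization follows the printed scheme: a nine-point Laplacian stencil on
a square lattice of spacing a_grid = 0.15*xi, periodic boundaries along x
(perpendicular to the front) and rows clamped to u = 1 well behind and u = 0
well ahead of the front.  Time integration is adaptive method-of-lines
(SciPy RK45, rtol = atol = 1e-6 by default); the contract is tolerance
insensitivity of the extracted fronts, not a specific stepper.

The front is the sub-cell interpolated u = u_thresh contour (default 0.05,
measured outside obstacles); front positions d use the unperturbed
lateral-edge columns, like the other engines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from skimage import measure

from .environments import Environment
from .eikonal import FrontCurve, IndentSeries, rasterize_blocked
from .errors import (
    AlignmentError,
    EmptyFrontError,
    IntegrationError,
    InvalidGeometryError,
    ParameterError,
)

__all__ = [
    "FkppParams",
    "DensityField",
    "nine_point_laplacian",
    "initial_condition",
    "integrate",
    "extract_front",
    "front_position",
    "estimate_growth_rate",
    "stokes_einstein_D",
    "comoving_profile_formula",
    "comoving_profile",
    "lag_vs_eikonal",
    "planar_front_speed",
]

_BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class FkppParams:
    """Physical and numerical parameters of the FKPP engine.

    D_eff in mm^2/h, k_hat in 1/h; carrying capacity is fixed at 1 after
    rescaling the density.  ``a_grid`` defaults to 0.15*xi and must resolve
    the front (a_grid <= 0.2*xi).  ``c = 2`` is the dimensionless pulled-front
    speed: v = 2*sqrt(D_eff*k_hat).
    """

    D_eff: float = 0.0144
    k_hat: float = 0.7
    u_thresh: float = 0.05
    a_grid: float | None = None
    rtol: float = 1e-6
    atol: float = 1e-6
    c: float = 2.0

    def __post_init__(self):
        if self.D_eff <= 0 or self.k_hat <= 0:
            raise ParameterError("D_eff and k_hat must be positive")
        if not (0 < self.u_thresh < 1):
            raise ParameterError("u_thresh must lie strictly between 0 and 1")
        if self.a_grid is None:
            object.__setattr__(self, "a_grid", 0.15 * self.xi)
        if self.a_grid > 0.2 * self.xi + 1e-12:
            raise ParameterError("a_grid must not exceed 0.2*xi")

    @property
    def xi(self) -> float:
        """Front width parameter sqrt(D_eff/k_hat) (mm)."""
        return math.sqrt(self.D_eff / self.k_hat)

    @property
    def v(self) -> float:
        """Pulled front speed 2*sqrt(D_eff*k_hat) (mm/h)."""
        return self.c * math.sqrt(self.D_eff * self.k_hat)


@dataclass
class DensityField:
    """Population density u on a rectangular grid with its growth-rate map.

    Cell centers at x = a/2 + j*a, y = a/2 + i*a for u[i, j]; ``kmap`` holds
    k_eff per cell (k_hat or 0), ``blocked`` the obstacle raster.
    """

    u: np.ndarray
    kmap: np.ndarray
    blocked: np.ndarray
    a: float
    t: float
    env: Environment
    params: FkppParams

    @property
    def x(self) -> np.ndarray:
        return self.a / 2.0 + self.a * np.arange(self.u.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.a / 2.0 + self.a * np.arange(self.u.shape[0])

    def save(self, path) -> None:
        np.savez_compressed(path, u=self.u, kmap=self.kmap, a=self.a, t=self.t)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def estimate_growth_rate(v: float, D_eff: float) -> float:
    """Effective growth rate from front speed: k_hat = v^2/(4*D_eff) (1/h)."""
    if v <= 0 or D_eff <= 0:
        raise ParameterError("v and D_eff must be positive")
    return v * v / (4.0 * D_eff)


def stokes_einstein_D(diameter_nm: float, viscosity_mPas: float, temperature_K: float) -> float:
    """Stokes-Einstein diffusion coefficient of a sphere, in mm^2/h.

    D = k_B*T / (3*pi*eta*d).  A 60 nm particle in water at 37 C
    (eta = 0.692 mPa s) gives ~0.04 mm^2/h.
    """
    if diameter_nm <= 0 or viscosity_mPas <= 0 or temperature_K <= 0:
        raise ParameterError("all Stokes-Einstein inputs must be positive")
    d_m = diameter_nm * 1e-9
    eta = viscosity_mPas * 1e-3  # Pa s
    D_m2_s = _BOLTZMANN_J_PER_K * temperature_K / (3.0 * math.pi * eta * d_m)
    return D_m2_s * 1e6 * 3600.0  # m^2/s -> mm^2/h


# ---------------------------------------------------------------------------
# spatial discretization
# ---------------------------------------------------------------------------

def nine_point_laplacian(u: np.ndarray, a_grid: float) -> np.ndarray:
    """Nine-point Laplacian on interior cells, exactly as discretized:

        lap u = [-20 u + (corner sum) + 4 (edge sum)] / (6 a^2).

    Returns an array of shape (ny-2, nx-2); the stencil is exact on
    quadratics.  Boundary handling (periodic/clamped ghosts) lives in the
    integrator.
    """
    u = np.asarray(u, dtype=float)
    if u.shape[0] < 3 or u.shape[1] < 3:
        raise ParameterError("grid must be at least 3x3 for the nine-point stencil")
    corners = u[:-2, :-2] + u[:-2, 2:] + u[2:, :-2] + u[2:, 2:]
    edges = u[:-2, 1:-1] + u[2:, 1:-1] + u[1:-1, :-2] + u[1:-1, 2:]
    return (-20.0 * u[1:-1, 1:-1] + corners + 4.0 * edges) / (6.0 * a_grid * a_grid)


def _make_kmap(env: Environment, params: FkppParams) -> tuple[np.ndarray, np.ndarray]:
    blocked = rasterize_blocked(env, params.a_grid)
    kmap = np.where(blocked, 0.0, params.k_hat)
    return kmap, blocked


def initial_condition(
    env: Environment,
    params: FkppParams,
    y0_front: float,
    ramp_width: float | None = None,
) -> DensityField:
    """Linear initial front: u = 1 behind y0_front, a linear ramp of width
    ``ramp_width`` (default 2*xi) down to 0, then 0 ahead.

    The ramp relaxes into the Fisher wave profile within a few growth times;
    obstacles closer than 10*xi to the founder line leave too little room for
    that relaxation and trigger a warning.
    """
    if ramp_width is None:
        ramp_width = 2.0 * params.xi
    kmap, blocked = _make_kmap(env, params)
    ny, nx = kmap.shape
    a = params.a_grid
    ys = a / 2.0 + a * np.arange(ny)
    for ob in env.obstacles:
        if ob.vertices[:, 1].min() - y0_front < 10.0 * params.xi:
            warnings.warn(
                "obstacle closer than 10*xi to the founder line; the Fisher "
                "profile may not be developed on contact",
                stacklevel=2,
            )
    ramp = np.clip((y0_front + ramp_width - ys) / ramp_width, 0.0, 1.0)
    u = np.broadcast_to(ramp[:, None], (ny, nx)).copy()
    return DensityField(u=u, kmap=kmap, blocked=blocked, a=a, t=0.0, env=env, params=params)


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------

@njit(cache=False)
def _rhs_kernel(u, kmap, D, inv6a2, out):
    """Fused nine-point Laplacian + logistic reaction; periodic in x,
    clamped (du/dt = 0) first and last rows."""
    ny, nx = u.shape
    for j in range(nx):
        out[0, j] = 0.0
        out[ny - 1, j] = 0.0
    for i in range(1, ny - 1):
        for j in range(nx):
            jm = j - 1 if j > 0 else nx - 1
            jp = j + 1 if j < nx - 1 else 0
            corners = u[i - 1, jm] + u[i - 1, jp] + u[i + 1, jm] + u[i + 1, jp]
            edges = u[i - 1, j] + u[i + 1, j] + u[i, jm] + u[i, jp]
            lap = (-20.0 * u[i, j] + corners + 4.0 * edges) * inv6a2
            out[i, j] = D * lap + kmap[i, j] * u[i, j] * (1.0 - u[i, j])


def _rhs_factory(kmap: np.ndarray, D: float, a: float):
    ny, nx = kmap.shape
    inv6a2 = 1.0 / (6.0 * a * a)
    kmap = np.ascontiguousarray(kmap)

    def rhs(t, uflat):
        out = np.empty((ny, nx))  # fresh: the solver keeps references
        _rhs_kernel(np.ascontiguousarray(uflat).reshape(ny, nx), kmap, D, inv6a2, out)
        return out.ravel()

    return rhs


def integrate(
    state: DensityField,
    params: FkppParams | None = None,
    t_end: float = None,
    t_eval: np.ndarray | None = None,
) -> list[DensityField]:
    """Method-of-lines integration of the FKPP equation up to t_end.

    Returns density snapshots at ``t_eval`` (default: t_end only).  Lateral
    boundaries are periodic; the first and last rows are Dirichlet rows held
    at their initial values (1 behind / 0 ahead for the standard setup), so
    obstacles must not overlap them.
    """
    params = params or state.params
    if t_end is None or t_end <= state.t:
        raise ParameterError("t_end must exceed the current time")
    a = state.a
    ny = state.u.shape[0]
    for ob in state.env.obstacles:
        ymin, ymax = ob.vertices[:, 1].min(), ob.vertices[:, 1].max()
        if ymin <= a or ymax >= (ny - 1) * a:
            raise InvalidGeometryError("obstacle overlaps a clamped boundary row")
    # first/last rows are Dirichlet: they keep their current values (1 behind
    # and 0 ahead for the standard initial condition)
    u0 = state.u.copy()
    rhs = _rhs_factory(state.kmap, params.D_eff, a)
    if t_eval is None:
        t_eval = np.array([t_end])
    sol = solve_ivp(
        rhs, (state.t, float(t_end)), u0.ravel(),
        method="RK45", rtol=params.rtol, atol=params.atol, t_eval=np.asarray(t_eval, dtype=float),
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    # accumulated solver noise leaves excursions of O(10*atol) at the wave
    # tail and the saturated state; instabilities grow to O(1), so a 100*atol
    # threshold separates the two cleanly
    bound_tol = max(1e-6, 100.0 * params.atol)
    out = []
    for k, tk in enumerate(sol.t):
        uk = sol.y[:, k].reshape(state.u.shape)
        if uk.min() < -bound_tol or uk.max() > 1.0 + bound_tol:
            raise IntegrationError(
                f"density bounds violated at t={tk:.4g}: "
                f"min={uk.min():.3g}, max={uk.max():.3g}"
            )
        out.append(replace(state, u=uk, t=float(tk)))
    return out


# ---------------------------------------------------------------------------
# front extraction and comparisons
# ---------------------------------------------------------------------------

def front_position(state: DensityField, u_thresh: float | None = None) -> float:
    """Unperturbed front y-position: the threshold crossing averaged over the
    two lateral-edge columns (far from any obstacle)."""
    u_thresh = u_thresh if u_thresh is not None else state.params.u_thresh
    ys = state.y
    pos = []
    for col in (state.u[:, 0], state.u[:, -1]):
        idx = np.nonzero(col >= u_thresh)[0]
        if len(idx) == 0 or idx.max() >= len(col) - 1:
            raise EmptyFrontError("threshold level absent from an edge column")
        i = idx.max()
        f = (col[i] - u_thresh) / (col[i] - col[i + 1])
        pos.append(ys[i] + f * state.a)
    return float(np.mean(pos))


def extract_front(state: DensityField, u_thresh: float | None = None) -> FrontCurve:
    """Sub-cell interpolated u = u_thresh contour, obstacle cells masked.

    The d label is the edge-column front position minus y_maxwidth of the
    (single) obstacle; obstacle-free fields are labeled from y = 0.
    """
    u_thresh = u_thresh if u_thresh is not None else state.params.u_thresh
    um = np.where(state.blocked, np.nan, state.u)
    contours = measure.find_contours(um, u_thresh)
    if not contours:
        raise EmptyFrontError(f"no u = {u_thresh} crossing found")
    a = state.a
    segs = []
    for c in contours:
        xy = np.column_stack([a / 2.0 + a * c[:, 1], a / 2.0 + a * c[:, 0]])
        if xy[0, 0] > xy[-1, 0]:
            xy = xy[::-1]
        segs.append(xy)
    segs.sort(key=lambda s: s[:, 0].mean())
    y_ref = state.env.obstacles[0].y_maxwidth if state.env.obstacles else 0.0
    d = front_position(state, u_thresh) - y_ref
    return FrontCurve(tuple(segs), d, "pde")


def lag_vs_eikonal(
    pde_series: IndentSeries,
    eikonal_series: IndentSeries,
    d_grid: np.ndarray,
) -> dict:
    """Per-d lag Delta_pde(d) - Delta_eikonal(d) on a common d grid.

    Both series must cover the requested d values (linear interpolation in
    between); both engines are assumed to share the obstacle geometry.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    for s in (pde_series, eikonal_series):
        if d_grid.min() < s.d.min() - 1e-9 or d_grid.max() > s.d.max() + 1e-9:
            raise AlignmentError(
                f"requested d range [{d_grid.min():.3g}, {d_grid.max():.3g}] not covered "
                f"by series spanning [{s.d.min():.3g}, {s.d.max():.3g}]"
            )
    dp = np.interp(d_grid, pde_series.d, pde_series.delta)
    de = np.interp(d_grid, eikonal_series.d, eikonal_series.delta)
    return {"d": d_grid, "lag": dp - de, "delta_pde": dp, "delta_eikonal": de}


def rhombus_indent_series(
    params: FkppParams,
    w_half: float = 1.2,
    h_half: float = 0.9,
    d_range: tuple[float, float] = (1.6, 2.6),
    n_snapshots: int = 10,
) -> IndentSeries:
    """Measured indent series Delta(d) for a single rhombus obstacle.

    Builds the standard geometry (lateral edges 5*w_half from the obstacle,
    founder line and clamped rows >= 10*xi away), integrates through the
    requested d window and measures (d, Delta) from each snapshot: d from the
    unperturbed edge columns, Delta from the windowed front minimum.
    """
    from .environments import Environment, make_rhombus
    from .frontstats import indent_from_front

    xi, v = params.xi, params.v
    Lx = 12.0 * w_half
    y0 = 3.0 * xi
    cy = y0 + 10.0 * xi + h_half + 0.25
    d_lo, d_hi = d_range
    Ly = cy + d_hi + 10.0 * xi + 0.4
    env = Environment(Lx, Ly, (make_rhombus(w_half, h_half, (Lx / 2.0, cy)),))
    state = initial_condition(env, params, y0_front=y0)
    t_lo = max((cy + d_lo - y0) / v - 2.0, 1.0)
    t_hi = (cy + d_hi - y0) / v + 2.0
    t_eval = np.linspace(t_lo, t_hi, n_snapshots)
    snaps = integrate(state, params, t_end=float(t_hi), t_eval=t_eval)
    ob = env.obstacles[0]
    ds, deltas = [], []
    for s in snaps:
        front = extract_front(s)
        ds.append(front.d)
        deltas.append(indent_from_front(front, ob))
    order = np.argsort(ds)
    return IndentSeries(
        np.asarray(ds)[order], np.asarray(deltas)[order],
        w_half, h_half, provenance="pde",
    )


# ---------------------------------------------------------------------------
# planar-front diagnostics
# ---------------------------------------------------------------------------

def _planar_run(params: FkppParams, t_eval: np.ndarray, Ly: float, nx: int = 4,
                y0_front: float | None = None) -> list[DensityField]:
    env = Environment(nx * params.a_grid, Ly)
    y0 = y0_front if y0_front is not None else 4.0 * params.xi
    state = initial_condition(env, params, y0_front=y0)
    return integrate(state, params, t_end=float(t_eval[-1]), t_eval=t_eval)


def planar_front_speed(
    params: FkppParams,
    t_window: tuple[float, float] | None = None,
    n_samples: int = 11,
) -> float:
    """Late-time speed of the u_thresh level for an obstacle-free planar front.

    Integrates a quasi-1D domain (periodic in x) and fits the front position
    over ``t_window`` (default [20/k, 40/k]) by least squares.  Converges to
    v = 2*sqrt(D*k) from below with the usual slow 1/t correction.
    """
    k = params.k_hat
    if t_window is None:
        t_window = (20.0 / k, 40.0 / k)
    t0, t1 = t_window
    y0 = 4.0 * params.xi
    Ly = y0 + params.v * t1 + 12.0 * params.xi
    t_eval = np.linspace(t0, t1, n_samples)
    snaps = _planar_run(params, t_eval, Ly, y0_front=y0)
    pos = np.array([front_position(s) for s in snaps])
    slope = np.polyfit(t_eval, pos, 1)[0]
    return float(slope)


def comoving_profile_formula(z: np.ndarray, c: float = 2.0) -> np.ndarray:
    """Approximate comoving FKPP wave profile u(z), z = y' * sqrt(k/D):

        u(z) = s + (1/4) e^{z/c} s^2 ln(4 e^{z/c} s^2),   s = (1 + e^{z/c})^{-1},

    with c = 2 the dimensionless pulled speed.  u(0) = 1/2 exactly.
    """
    z = np.asarray(z, dtype=float)
    e = np.exp(z / c)
    s = 1.0 / (1.0 + e)
    arg = 4.0 * e * s * s
    return s + 0.25 * e * s * s * np.log(arg)


def comoving_profile(
    params: FkppParams,
    t_relax: float | None = None,
    z_window: tuple[float, float] = (-8.0, 8.0),
    n_z: int = 400,
) -> dict:
    """Measured obstacle-free wave profile in comoving coordinates.

    Runs a quasi-1D front to ``t_relax`` (default 15/k), centers z on the
    u = 1/2 crossing and samples u(z) on ``z_window``; returns the samples
    together with the closed-form approximation and their sup-distance.
    """
    k = params.k_hat
    if t_relax is None:
        t_relax = 15.0 / k
    y0 = 4.0 * params.xi
    Ly = y0 + params.v * t_relax + 14.0 * params.xi
    snap = _planar_run(params, np.array([t_relax]), Ly, y0_front=y0)[-1]
    prof = snap.u[:, 0]
    ys = snap.y
    # center on the u = 1/2 crossing (the formula has u(0) = 1/2 exactly)
    idx = np.nonzero(prof >= 0.5)[0].max()
    f = (prof[idx] - 0.5) / (prof[idx] - prof[idx + 1])
    y_half = ys[idx] + f * snap.a
    z_meas = (ys - y_half) / params.xi
    z = np.linspace(*z_window, n_z)
    u_meas = np.interp(z, z_meas, prof)
    u_ref = comoving_profile_formula(z, params.c)
    return {
        "z": z,
        "u": u_meas,
        "u_formula": u_ref,
        "sup_distance": float(np.max(np.abs(u_meas - u_ref))),
    }
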