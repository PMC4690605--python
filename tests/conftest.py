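"""Shared fixtures.

Heavy artifacts (arrival fields, lattice runs, PDE indent series) are
session-scoped so the unit suite and the acceptance suite share them.
"""

import pytest

from rangefront import eden
from rangefront.environments import Environment, make_rhombus
from rangefront.eikonal import solve_arrival
from rangefront.fkpp import FkppParams, estimate_growth_rate, rhombus_indent_series

PRINTED_RHOMBI = [(0.9, 0.9), (0.9, 1.2), (1.2, 0.9), (1.2, 1.2)]
V_FRONT = 0.2  # mm/h, printed front speed
D_EFF = 0.0144  # mm^2/h
K_HAT = 0.7  # 1/h


def rhombus_environment(w_half: float, h_half: float, d_max_w: float = 10.0) -> Environment:
    """Single printed rhombus, lateral edges >= 5*w_half away, room for d up
    to ``d_max_w`` half-widths."""
    Lx = 12.0 * w_half
    cy = 2.0 + h_half
    Ly = cy + d_max_w * w_half + 1.0
    return Environment(Lx, Ly, (make_rhombus(w_half, h_half, (Lx / 2.0, cy)),))


@pytest.fixture(scope="session")
def rhombus_fields():
    """Arrival fields for the four printed rhombi at the default resolution."""
    out = {}
    for w, h in PRINTED_RHOMBI:
        env = rhombus_environment(w, h)
        out[(w, h)] = solve_arrival(env, v=V_FRONT, a_eik=w / 100.0, y0_front=0.0)
    return out


@pytest.fixture(scope="session")
def eden_two_obstacle_runs():
    """Ten printed-scale runs of the staggered two-disk configuration."""
    W, R = 600, 80.0
    cx, cy = 0.5 + W / 2.0, 1.0 + W / 3.0
    obstacles = ((cx, cy, R), (cx + 5.0 / 3.0 * R, cy + 5.0 / 2.0 * R, R))
    runs = []
    for seed in range(10):
        cfg = eden.EdenConfig(W=W, R=R, obstacles=obstacles, seed=seed)
        runs.append(eden.run(cfg))
    return runs, obstacles


@pytest.fixture(scope="session")
def eden_single_runs():
    """Ten printed-scale single-disk runs plus matched obstacle-free runs."""
    W, R = 600, 80.0
    with_obstacle, free = [], []
    for seed in range(10):
        cfg = eden.EdenConfig(W=W, R=R, seed=seed)
        with_obstacle.append(eden.run(cfg))
        cfg0 = eden.EdenConfig(
            W=W, R=R, obstacles=(), stop_row=cfg.resolved_stop_row(), seed=seed
        )
        free.append(eden.run(cfg0))
    return with_obstacle, free


@pytest.fixture(scope="session")
def fkpp_lag_series():
    """PDE indent series for the wide printed rhombus at D and D/3 (fixed v)."""
    base = FkppParams(D_eff=D_EFF, k_hat=K_HAT)
    small = FkppParams(D_eff=D_EFF / 3.0, k_hat=estimate_growth_rate(V_FRONT, D_EFF / 3.0))
    return {
        "base": rhombus_indent_series(base),
        "smallD": rhombus_indent_series(small),
    }


@pytest.fixture(scope="session")
def small_eden_run():
    """One modest run reused by unit-scale lattice tests."""
    cfg = eden.EdenConfig(W=120, R=16.0, seed=11)
    return eden.run(cfg, traj_every=64)
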