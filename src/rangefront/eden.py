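"""Stochastic Eden-type growth on a hexagonal lattice with genotype tracking.

Each lattice site holds at most one individual carrying an integer genotype.
At every event a *frontier* site (occupied, with at least one empty neighbour)
is chosen uniformly at random and copies its genotype into a uniformly chosen
empty neighbour; individuals never die.  Simulation time advances by an
exponential increment with mean 1/|frontier|, the frontier size being taken
before the event.  Obstacles are disks of blocked sites that can never be
occupied and are excluded from the frontier; the lateral boundary columns are
blocked as well (no periodic wrap-around).

Lattice geometry: "pointy-top" rows with odd rows offset by half a site and
unit row spacing, so the site density is one per unit area and a disk of
radius R rasterizes to ~pi*R^2 sites.  Row 0 and the outermost columns are
blocked sentinels; the founder row (row 1) starts fully occupied with unique
genotypes 0..W-1, one per interior column.

The full event history (parent pointers, birth times) is retained, so the
genealogy of any frontier — the lineage forest — can be reconstructed exactly,
and sector boundaries, pinned boundaries at obstacle tops, and lineage routes
around obstacles can be measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidGeometryError,
    NotApplicableError,
    NotReadyError,
    StallError,
)

__all__ = [
    "EdenConfig",
    "HexLattice",
    "EdenRun",
    "LineageForest",
    "init",
    "step",
    "run",
    "genealogy",
    "sector_boundaries",
    "detect_pinned_boundary",
    "classify_lineage_route",
    "frontier_sites",
    "frontier_genotypes",
    "replay_parents",
    "forest_to_newick",
]

EMPTY, OCCUPIED, BLOCKED = 0, 1, 2

_RAND_BLOCK = 1 << 14


@dataclass(frozen=True)
class EdenConfig:
    """Run configuration in lattice units.

    ``W`` interior columns (defaults to the printed ~600), obstacle radius
    ``R`` (~80), obstacle center one third of the system width ahead of the
    founder row and laterally centered.  ``obstacles`` may override placement
    as explicit (cx, cy, R) disks; ``obstacles=()`` runs obstacle-free.
    The run stops once every column's front has passed ``stop_row``
    (default: top of the highest obstacle + 3R, or 1.2*W obstacle-free).
    """

    W: int = 600
    R: float = 80.0
    obstacles: tuple | None = None  # tuple of (cx, cy, R); None -> single default disk
    stop_row: int | None = None
    seed: int = 0

    def resolved_obstacles(self) -> tuple:
        if self.obstacles is not None:
            return tuple(self.obstacles)
        return ((0.5 + self.W / 2.0, 1.0 + self.W / 3.0, float(self.R)),)

    def resolved_stop_row(self) -> int:
        if self.stop_row is not None:
            return int(self.stop_row)
        obs = self.resolved_obstacles()
        if obs:
            return int(math.ceil(max(cy + r for _, cy, r in obs) + 3.0 * max(r for _, _, r in obs)))
        return int(round(1.2 * self.W))


@dataclass
class HexLattice:
    """Per-site state of the simulator (flat arrays of shape n_rows*(W+2)).

    Sites index as ``row * stride + col`` with ``stride = W + 2``; interior
    columns are 1..W.  Site (row, col) sits at x = col + 0.5*(row % 2),
    y = row - 1 (founder row 1 is y = 0).
    """

    W: int
    n_rows: int
    state: np.ndarray  # uint8: EMPTY/OCCUPIED/BLOCKED
    genotype: np.ndarray  # int32, -1 if unset
    parent: np.ndarray  # int64 flat site index, -1 for founders
    btime: np.ndarray  # float64 birth time, -inf if unset
    bevent: np.ndarray  # int64 birth event index, -1 for founders
    obstacles: tuple = ()

    @property
    def stride(self) -> int:
        return self.W + 2

    def rc(self, idx: int) -> tuple[int, int]:
        return idx // self.stride, idx % self.stride

    def xy(self, idx) -> np.ndarray:
        idx = np.asarray(idx)
        row, col = idx // self.stride, idx % self.stride
        return np.stack([col + 0.5 * (row % 2), row - 1.0], axis=-1)

    def genotype_raster(self) -> np.ndarray:
        """(n_rows, W+2) genotype image, -1 on empty, -2 on blocked."""
        g = self.genotype.reshape(self.n_rows, self.stride).copy()
        s = self.state.reshape(self.n_rows, self.stride)
        g[s == BLOCKED] = -2
        return g


@dataclass
class EdenRun:
    """A completed (or stalled) run: final lattice plus the full event log."""

    lattice: HexLattice
    config: EdenConfig
    times: np.ndarray  # event times (len = n_events)
    children: np.ndarray  # child flat index per event
    parents: np.ndarray  # parent flat index per event
    n_founders: int
    frontier_trajectory: np.ndarray  # (sampled event index, frontier size)

    @property
    def n_events(self) -> int:
        return len(self.times)

    def log_dataframe(self):
        import pandas as pd

        g = self.lattice.genotype
        return pd.DataFrame(
            {
                "event": np.arange(self.n_events),
                "time": self.times,
                "parent_site": self.parents,
                "child_site": self.children,
                "genotype": g[self.children],
            }
        )


@dataclass
class LineageForest:
    """Ancestor paths of a frontier set, as child -> parent edges.

    ``tips`` are the frontier sites the forest was built from; ``roots`` lie
    in the founder row.  Birth times strictly decrease along child -> parent
    edges (parents are born earlier by construction).
    """

    edges: dict  # child flat index -> parent flat index
    tips: np.ndarray
    roots: np.ndarray
    btime: np.ndarray  # full lattice birth-time array (view)
    lattice: HexLattice

    @property
    def nodes(self) -> np.ndarray:
        return np.array(sorted(set(self.edges) | set(self.edges.values()) | set(self.tips.tolist())))


# ---------------------------------------------------------------------------
# neighbour topology
# ---------------------------------------------------------------------------

def _neighbor_offsets(stride: int) -> tuple[tuple, tuple]:
    """Flat-index offsets of the 6 neighbours, for even and odd rows.

    With odd rows shifted +1/2: an even-row site (r, c) touches columns
    (c-1, c) in rows r+-1; an odd-row site touches (c, c+1).
    """
    even = (-1, 1, -stride - 1, -stride, stride - 1, stride)
    odd = (-1, 1, -stride, -stride + 1, stride, stride + 1)
    return even, odd


def neighbors(lattice: HexLattice, idx: int) -> list[int]:
    even, odd = _neighbor_offsets(lattice.stride)
    offs = odd if (idx // lattice.stride) % 2 else even
    return [idx + o for o in offs]


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init(config: EdenConfig, n_rows: int | None = None) -> HexLattice:
    """Founder row of W unique genotypes plus blocked sentinels and obstacles.

    Row 0 and the outermost columns are blocked sentinels; obstacle disks
    (site blocked iff its center lies within radius R of the disk center)
    must not touch the founder row.
    """
    W = config.W
    if W < 2 or config.R < 0:
        raise InvalidGeometryError("W must be >= 2 and R non-negative")
    stop_row = config.resolved_stop_row()
    if n_rows is None:
        n_rows = stop_row + max(4, int(config.R // 2) + 2)
    stride = W + 2
    n = n_rows * stride
    state = np.zeros(n, dtype=np.uint8)
    genotype = np.full(n, -1, dtype=np.int32)
    parent = np.full(n, -1, dtype=np.int64)
    btime = np.full(n, -np.inf)
    bevent = np.full(n, -1, dtype=np.int64)

    s2 = state.reshape(n_rows, stride)
    s2[0, :] = BLOCKED
    s2[-1, :] = BLOCKED
    s2[:, 0] = BLOCKED
    s2[:, -1] = BLOCKED

    obstacles = config.resolved_obstacles()
    if obstacles:
        rows = np.arange(n_rows)
        cols = np.arange(stride)
        X = cols[None, :] + 0.5 * (rows[:, None] % 2)
        Y = np.broadcast_to(rows[:, None].astype(float), (n_rows, stride))
        for cx, cy, r in obstacles:
            mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r * r
            if mask[1, :].any():
                raise InvalidGeometryError("obstacle overlaps the founder row")
            if mask[:, 1].any() or mask[:, -2].any():
                raise InvalidGeometryError("obstacle touches the lateral boundary")
            s2[mask] = BLOCKED

    # founder row: unique genotypes 0..W-1 left to right
    founder = np.arange(stride * 1 + 1, stride * 1 + 1 + W)
    state[founder] = OCCUPIED
    genotype[founder] = np.arange(W, dtype=np.int32)
    btime[founder] = 0.0
    return HexLattice(
        W=W, n_rows=n_rows, state=state, genotype=genotype,
        parent=parent, btime=btime, bevent=bevent, obstacles=obstacles,
    )


# ---------------------------------------------------------------------------
# event loop
# ---------------------------------------------------------------------------

class _Frontier:
    """Uniform-sampling set with O(1) insert/remove (swap-pop + position map)."""

    def __init__(self, n_sites: int):
        self.items: list[int] = []
        self.pos = np.full(n_sites, -1, dtype=np.int64)

    def __len__(self):
        return len(self.items)

    def __contains__(self, idx):
        return self.pos[idx] >= 0

    def add(self, idx: int):
        if self.pos[idx] < 0:
            self.pos[idx] = len(self.items)
            self.items.append(idx)

    def remove(self, idx: int):
        p = self.pos[idx]
        if p < 0:
            return
        last = self.items[-1]
        self.items[p] = last
        self.pos[last] = p
        self.items.pop()
        self.pos[idx] = -1


def _build_frontier(lattice: HexLattice) -> _Frontier:
    f = _Frontier(lattice.state.size)
    occ = np.nonzero(lattice.state == OCCUPIED)[0]
    for idx in occ:
        for nb in neighbors(lattice, int(idx)):
            if lattice.state[nb] == EMPTY:
                f.add(int(idx))
                break
    return f


def step(lattice: HexLattice, frontier: _Frontier, rng: np.random.Generator, t: float):
    """One reproduction event; returns (child, parent, new_time) or None.

    Exposed for unit-scale work; ``run`` uses an equivalent inlined loop.
    """
    if len(frontier) == 0:
        return None
    even, odd = _neighbor_offsets(lattice.stride)
    state = lattice.state
    k = frontier.items[int(rng.integers(len(frontier)))]
    offs = odd if (k // lattice.stride) % 2 else even
    empties = [k + o for o in offs if state[k + o] == EMPTY]
    child = empties[int(rng.integers(len(empties)))]
    t_new = t + rng.exponential(1.0 / len(frontier))
    _occupy(lattice, frontier, child, k, t_new, even, odd)
    return child, k, t_new


def _occupy(lattice, frontier, child, parent, t_new, even, odd):
    state = lattice.state
    state[child] = OCCUPIED
    lattice.genotype[child] = lattice.genotype[parent]
    lattice.parent[child] = parent
    lattice.btime[child] = t_new
    offs_c = odd if (child // lattice.stride) % 2 else even
    child_has_empty = False
    for o in offs_c:
        nb = child + o
        st = state[nb]
        if st == EMPTY:
            child_has_empty = True
        elif st == OCCUPIED and frontier.pos[nb] >= 0:
            # nb lost an empty neighbour (child); recheck its frontier status
            offs_n = odd if (nb // lattice.stride) % 2 else even
            still = False
            for o2 in offs_n:
                if state[nb + o2] == EMPTY:
                    still = True
                    break
            if not still:
                frontier.remove(nb)
    if child_has_empty:
        frontier.add(child)


def run(config: EdenConfig, seed: int | None = None, traj_every: int = 2048) -> EdenRun:
    """Repeat events until every column's front passes the stop row.

    Identical seeds give identical runs.  Raises StallError if the frontier
    empties before the stop condition is met (blocked channel).
    """
    seed = config.seed if seed is None else seed
    lattice = init(config)
    stride = lattice.stride
    state = lattice.state
    stop_row = config.resolved_stop_row()
    if stop_row >= lattice.n_rows - 1:
        raise InvalidGeometryError("stop row beyond allocated lattice depth")
    frontier = _build_frontier(lattice)
    even, odd = _neighbor_offsets(stride)
    rng = np.random.default_rng(seed)

    # per-column front height bookkeeping for the stop condition
    colmax = np.zeros(stride, dtype=np.int64)
    colmax[0] = colmax[-1] = stop_row  # sentinels never count
    colmax[1:-1] = 1
    n_pending = int(np.sum(colmax < stop_row))

    times: list[float] = []
    children: list[int] = []
    parents: list[int] = []
    traj: list[tuple[int, int]] = []
    t = 0.0
    n_founders = int(np.sum(state == OCCUPIED))
    u_buf = np.empty(0)
    e_buf = np.empty(0)
    bi = 0
    event = 0
    max_events = int(lattice.n_rows * stride * 1.1) + 10_000
    while n_pending > 0:
        if len(frontier) == 0:
            raise StallError(
                f"frontier empty after {event} events with {n_pending} columns "
                "short of the stop row (blocked channel?)"
            )
        if bi == 0:
            u_buf = rng.random(2 * _RAND_BLOCK)
            e_buf = rng.standard_exponential(_RAND_BLOCK)
            bi = _RAND_BLOCK
        if event >= max_events:
            raise StallError(f"stop condition unreachable within {max_events} events")
        nf = len(frontier)
        k = frontier.items[int(u_buf[2 * bi - 2] * nf)]
        offs = odd if (k // stride) % 2 else even
        empties = [k + o for o in offs if state[k + o] == EMPTY]
        child = empties[int(u_buf[2 * bi - 1] * len(empties))]
        t += e_buf[bi - 1] / nf
        bi -= 1
        _occupy(lattice, frontier, child, k, t, even, odd)
        lattice.bevent[child] = event
        row, col = child // stride, child % stride
        if row > colmax[col]:
            if row >= stop_row > colmax[col]:
                n_pending -= 1
            colmax[col] = row
        times.append(t)
        children.append(child)
        parents.append(k)
        if event % traj_every == 0:
            traj.append((event, nf))
        event += 1

    return EdenRun(
        lattice=lattice,
        config=config,
        times=np.asarray(times),
        children=np.asarray(children, dtype=np.int64),
        parents=np.asarray(parents, dtype=np.int64),
        n_founders=n_founders,
        frontier_trajectory=np.asarray(traj, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# frontier and genealogy
# ---------------------------------------------------------------------------

def frontier_sites(lattice: HexLattice, at_time: float | None = None) -> np.ndarray:
    """Occupied sites with at least one empty neighbour, now or at ``at_time``.

    For a past time the occupancy is reconstructed from birth times (sites
    never vacate, so occupancy at t is simply btime <= t).
    """
    if at_time is not None and at_time < 0:
        raise NotReadyError("requested time precedes the founder row (t = 0)")
    state = lattice.state
    if at_time is None:
        occ = state == OCCUPIED
        emp = state == EMPTY
    else:
        occ = (state == OCCUPIED) & (lattice.btime <= at_time)
        emp = (state != BLOCKED) & ~occ
    occ2 = occ.reshape(lattice.n_rows, lattice.stride)
    emp2 = emp.reshape(lattice.n_rows, lattice.stride)
    has_empty = np.zeros_like(occ2)
    # same-row neighbours
    has_empty[:, 1:] |= emp2[:, :-1]
    has_empty[:, :-1] |= emp2[:, 1:]
    evenrow = (np.arange(lattice.n_rows) % 2) == 0
    for drow in (-1, 1):
        shifted = np.zeros_like(emp2)
        if drow == -1:
            shifted[1:, :] = emp2[:-1, :]
        else:
            shifted[:-1, :] = emp2[1:, :]
        # even rows touch columns (c-1, c) above/below; odd rows (c, c+1)
        has_empty[evenrow] |= shifted[evenrow]
        has_empty[evenrow, 1:] |= shifted[evenrow][:, :-1]
        has_empty[~evenrow] |= shifted[~evenrow]
        has_empty[~evenrow, :-1] |= shifted[~evenrow][:, 1:]
    return np.nonzero((occ2 & has_empty).ravel())[0]


def frontier_genotypes(lattice: HexLattice, at_time: float | None = None) -> np.ndarray:
    return np.unique(lattice.genotype[frontier_sites(lattice, at_time)])


def genealogy(run_or_lattice, frontier_at: float | str = "final") -> LineageForest:
    """Lineage forest: union of ancestor paths of the chosen frontier.

    ``frontier_at`` is a simulation time or "final".  Edges follow stored
    parent pointers back to the founder row.
    """
    lattice = run_or_lattice.lattice if isinstance(run_or_lattice, EdenRun) else run_or_lattice
    at = None if frontier_at == "final" else float(frontier_at)
    tips = frontier_sites(lattice, at)
    edges: dict[int, int] = {}
    roots = set()
    for tip in tips:
        node = int(tip)
        while node not in edges:
            par = int(lattice.parent[node])
            if par < 0:
                roots.add(node)
                break
            edges[node] = par
            node = par
    return LineageForest(
        edges=edges, tips=tips, roots=np.array(sorted(roots)),
        btime=lattice.btime, lattice=lattice,
    )


def replay_parents(run: EdenRun) -> np.ndarray:
    """Parent pointers reconstructed from the event log alone (oracle)."""
    parent = np.full(run.lattice.state.size, -1, dtype=np.int64)
    for child, par in zip(run.children, run.parents):
        parent[child] = par
    return parent


def ancestry_path(lattice: HexLattice, tip: int) -> np.ndarray:
    """Flat site indices from ``tip`` back to its founder-row root."""
    nodes = [int(tip)]
    while lattice.parent[nodes[-1]] >= 0:
        nodes.append(int(lattice.parent[nodes[-1]]))
    return np.asarray(nodes)


def forest_to_newick(forest: LineageForest) -> str:
    """One Newick tree per root (semicolon separated), branch lengths =
    birth-time differences.  Iterative writer: lineage paths can be thousands
    of nodes deep."""
    children: dict[int, list[int]] = {}
    for c, p in forest.edges.items():
        children.setdefault(p, []).append(c)
    bt = forest.btime
    trees = []
    for root in forest.roots:
        out: list[str] = []
        # explicit stack of (node, child cursor)
        stack = [(int(root), 0)]
        while stack:
            node, cursor = stack[-1]
            kids = sorted(children.get(node, []))
            if cursor == 0 and kids:
                out.append("(")
            if cursor < len(kids):
                if cursor > 0:
                    out.append(",")
                stack[-1] = (node, cursor + 1)
                stack.append((kids[cursor], 0))
                continue
            if kids:
                out.append(")")
            par = forest.edges.get(node)
            t0 = bt[par] if par is not None else 0.0
            bl = bt[node] - t0 if np.isfinite(bt[node]) else 0.0
            out.append(f"s{node}:{bl:.9g}")
            stack.pop()
        trees.append("".join(out) + ";")
    return "\n".join(trees)


# ---------------------------------------------------------------------------
# sector statistics
# ---------------------------------------------------------------------------

def sector_boundaries(lattice: HexLattice, row_range: tuple[int, int] | None = None) -> list:
    """Adjacent occupied site pairs with different genotypes, grouped into
    boundary paths (connected components of nearby boundary segments)."""
    r0, r1 = row_range if row_range is not None else (0, lattice.n_rows)
    stride = lattice.stride
    s = lattice.state.reshape(lattice.n_rows, stride)
    g = lattice.genotype.reshape(lattice.n_rows, stride)
    pairs = []
    rows = np.arange(max(0, r0), min(lattice.n_rows, r1))
    for r in rows:
        occ = s[r] == OCCUPIED
        m = occ[:-1] & occ[1:] & (g[r, :-1] != g[r, 1:])
        for c in np.nonzero(m)[0]:
            pairs.append((r * stride + c, r * stride + c + 1))
        if r + 1 < lattice.n_rows:
            occ_up = s[r + 1] == OCCUPIED
            dcols = (0, -1) if r % 2 == 0 else (0, 1)
            for dc in dcols:
                lo = max(0, -dc)
                hi = stride - max(0, dc)
                m = (
                    occ[lo:hi]
                    & occ_up[lo + dc:hi + dc]
                    & (g[r, lo:hi] != g[r + 1, lo + dc:hi + dc])
                )
                for c in np.nonzero(m)[0] + lo:
                    pairs.append((r * stride + c, (r + 1) * stride + c + dc))
    if not pairs:
        return []
    # group segments whose midpoints are within 1.5 lattice units
    mids = np.array([(lattice.xy(a) + lattice.xy(b)) / 2.0 for a, b in pairs])
    from scipy.spatial import cKDTree

    tree = cKDTree(mids)
    neigh = tree.query_pairs(1.5, output_type="ndarray")
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    n = len(pairs)
    adj = sp.coo_matrix(
        (np.ones(len(neigh)), (neigh[:, 0], neigh[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list] = {}
    for lab, pair in zip(labels, pairs):
        groups.setdefault(int(lab), []).append(pair)
    return list(groups.values())


def _trace_side_at_row(lattice: HexLattice, site: int, row: float, cx: float) -> int:
    """Side (-1 left, +1 right) of the ancestry of ``site`` at lattice row ``row``."""
    path = ancestry_path(lattice, site)
    xy = lattice.xy(path)
    yr = row - 1.0  # row index -> y
    below = xy[:, 1] <= yr
    if not below.any():
        return 0
    i = int(np.argmax(below))  # first ancestor at or below the row (path runs tip->root)
    x = xy[i, 0]
    return -1 if x < cx else 1


def detect_pinned_boundary(
    lattice: HexLattice,
    obstacle: tuple[float, float, float] | None = None,
    window_frac: float = 1.0 / 8.0,
) -> tuple[bool, tuple | None]:
    """Is a sector boundary pinned at the obstacle's top?

    Searches the first R/4 rows beyond the obstacle top, within a lateral
    window +-window_frac*R of its vertical axis, for an adjacent pair of
    different genotypes whose ancestries pass the obstacle's max-width row on
    opposite lateral sides.  Returns (found, (site_a, site_b) or None).
    """
    if obstacle is None:
        if not lattice.obstacles:
            raise NotApplicableError("no obstacle present; pinning is undefined")
        obstacle = max(lattice.obstacles, key=lambda o: o[1] + o[2])
    cx, cy, R = obstacle
    top = cy + R
    span = max(2, int(round(R / 4.0)))
    r0 = int(math.floor(top)) + 1
    s = lattice.state.reshape(lattice.n_rows, lattice.stride)
    # front must have passed the top by >= R/4 rows across the window
    probe_row = min(lattice.n_rows - 2, r0 + span)
    cols = np.arange(1, lattice.stride - 1)
    in_window = np.abs(cols + 0.25 - cx) <= window_frac * R + 0.75
    if not (s[probe_row, cols[in_window]] == OCCUPIED).any():
        raise NotReadyError("front has not passed the obstacle top by R/4 rows yet")
    g = lattice.genotype.reshape(lattice.n_rows, lattice.stride)
    for r in range(r0, min(r0 + span, lattice.n_rows - 1)):
        xrow = cols + 0.5 * (r % 2)
        win = np.abs(xrow - cx) <= window_frac * R
        for c in cols[win]:
            a = r * lattice.stride + c
            if lattice.state[a] != OCCUPIED:
                continue
            for b in neighbors(lattice, a):
                if lattice.state[b] != OCCUPIED or lattice.genotype[b] == g.ravel()[a]:
                    continue
                sa = _trace_side_at_row(lattice, a, cy, cx)
                sb = _trace_side_at_row(lattice, b, cy, cx)
                if sa * sb == -1:
                    return True, (a, int(b))
    return False, None


def classify_lineage_route(forest: LineageForest, obstacles: tuple | None = None) -> dict:
    """Per-tip route labels around each obstacle.

    For every root-to-tip path and every obstacle (cx, cy, R) the label is
    'left' or 'right' from the path's lateral position where it crosses the
    obstacle's max-width row, prefixed with 'graze-' if the path comes within
    2 lattice units of the obstacle boundary.  Obstacle-free runs yield empty
    label lists.
    """
    lattice = forest.lattice
    obstacles = obstacles if obstacles is not None else lattice.obstacles
    out: dict[int, list[str]] = {}
    for tip in forest.tips:
        path = ancestry_path(lattice, int(tip))
        xy = lattice.xy(path)
        labels = []
        for cx, cy, R in obstacles:
            side = _trace_side_at_row(lattice, int(tip), cy, cx)
            band = np.abs(xy[:, 1] - (cy - 1.0)) <= R
            graze = False
            if band.any():
                dist = np.hypot(xy[band, 0] - cx, xy[band, 1] - (cy - 1.0)) - R
                if dist.min() < -1e-9:
                    raise RuntimeError("lineage path enters an obstacle (internal inconsistency)")
                graze = bool(dist.min() <= 2.0)
            name = "left" if side < 0 else "right"
            labels.append(f"graze-{name}" if graze else name)
        out[int(tip)] = labels
    return out
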