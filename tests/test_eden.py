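"""Stochastic lattice engine: event rules, clocks, genealogy, sectors."""

import math

import numpy as np
import pytest

from rangefront import eden
from rangefront.errors import InvalidGeometryError, NotApplicableError


class TestInit:
    def test_founder_row_unique_genotypes(self):
        lat = eden.init(eden.EdenConfig(W=600, R=80.0))
        g = lat.genotype.reshape(lat.n_rows, lat.stride)
        founders = g[1, 1:-1]
        assert len(np.unique(founders)) == 600
        np.testing.assert_array_equal(founders, np.arange(600))

    def test_disk_raster_count_close_to_pi_r_squared(self):
        lat = eden.init(eden.EdenConfig(W=600, R=80.0))
        s = lat.state.reshape(lat.n_rows, lat.stride)
        n_blocked = int(np.sum(s == eden.BLOCKED))
        n_frame = 2 * lat.stride + 2 * (lat.n_rows - 2)
        n_disk = n_blocked - n_frame
        assert n_disk == pytest.approx(math.pi * 80 ** 2, rel=0.02)

    def test_reinit_identical(self):
        a = eden.init(eden.EdenConfig(W=60, R=8.0, seed=5))
        b = eden.init(eden.EdenConfig(W=60, R=8.0, seed=5))
        np.testing.assert_array_equal(a.state, b.state)
        np.testing.assert_array_equal(a.genotype, b.genotype)

    def test_obstacle_on_founder_row_rejected(self):
        with pytest.raises(InvalidGeometryError):
            eden.init(eden.EdenConfig(W=60, R=8.0, obstacles=((30.0, 2.0, 8.0),)))


class TestStep:
    def test_two_empty_neighbors_filled_equally_often(self):
        """A lone frontier site with exactly two empty neighbours converts
        each first with probability 1/2 (exact enumeration over the uniform
        choice, checked against the empirical split)."""
        first_child = []
        for seed in range(400):
            lat = eden.init(eden.EdenConfig(W=3, R=0.0, obstacles=(), stop_row=2))
            # keep only the middle founder: block the side founders
            s = lat.state
            mid = lat.stride + 2
            for idx in (lat.stride + 1, lat.stride + 3):
                s[idx] = eden.BLOCKED
            # the middle site (even row 1... row 1 is odd) has up-neighbours
            frontier = eden._build_frontier(lat)
            rng = np.random.default_rng(seed)
            child, parent, _ = eden.step(lat, frontier, rng, 0.0)
            assert parent == mid
            first_child.append(child)
        counts = np.unique(first_child, return_counts=True)[1]
        assert len(counts) == 2
        # binomial(400, 1/2): 5 sigma band
        assert abs(counts[0] - 200) < 5 * math.sqrt(400 * 0.25)

    def test_occupied_count_increases_by_one_per_event(self, small_eden_run):
        res = small_eden_run
        assert int(np.sum(res.lattice.state == eden.OCCUPIED)) == res.n_founders + res.n_events

    def test_time_strictly_increasing(self, small_eden_run):
        assert np.all(np.diff(small_eden_run.times) > 0)


class TestRun:
    def test_identical_seed_identical_output(self):
        cfg = eden.EdenConfig(W=80, R=10.0, seed=4)
        a, b = eden.run(cfg), eden.run(cfg)
        np.testing.assert_array_equal(a.children, b.children)
        np.testing.assert_allclose(a.times, b.times)
        np.testing.assert_array_equal(a.lattice.genotype, b.lattice.genotype)

    def test_no_occupied_site_inside_obstacle(self, small_eden_run):
        lat = small_eden_run.lattice
        (cx, cy, r), = lat.obstacles
        xy = lat.xy(np.nonzero(lat.state == eden.OCCUPIED)[0])
        inside = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - (cy - 1.0)) ** 2 <= r * r
        assert not inside.any()

    def test_front_advance_rate_roughly_constant(self):
        """Obstacle-free growth: events per unit time scale with the frontier,
        so front height advances steadily after a transient."""
        cfg = eden.EdenConfig(W=100, R=0.0, obstacles=(), stop_row=160, seed=2)
        res = eden.run(cfg)
        t_half = res.times[len(res.times) // 2]
        # mean front height at half time vs end, from birth times
        bt = res.lattice.btime.reshape(res.lattice.n_rows, -1)[:, 1:-1]
        height = lambda t: np.mean(
            np.max(np.where((bt >= 0) & (bt <= t), np.arange(bt.shape[0])[:, None], 0), axis=0)
        )
        h1, h2 = height(t_half), height(res.times[-1])
        rate1 = h1 / t_half
        rate2 = (h2 - h1) / (res.times[-1] - t_half)
        assert rate2 == pytest.approx(rate1, rel=0.25)

    def test_exponential_clock_mean(self, small_eden_run):
        """Increment i is Exp(1/|frontier_i|): the normalized increments
        dt_i * |frontier_i| are Exp(1) with mean 1."""
        res = small_eden_run
        # frontier sizes recorded at sampled event indices (before the event)
        ev, nf = res.frontier_trajectory.T
        dts = np.diff(res.times)  # dts[i-1] is the increment of event i
        mask = ev > 0
        z = dts[ev[mask] - 1] * nf[mask]
        assert len(z) > 100
        # mean of Exp(1) within 3 standard errors
        assert abs(z.mean() - 1.0) < 3.0 / math.sqrt(len(z))

    def test_stall_on_blocked_channel(self):
        # the middle columns are blocked all the way up: their front can
        # never reach the stop row, so the run stalls once the rest fills
        from rangefront.errors import StallError

        obstacles = tuple((15.5, float(y), 1.4) for y in range(4, 30, 2))
        cfg = eden.EdenConfig(W=29, R=1.4, obstacles=obstacles, stop_row=20, seed=0)
        with pytest.raises(StallError):
            eden.run(cfg)


class TestGenealogy:
    def test_forest_matches_event_log_replay_exactly(self):
        """Brute-force oracle: rebuild every parent pointer from the event
        log and compare with the incremental genealogy on a small lattice."""
        cfg = eden.EdenConfig(W=18, R=0.0, obstacles=(), stop_row=18, seed=9)
        res = eden.run(cfg)
        replayed = eden.replay_parents(res)
        forest = eden.genealogy(res)
        for child, parent in forest.edges.items():
            assert replayed[child] == parent
        # and conversely every logged event is consistent with stored pointers
        np.testing.assert_array_equal(
            res.lattice.parent[res.children], res.parents
        )

    def test_all_roots_in_founder_row(self, small_eden_run):
        forest = eden.genealogy(small_eden_run)
        rows = forest.roots // small_eden_run.lattice.stride
        assert np.all(rows == 1)

    def test_birth_times_decrease_toward_roots(self, small_eden_run):
        forest = eden.genealogy(small_eden_run)
        bt = small_eden_run.lattice.btime
        for child, parent in forest.edges.items():
            assert bt[child] > bt[parent]

    def test_initial_frontier_has_no_edges(self):
        lat = eden.init(eden.EdenConfig(W=40, R=5.0))
        forest = eden.genealogy(lat)
        assert forest.edges == {}
        assert len(forest.tips) == 40

    def test_newick_export_parses(self, small_eden_run):
        forest = eden.genealogy(small_eden_run)
        text = eden.forest_to_newick(forest)
        trees = [t for t in text.splitlines() if t.strip()]
        assert all(t.endswith(";") for t in trees)
        assert len(trees) == len(forest.roots)
        # depths balance: every '(' closes
        assert text.count("(") == text.count(")")


class TestSectors:
    def test_initial_row_has_all_boundaries(self):
        lat = eden.init(eden.EdenConfig(W=50, R=6.0))
        groups = eden.sector_boundaries(lat, (1, 2))
        n_pairs = sum(len(g) for g in groups)
        assert n_pairs == 49

    def test_monoclonal_region_has_none(self):
        lat = eden.init(eden.EdenConfig(W=50, R=6.0))
        lat.genotype[lat.state == eden.OCCUPIED] = 7
        assert eden.sector_boundaries(lat, (1, 2)) == []

    def test_frontier_genotype_count_non_increasing(self, small_eden_run):
        res = small_eden_run
        ts = np.quantile(res.times, [0.25, 0.5, 0.75, 1.0])
        counts = [len(eden.frontier_genotypes(res.lattice, t)) for t in ts]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestPinnedBoundary:
    def test_no_obstacle_not_applicable(self):
        cfg = eden.EdenConfig(W=40, R=0.0, obstacles=(), stop_row=30, seed=1)
        res = eden.run(cfg)
        with pytest.raises(NotApplicableError):
            eden.detect_pinned_boundary(res.lattice)

    def test_two_genotype_split_pins_at_top(self):
        """Left-half vs right-half founder genotypes around a symmetric
        obstacle must meet above it: the boundary can only pass there."""
        res_found = 0
        for seed in (21, 22, 23):
            cfg = eden.EdenConfig(W=120, R=16.0, seed=seed)
            lat = eden.init(cfg)
            g = lat.genotype
            occ = lat.state == eden.OCCUPIED
            half = lat.stride // 2
            cols = np.arange(lat.state.size) % lat.stride
            g[occ & (cols < half)] = 0
            g[occ & (cols >= half)] = 1
            frontier = eden._build_frontier(lat)
            rng = np.random.default_rng(seed)
            t = 0.0
            while True:
                out = eden.step(lat, frontier, rng, t)
                if out is None:
                    break
                t = out[2]
            found, _ = eden.detect_pinned_boundary(
                lat, lat.obstacles[0], window_frac=0.5
            )
            res_found += found
        assert res_found >= 2


class TestLineageRoutes:
    def test_obstacle_free_routes_empty(self):
        cfg = eden.EdenConfig(W=40, R=0.0, obstacles=(), stop_row=30, seed=3)
        res = eden.run(cfg)
        routes = eden.classify_lineage_route(eden.genealogy(res), ())
        assert all(v == [] for v in routes.values())

    def test_single_obstacle_both_sides_occur(self, small_eden_run):
        routes = eden.classify_lineage_route(eden.genealogy(small_eden_run))
        sides = {lab[0].replace("graze-", "") for lab in routes.values() if lab}
        assert sides == {"left", "right"}
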