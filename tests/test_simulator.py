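"""Agent dynamics: initialization, smoothing, stepping, full trajectories."""

import math

import numpy as np
import pytest

import lostperson as lp
from lostperson.behavior import HEADING_VECTORS, make_pmf
from lostperson.simulator import (
    SimConfig,
    child_seed,
    init_agent,
    mph_to_ms,
    simulate,
    simulate_replicates,
    smooth_update,
    step,
    steps_per_hour,
)

ONE_HOT = {
    name: make_pmf([1.0 if s == name else 0.0 for s in lp.STRATEGIES])
    for name in lp.STRATEGIES
}


class TestTimeCalibration:
    def test_paper_scale_steps_per_hour(self):
        assert steps_per_hour(1.575, 20000.0 / 3000.0) == 850

    def test_average_walking_speed_conversion(self):
        assert round(mph_to_ms(3.5), 2) == 1.56

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(alpha=0.0)
        with pytest.raises(ValueError):
            SimConfig(hours=-1)
        assert SimConfig(hours=100, steps_per_hour=850).n_steps == 85_000


class TestSmoothUpdate:
    def test_forward_step_example(self):
        assert smooth_update((10, 10), (9, 10), (11, 10), 0.55) == (11.0, 10.0)

    def test_momentum_drift_under_staying_put(self):
        x, y = smooth_update((11, 10), (10, 10), (11, 10), 0.55)
        assert (round(x, 10), y) == (11.45, 10.0)

    def test_alpha_one_returns_proposal(self):
        assert smooth_update((4, 7), (3, 6), (5, 8), 1.0) == (5.0, 8.0)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            smooth_update((0, 0), (0, 0), (0, 0), 0.0)


class TestInitAgent:
    def test_second_position_uniform_over_neighbors(self, flat_grid):
        from scipy import stats

        counts = {}
        for s in range(4000):
            st = init_agent((100, 100), flat_grid, np.random.default_rng(s))
            counts[st.cell] = counts.get(st.cell, 0) + 1
        assert len(counts) == 8
        assert stats.chisquare(list(counts.values())).pvalue > 0.01

    def test_inaccessible_neighbors_excluded(self, flat_grid):
        flat_grid.inaccessible[99, 99:102] = True  # 3 of the 8 neighbors
        seen = set()
        for s in range(500):
            st = init_agent((100, 100), flat_grid, np.random.default_rng(s))
            seen.add(st.cell)
        assert len(seen) == 5
        assert all(not flat_grid.inaccessible[c[1], c[0]] for c in seen)

    def test_fixed_seed_reproducible(self, flat_grid):
        a = init_agent((100, 100), flat_grid, np.random.default_rng(3))
        b = init_agent((100, 100), flat_grid, np.random.default_rng(3))
        assert a.cell == b.cell and a.heading == b.heading

    def test_heading_matches_initial_velocity(self, flat_grid):
        st = init_agent((100, 100), flat_grid, np.random.default_rng(1))
        v = (st.cell[0] - 100, st.cell[1] - 100)
        assert HEADING_VECTORS[st.heading] == v

    def test_bad_ipp_rejected(self, flat_grid):
        with pytest.raises(ValueError, match="outside"):
            init_agent((-1, 5), flat_grid, np.random.default_rng(0))
        flat_grid.inaccessible[50, 50] = True
        with pytest.raises(ValueError, match="inaccessible"):
            init_agent((50, 50), flat_grid, np.random.default_rng(0))


class TestStep:
    def test_blocked_move_stays_put(self, lake_grid):
        # agent just west of the lake, driven straight at it
        cfg = SimConfig(hours=1, steps_per_hour=10, replicates=1, seed=0)
        rng = np.random.default_rng(0)
        st = init_agent((38, 30), lake_grid, rng)
        st.x, st.y = 39.0, 30.0
        st.px, st.py = 38.0, 30.0
        st.cell = (39, 30)
        st.heading = 0  # east, into the lake
        before = (st.x, st.y, st.cell)
        step(st, ONE_HOT["DT"], lake_grid, cfg, rng)
        assert (st.x, st.y, st.cell) == before
        assert st.position_history[-1] == before[2]
        assert st.behavior_history[-1] == lp.DT

    def test_direction_traveling_reaches_unit_speed(self, flat_grid):
        cfg = SimConfig(hours=1, steps_per_hour=60, replicates=1, seed=0)
        rng = np.random.default_rng(4)
        st = init_agent((100, 100), flat_grid, rng)
        d = HEADING_VECTORS[st.heading]
        for _ in range(60):
            step(st, ONE_HOT["DT"], flat_grid, cfg, rng)
        # after burn-in the displacement per step converges to one cell
        # along the initial heading (fixed point of the smoothing update)
        cells = st.position_history
        diffs = {
            (cells[t + 1][0] - cells[t][0], cells[t + 1][1] - cells[t][1])
            for t in range(30, len(cells) - 1)
        }
        assert diffs == {d}

    def test_same_seed_same_state(self, flat_grid):
        cfg = SimConfig(hours=1, steps_per_hour=50, replicates=1, seed=0)
        pmf = make_pmf([0.3, 0.1, 0.2, 0.2, 0.1, 0.1])
        states = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            st = init_agent((100, 100), flat_grid, rng)
            for _ in range(50):
                step(st, pmf, flat_grid, cfg, rng)
            states.append((st.x, st.y, st.cell, st.heading, tuple(st.position_history)))
        assert states[0] == states[1]


class TestSimulate:
    def test_trajectory_length_is_steps_plus_one(self, flat_grid):
        cfg = SimConfig(hours=2, steps_per_hour=100, replicates=1, seed=0)
        traj = simulate((100, 100), ONE_HOT["RW"], flat_grid, cfg)
        assert len(traj) == cfg.n_steps + 1 == 201

    def test_matches_reference_step_loop(self, lake_grid):
        """The inlined fast loop reproduces step() draw for draw."""
        pmf = make_pmf([0.2, 0.2, 0.2, 0.1, 0.1, 0.2])
        cfg = SimConfig(hours=1, steps_per_hour=400, replicates=1, seed=0)
        traj = simulate((30, 30), pmf, lake_grid, cfg, seed=123)
        rng = np.random.default_rng(123)
        st = init_agent((30, 30), lake_grid, rng)
        for _ in range(cfg.n_steps - 1):
            step(st, pmf, lake_grid, cfg, rng)
        assert np.array_equal(traj.cells, np.asarray(st.position_history))
        assert [b for b in traj.behaviors[2:]] == st.behavior_history[2:]

    def test_staying_put_remains_near_ipp(self, flat_grid):
        cfg = SimConfig(hours=1, steps_per_hour=850, replicates=1, seed=0)
        traj = simulate((100, 100), ONE_HOT["SP"], flat_grid, cfg, seed=5)
        cheb = np.abs(traj.cells - np.array([100, 100])).max()
        assert cheb <= 3

    def test_seed_determinism(self, flat_grid):
        pmf = make_pmf([0.3, 0.1, 0.2, 0.2, 0.1, 0.1])
        cfg = SimConfig(hours=1, steps_per_hour=500, replicates=1, seed=0)
        a = simulate((100, 100), pmf, flat_grid, cfg, seed=9)
        b = simulate((100, 100), pmf, flat_grid, cfg, seed=9)
        assert np.array_equal(a.cells, b.cells)
        assert np.array_equal(a.behaviors, b.behaviors)

    def test_never_enters_inaccessible_cells(self, lake_grid):
        pmf = make_pmf([0.3, 0.2, 0.3, 0.0, 0.1, 0.1])
        cfg = SimConfig(hours=2, steps_per_hour=850, replicates=1, seed=0)
        for s in range(3):
            traj = simulate((38, 30), pmf, lake_grid, cfg, seed=s)
            assert not lake_grid.inaccessible[traj.cells[:, 1], traj.cells[:, 0]].any()

    def test_lazy_random_walk_msd_slope_without_smoothing(self):
        # alpha=1: the rounded path is a simple lazy 9-cell walk whose mean
        # squared displacement grows by E[dx^2+dy^2] = 12/9 per step
        n = 2001
        grid = lp.GridMap(np.zeros((n, n)), np.zeros((n, n), bool), np.zeros((n, n), bool))
        cfg = SimConfig(alpha=1.0, hours=1, steps_per_hour=400, replicates=1, seed=0)
        msd = np.zeros(cfg.n_steps + 1)
        reps = 150
        for r in range(reps):
            traj = simulate((1000, 1000), ONE_HOT["RW"], grid, cfg, seed=r)
            d = traj.cells - np.array([1000, 1000])
            msd += (d**2).sum(axis=1)
        msd /= reps
        t = np.arange(len(msd))
        slope = np.polyfit(t[50:], msd[50:], 1)[0]
        assert abs(slope - 12.0 / 9.0) < 0.15

    def test_displacement_bound_over_random_steps(self, flat_grid):
        """||disp|| <= (1-a)||momentum|| + 1.5*a*sqrt(2) for local proposals.

        The proposal lies within Chebyshev distance 1 of the rounded cell
        and the continuous position is at most 0.5 off-center per component,
        so the step-direction term is bounded by 1.5*sqrt(2) cells.
        """
        pmf = make_pmf([0.3, 0.15, 0.25, 0.15, 0.15, 0.0])  # no history replay
        cfg = SimConfig(hours=1, steps_per_hour=100, replicates=1, seed=0)
        rng = np.random.default_rng(12345)
        st = init_agent((100, 100), flat_grid, rng)
        alpha = cfg.alpha
        bound_term = 1.5 * alpha * math.sqrt(2)
        for _ in range(100_000):
            ox, oy = st.x, st.y
            mom = math.hypot(st.x - st.px, st.y - st.py)
            step(st, pmf, flat_grid, cfg, rng)
            disp = math.hypot(st.x - ox, st.y - oy)
            assert disp <= (1 - alpha) * mom + bound_term + 1e-9


class TestReplicates:
    def test_replicate_count_and_order(self, flat_grid):
        cfg = SimConfig(hours=1, steps_per_hour=50, replicates=5, seed=3)
        trajs = simulate_replicates((100, 100), ONE_HOT["RW"], flat_grid, cfg)
        assert [t.replicate for t in trajs] == [0, 1, 2, 3, 4]

    def test_single_replicate_equals_child_seed_zero(self, flat_grid):
        cfg = SimConfig(hours=1, steps_per_hour=50, replicates=1, seed=3)
        pmf = make_pmf([0.5, 0, 0.3, 0.2, 0, 0])
        (traj,) = simulate_replicates((100, 100), pmf, flat_grid, cfg)
        direct = simulate((100, 100), pmf, flat_grid, cfg, seed=child_seed(3, 0))
        assert np.array_equal(traj.cells, direct.cells)

    def test_same_master_seed_identical_sets(self, flat_grid):
        cfg = SimConfig(hours=1, steps_per_hour=50, replicates=4, seed=11)
        pmf = make_pmf([0.4, 0.1, 0.3, 0.1, 0.1, 0])
        a = simulate_replicates((100, 100), pmf, flat_grid, cfg)
        b = simulate_replicates((100, 100), pmf, flat_grid, cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.cells, tb.cells)

    def test_replicates_differ_from_each_other(self, flat_grid):
        cfg = SimConfig(hours=1, steps_per_hour=200, replicates=3, seed=1)
        trajs = simulate_replicates((100, 100), ONE_HOT["RW"], flat_grid, cfg)
        assert not np.array_equal(trajs[0].cells, trajs[1].cells)


class TestTrajectoryExport:
    def test_csv_round_trip(self, flat_grid, tmp_path):
        import pandas as pd

        cfg = SimConfig(hours=1, steps_per_hour=20, replicates=1, seed=0)
        traj = simulate((100, 100), ONE_HOT["DT"], flat_grid, cfg, seed=1)
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        df = pd.read_csv(path, keep_default_na=False)
        assert list(df.columns) == ["step", "x", "y", "behavior"]
        assert len(df) == len(traj)
        assert (df[["x", "y"]].to_numpy() == traj.cells).all()
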