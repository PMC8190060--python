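"""Cell populations, Stokes drag, tracing, trapping and summaries."""

import numpy as np
import pytest
import shapely

from chipflow.geometry import ChipParams, post_patch_polygon
from chipflow.particles import (CellPopulation, DEFAULT_CV_SCHEDULE,
                                sample_population, release_positions,
                                stokes_drag, relaxation_time, trace,
                                first_arrival_time, position_histogram,
                                channel_occupancy, mean_cell_speed,
                                Trajectories, IN_DOMAIN, TRAPPED, EXITED,
                                _rk4_step)

from conftest import U_IN_40


class TestSampling:
    def test_zero_cv_is_degenerate(self):
        pop = sample_population(50, 12e-6, 0.0, seed=0)
        assert np.all(pop.diameters == 12e-6)

    def test_sample_mean_within_three_standard_errors(self):
        # 3 sigma / sqrt(n) = 3 * 1.8e-6 / 100 = 0.054 um around 12 um
        pop = sample_population(10_000, 12e-6, 0.15, seed=1)
        assert 11.95e-6 <= pop.diameters.mean() <= 12.05e-6
        assert np.all(pop.diameters > 0)
        assert pop.diameters.min() >= 12e-6 * (1 - 3 * 0.15) - 1e-12
        assert pop.diameters.max() <= 12e-6 * (1 + 3 * 0.15) + 1e-12

    def test_excessive_cv_rejected(self):
        with pytest.raises(ValueError):
            sample_population(10, 12e-6, 0.34)

    def test_deterministic_for_fixed_seed(self):
        a = sample_population(100, 12e-6, 0.15, seed=7)
        b = sample_population(100, 12e-6, 0.15, seed=7)
        assert np.array_equal(a.diameters, b.diameters)

    def test_default_cv_schedule_wider_for_larger_cells(self):
        assert DEFAULT_CV_SCHEDULE[19e-6] > DEFAULT_CV_SCHEDULE[8e-6]
        pop8 = sample_population(10, 8e-6, seed=0)
        pop19 = sample_population(10, 19e-6, seed=0)
        assert pop19.cv > pop8.cv


class TestRelease:
    def test_reproducible_positions_per_seed(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        pop = sample_population(1000, 12e-6, 0.15, seed=3)
        p1, v1, t1 = release_positions(pop, ev, seed=5)
        p2, v2, t2 = release_positions(pop, ev, seed=5)
        assert np.array_equal(p1, p2) and np.array_equal(v1, v2)

    def test_release_y_uniform_by_ks(self, default_model):
        """KS statistic vs uniform below the alpha=0.01 critical value
        1.628 / sqrt(n) for n = 10^4 (point-size particles, no wall clip)."""
        ev = default_model.evaluator(U_IN_40)
        pop = sample_population(10_000, 1e-8, 0.0, seed=2)
        pos, _, _ = release_positions(pop, ev, seed=2)
        w = default_model.params.inlet_width
        u = np.sort((pos[:, 1] + w / 2) / w)
        n = len(u)
        d = np.max(np.maximum(u - np.arange(n) / n, (np.arange(1, n + 1)) / n - u))
        assert d < 1.628 / np.sqrt(n)

    def test_initial_velocity_couples_to_fluid(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        pop = sample_population(20, 12e-6, 0.0, seed=4)
        pos, vel, _ = release_positions(pop, ev, seed=4)
        assert np.allclose(vel, ev.velocity(pos), equal_nan=True)

    def test_zero_cells_trace_without_error(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        pop = CellPopulation(diameters=np.empty(0), mean_diameter=12e-6,
                             cv=0.0, seed=0)
        traj = trace(ev, pop, dt=2e-3, t_end=0.2)
        assert traj.n == 0
        assert first_arrival_time(traj) is None


class TestForces:
    def test_equilibrium_gives_zero_drag(self):
        v = np.array([[1e-3, 0.0]])
        assert np.all(stokes_drag(12e-6, 1e-3, v, v) == 0.0)

    def test_hand_value_for_12um_cell(self):
        # 3 pi * 12e-6 * 1e-3 * 1e-3 = 1.131e-10 N
        f = stokes_drag(12e-6, 1e-3, np.array([[1e-3, 0.0]]), np.array([[0.0, 0.0]]))
        assert np.linalg.norm(f) == pytest.approx(1.131e-10, rel=1e-3)

    def test_drag_linear_in_diameter(self):
        v, vp = np.array([[2e-3, 1e-3]]), np.array([[0.0, 0.0]])
        f1 = stokes_drag(6e-6, 1e-3, v, vp)
        f2 = stokes_drag(12e-6, 1e-3, v, vp)
        assert np.allclose(f2, 2 * f1)

    def test_relaxation_time_hand_value_and_tracer_regime(self):
        tau = relaxation_time(12e-6, 1050.0, 1e-3)
        assert tau == pytest.approx(8.4e-6, rel=1e-3)
        assert tau < 1e-4 * 5.8          # << advective first-arrival time ~5.8 s
        assert relaxation_time(0.0, 1050.0, 1e-3) == 0.0


class TestIntegration:
    def test_rk4_exact_for_uniform_advection(self):
        U = np.array([3e-3, -1e-3])
        x = np.zeros((1, 2))
        for _ in range(10_000):
            x = _rk4_step(lambda p: np.tile(U, (len(p), 1)), x, 1e-3)
        exact = U * 10.0
        assert np.linalg.norm(x[0] - exact) / np.linalg.norm(exact) < 1e-10

    def test_inertial_and_tracer_modes_agree_for_cells(self, default_model):
        """Relaxation-time argument: microsecond particle inertia leaves
        trajectories within 0.1% of the channel length for (at least) 95% of
        cells; the worst case stays below 0.5% (cells arriving at a channel
        mouth trade a small inertial time lag for a position offset at the
        manifold/array speed jump)."""
        ev = default_model.evaluator(U_IN_40)
        pop = sample_population(50, 12e-6, 0.15, seed=6)
        a = trace(ev, pop, dt=2e-3, t_end=2.0, seed=6, mode="tracer")
        b = trace(ev, pop, dt=2e-3, t_end=2.0, seed=6, mode="inertial")
        d = np.linalg.norm(a.positions[-1] - b.positions[-1], axis=1)
        assert np.nanquantile(d, 0.95) < 1e-3 * 20e-3
        assert np.nanmax(d) < 5e-3 * 20e-3
        # the inertial mode records its drag forces
        assert b.drag is not None and np.isfinite(b.drag[-1]).any()

    def test_seed_determinism_bit_for_bit(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        pop = sample_population(30, 12e-6, 0.15, seed=9)
        a = trace(ev, pop, dt=2e-3, t_end=1.0, seed=9)
        b = trace(ev, pop, dt=2e-3, t_end=1.0, seed=9)
        assert np.array_equal(a.positions, b.positions, equal_nan=True)
        assert np.array_equal(a.status, b.status)


class TestTrapping:
    def test_12um_cells_trap_at_terminal_microposts(self, sw_trace, default_model):
        g = default_model.geom
        trapped = sw_trace.status[-1] == TRAPPED
        assert trapped.any()
        xs = sw_trace.positions[-1, trapped, 0]
        radii = sw_trace.diameters[trapped] / 2
        assert np.allclose(xs, g.capture_x(0.0) - radii, atol=1e-9)

    def test_count_conservation_at_every_frame(self, sw_trace):
        for fi in range(len(sw_trace.times)):
            c = sw_trace.counts(fi)
            assert c["in_domain"] + c["trapped"] + c["exited"] == sw_trace.n

    @pytest.fixture(scope="class")
    def small_particle_trace(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        pop = sample_population(5, 3e-6, 0.0, seed=11)
        return trace(ev, pop, dt=2e-3, t_end=12.0, seed=11)

    def test_small_particles_pass_the_gaps_and_exit(self, small_particle_trace):
        c = small_particle_trace.counts(-1)
        assert c["trapped"] == 0
        assert c["exited"] >= 2

    def test_no_trajectory_point_inside_a_post(self, small_particle_trace,
                                               default_model):
        ev = small_particle_trace.evaluator
        traj = small_particle_trace
        _, posts, _ = post_patch_polygon(default_model.params)
        union = shapely.unary_union(posts)
        g = default_model.geom
        pos = traj.positions.reshape(-1, 2)
        pos = pos[np.isfinite(pos).all(axis=1)]
        inz = (pos[:, 0] >= ev.x_patch) & (pos[:, 0] <= g.x_collection_end)
        loc = pos[inz].copy()
        k = np.clip(g.channel_of(loc[:, 1], None), 0, 127)
        loc[:, 0] -= ev.x_patch
        loc[:, 1] -= g.channel_center_y(k)
        assert not shapely.contains_xy(union, loc[:, 0], loc[:, 1]).any()

    def test_queueing_stacks_cells_one_diameter_apart(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        pop = sample_population(60, 12e-6, 0.0, seed=13)
        traj = trace(ev, pop, dt=2e-3, t_end=10.0, seed=13, queueing=True)
        g = default_model.geom
        trapped = traj.status[-1] == TRAPPED
        xs = traj.positions[-1, trapped, 0]
        ks = g.channel_of(traj.positions[-1, trapped, 1], None)
        for k in np.unique(ks):
            q = np.sort(xs[ks == k])[::-1]
            if len(q) > 1:
                gaps = -np.diff(q)
                assert np.all(gaps >= 12e-6 * 0.999)


class TestArrivalAndSummaries:
    def test_first_arrival_near_centerline_transit_time(self, sw_trace, default_model):
        g = default_model.geom
        fa = first_arrival_time(sw_trace)
        assert fa is not None
        # channel transit of the fastest (near-centerline) cells: L / (1.5 Uc)
        ev = sw_trace.evaluator
        entry = (g.capture_x(6e-6) - g.x_channels_start) / (1.5 * ev.Uc)
        manifold = 0.3    # lower bound on feed+header transit
        assert fa > entry + manifold * 0.5
        assert fa < entry * 1.25 + 1.5

    def test_doubling_inlet_velocity_halves_first_arrival(self, default_model):
        pops = sample_population(80, 12e-6, 0.15, seed=17)
        t = {}
        for fac in (1.0, 2.0):
            ev = default_model.evaluator(U_IN_40 * fac)
            traj = trace(ev, pops, dt=1e-3, t_end=12.0, seed=17,
                         stop_at_first_arrival=True)
            t[fac] = first_arrival_time(traj)
        assert t[1.0] / t[2.0] == pytest.approx(2.0, rel=0.01)

    def test_histogram_counts_and_bins(self, sw_trace):
        fa = first_arrival_time(sw_trace)
        counts, edges, per_channel = position_histogram(sw_trace, fa, 40)
        live = np.isin(sw_trace.status[sw_trace.frame_at(fa)], (IN_DOMAIN, TRAPPED))
        assert counts.sum() == live.sum()
        assert len(edges) == 41
        assert per_channel.sum() <= counts.sum()

    def test_all_cells_at_origin_fall_in_bin_zero(self, sw_trace):
        counts, edges, _ = position_histogram(sw_trace, 0.0, 25)
        assert counts[0] == sw_trace.n
        assert counts[1:].sum() == 0

    def test_histogram_decays_toward_outlet(self, decay_replicates):
        """Counts decrease from inlet to outlet along the channel region in
        >= 95% of 20 seeded replicates (linear-fit slope <= 0)."""
        ok = 0
        for traj in decay_replicates:
            fa = first_arrival_time(traj) or traj.times[-1]
            g = traj.evaluator.geom
            counts, edges, _ = position_histogram(
                traj, fa, 20, x_range=(g.x_channels_start, g.x_channels_end))
            xc = 0.5 * (edges[:-1] + edges[1:])
            slope = np.polyfit(xc, counts, 1)[0]
            ok += slope <= 0
        assert ok >= 19

    def test_mirrored_channel_pairs_equal_within_binomial_error(self, decay_replicates):
        """Pooled over replicates, top/bottom mirror channels hold equal
        counts up to binomial sampling noise (two-sided, alpha = 0.01)."""
        from scipy.stats import binomtest
        total = np.zeros(128, dtype=int)
        for traj in decay_replicates:
            fa = first_arrival_time(traj) or traj.times[-1]
            _, _, per_channel = position_histogram(traj, fa, 10)
            total += per_channel
        fails = 0
        tested = 0
        for k in range(64):
            a, b = int(total[k]), int(total[127 - k])
            if a + b == 0:
                continue
            tested += 1
            if binomtest(a, a + b, 0.5).pvalue < 0.01:
                fails += 1
        assert tested > 50
        assert fails <= max(3, 0.05 * tested)   # alpha = 0.01 expects ~1 false hit

    def test_occupancy_monotone_in_cell_count(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        wins = 0
        for seed in range(5):
            occ = {}
            for n in (60, 180):      # 1:3, the published concentration ratio
                pop = sample_population(n, 12e-6, 0.15, seed=seed)
                traj = trace(ev, pop, dt=4e-3, t_end=15.0, seed=seed,
                             stop_at_first_arrival=True)
                fa = first_arrival_time(traj) or traj.times[-1]
                occ[n] = channel_occupancy(traj, fa)
            wins += occ[180] >= occ[60]
        assert wins == 5

    def test_zero_cells_zero_occupancy(self, default_model):
        ev = default_model.evaluator(U_IN_40)
        pop = CellPopulation(diameters=np.empty(0), mean_diameter=12e-6, cv=0, seed=0)
        traj = trace(ev, pop, dt=2e-3, t_end=0.2)
        assert channel_occupancy(traj, 0.1) == 0.0


class TestMeanCellSpeed:
    def _uniform_traj(self, default_model, speed=4e-3):
        ev = default_model.evaluator(U_IN_40)
        times = np.arange(31) / 30.0
        n = 5
        x0 = default_model.geom.x_channels_start + 1e-3
        pos = np.zeros((31, n, 2))
        pos[..., 0] = x0 + speed * times[:, None]
        pos[..., 1] = np.linspace(-1e-3, 1e-3, n)
        return Trajectories(times=times, positions=pos,
                            status=np.zeros((31, n), dtype=np.int8),
                            diameters=np.full(n, 12e-6), release_times=np.zeros(n),
                            event_times=np.full(n, np.nan), evaluator=ev)

    def test_uniform_motion_recovered_exactly(self, default_model):
        traj = self._uniform_traj(default_model)
        assert mean_cell_speed(traj, region="all") == pytest.approx(4e-3, rel=1e-12)
        assert mean_cell_speed(traj, region="all", weighting="tracks") == \
            pytest.approx(4e-3, rel=1e-12)

    def test_speed_scales_linearly_with_flow(self, default_model):
        pop = sample_population(120, 12e-6, 0.15, seed=21)
        vals = {}
        for fac in (0.5, 1.0):
            ev = default_model.evaluator(U_IN_40 * fac)
            traj = trace(ev, pop, dt=2e-3, t_end=18.0, seed=21,
                         stop_at_first_arrival=True)
            vals[fac] = mean_cell_speed(traj, region="channels")
        assert vals[1.0] / vals[0.5] == pytest.approx(2.0, rel=0.02)

    def test_no_samples_in_region_raises(self, default_model):
        traj = self._uniform_traj(default_model)
        traj.positions[..., 0] -= 10e-3   # move everything out of the channels
        with pytest.raises(ValueError):
            mean_cell_speed(traj, region="channels")
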