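import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_density, random_point_set
from symspike.density import DensityConfig, symmetry_density
from symspike.fields import BinningSpec, Metric, PointSet, distance
from symspike.snn import (
    DelayLine,
    LIFParams,
    NetworkState,
    add_delay_noise,
    build_symmetry_network,
    detect_symmetry,
    export_trace_csv,
    latency,
    run_symmetry,
    step,
)


class TestLIFParams:
    def test_threshold_must_exceed_pulse(self):
        with pytest.raises(ValueError):
            LIFParams(threshold=1.0, pulse_amplitude=1.0)

    def test_default_pair_coincidence(self):
        assert LIFParams().min_coincidence == 2


class TestDelayLine:
    @given(length=st.integers(1, 12),
           schedule=st.lists(st.booleans(), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_representations_observationally_equal(self, length, schedule):
        """Shift-register and countdown lines emit identical outputs for
        identical insertion schedules."""
        sr = DelayLine(length, "shift_register")
        cd = DelayLine(length, "countdown")
        outputs = []
        for fire in schedule + [False] * (length + 1):
            if fire:
                sr.insert(1.0)
                cd.insert(1.0)
            assert sr.tick() == cd.tick()

    @pytest.mark.parametrize("representation", ["shift_register", "countdown"])
    def test_emergence_after_exactly_length_cycles(self, representation):
        # Insertion precedes tick 0, so the pulse is in flight during ticks
        # 0..L-1 and emerges on the tick producing cycle L.
        line = DelayLine(4, representation)
        line.insert(1.0)
        emitted = [line.tick() for _ in range(6)]
        assert emitted == [0.0, 0.0, 0.0, 0.0, 1.0, 0.0]

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            DelayLine(0)


class TestBuildNetwork:
    def test_8x8_has_4096_lines_max_16(self):
        topo = build_symmetry_network(8, 8, Metric.MANHATTAN, k=1, base=2)
        assert topo.n_lines == 4096
        assert topo.max_delay == 16  # Manhattan max 14 plus 2-cycle base

    def test_1x1_single_line_of_base_length(self):
        topo = build_symmetry_network(1, 1, Metric.MANHATTAN, base=2)
        assert topo.n_lines == 1
        assert topo.max_delay == 2

    def test_delay_symmetry(self):
        topo = build_symmetry_network(5, 4, Metric.EUCLIDEAN)
        assert np.array_equal(topo.delays, topo.delays.T)
        assert topo.delays.min() >= topo.base

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            build_symmetry_network(0, 3)


class TestLatency:
    def test_8x8_manhattan_is_18(self):
        topo = build_symmetry_network(8, 8, Metric.MANHATTAN, k=1, base=2)
        assert latency(topo, accumulation_stages=2) == 18

    def test_1x1(self):
        assert latency(build_symmetry_network(1, 1), 2) == 4

    def test_nondecreasing_in_grid_size(self):
        lats = [latency(build_symmetry_network(n, n)) for n in (2, 4, 6, 8)]
        assert lats == sorted(lats)


class TestStep:
    def test_quiet_network_stays_quiet(self):
        state = NetworkState(build_symmetry_network(3, 3))
        step(state)
        assert state.cycle == 1
        assert np.all(state.acc == 0)
        assert not state.trace.fires_array().any()

    def test_two_simultaneous_pulses_fire(self):
        """Hand-trace: two amplitude-1 pulses in one cycle reach
        2 - 0.5 = 1.5 >= theta and fire; the accumulator resets."""
        topo = build_symmetry_network(3, 1, Metric.MANHATTAN, base=2)
        params = LIFParams()
        # Inputs (0,0) and (2,0) are both Manhattan distance 1 from (1,0).
        trace = run_symmetry(topo, PointSet.from_points([(0, 0), (2, 0)]), params)
        mid = topo.neuron_index(1, 0)
        fires = trace.fires_array()
        assert fires[:, mid].any()
        fire_cycle = int(np.nonzero(fires[:, mid])[0][0])
        assert fire_cycle == 3  # delay 1 + base 2
        assert trace.acc[fire_cycle][mid] == 0.0  # reset on fire

    def test_pulses_two_cycles_apart_do_not_fire(self):
        """Hand-trace oracle: first pulse leaves 0.5, leaks to 0, second
        pulse reaches only 0.5 < 1.5."""
        topo = build_symmetry_network(4, 1, Metric.MANHATTAN, base=2)
        # Distances to output (0,0): input 1 -> 1 cycle, input 3 -> 3 cycles.
        trace = run_symmetry(topo, PointSet.from_points([(1, 0), (3, 0)]))
        out = topo.neuron_index(0, 0)
        assert not trace.fires_array()[:, out].any()
        accs = [a[out] for a in trace.acc]
        assert max(accs) == 0.5

    def test_pulses_one_cycle_apart_do_not_fire(self):
        topo = build_symmetry_network(3, 1, Metric.MANHATTAN, base=2)
        trace = run_symmetry(topo, PointSet.from_points([(1, 0), (2, 0)]))
        out = topo.neuron_index(0, 0)
        # Arrivals at cycles 3 and 4: 0.5 residual + 1 - 0.5 = 1.0 < 1.5.
        assert not trace.fires_array()[:, out].any()
        assert max(a[out] for a in trace.acc) == 1.0


class TestRunSymmetry:
    def test_single_input_never_fires(self, rng):
        topo = build_symmetry_network(6, 6)
        trace = run_symmetry(topo, PointSet.from_points([(2, 3)]))
        assert not trace.fires_array().any()
        assert np.all(detect_symmetry(trace).values == 1)

    def test_equidistant_pair_fires_midline_only(self):
        topo = build_symmetry_network(8, 8, Metric.MANHATTAN)
        a, b = (1, 3), (5, 3)
        trace = run_symmetry(topo, PointSet.from_points([a, b]))
        fired = trace.fires_array().any(axis=0).reshape(8, 8)
        for y in range(8):
            for x in range(8):
                equidistant = distance((x, y), a, Metric.MANHATTAN) == \
                    distance((x, y), b, Metric.MANHATTAN)
                assert fired[y, x] == equidistant

    def test_horizon_too_small(self):
        topo = build_symmetry_network(4, 4)
        with pytest.raises(ValueError):
            run_symmetry(topo, PointSet.from_points([(0, 0)]), T=3)

    def test_causality(self, rng):
        """No arrival occurs before the shortest active line has drained
        nor after the longest one has."""
        topo = build_symmetry_network(7, 7)
        pts = random_point_set(rng, 7, 7, 5)
        trace = run_symmetry(topo, pts)
        arr = trace.arrivals_array()
        active_cycles = np.nonzero(arr.any(axis=1))[0]
        idx = [topo.neuron_index(x, y) for x, y in pts.coords]
        assert active_cycles.min() == topo.delays[idx, :].min()
        assert active_cycles.max() == topo.delays[idx, :].max()

    def test_determinism(self, rng):
        topo = build_symmetry_network(6, 6)
        pts = random_point_set(rng, 6, 6, 4)
        t1 = run_symmetry(topo, pts)
        t2 = run_symmetry(topo, pts)
        assert np.array_equal(t1.arrivals_array(), t2.arrivals_array())
        assert np.array_equal(t1.fires_array(), t2.fires_array())


class TestAlgorithmEquivalence:
    """The central claim: coincidence detection computes the same map as
    the explicit distance-histogram algorithm with whole-cycle bins."""

    @pytest.mark.parametrize("metric", list(Metric))
    def test_four_corner_equivalence(self, metric):
        topo = build_symmetry_network(9, 9, metric)
        pts = PointSet.from_points([(0, 0), (8, 0), (0, 8), (8, 8)])
        snn_map = detect_symmetry(run_symmetry(topo, pts))
        alg_map = symmetry_density(pts, (9, 9),
                                   DensityConfig(metric=metric, binning=BinningSpec(0)))
        assert np.array_equal(snn_map.values, alg_map.values)
        assert snn_map.values[4, 4] == 4

    @pytest.mark.parametrize("metric", list(Metric))
    def test_random_pointsets_equivalence(self, rng, metric):
        for _ in range(10):
            w, h = int(rng.integers(3, 13)), int(rng.integers(3, 13))
            n = int(rng.integers(1, min(w * h, 12) + 1))
            pts = random_point_set(rng, w, h, n)
            topo = build_symmetry_network(w, h, metric)
            snn_map = detect_symmetry(run_symmetry(topo, pts))
            alg_map = symmetry_density(
                pts, (w, h), DensityConfig(metric=metric, binning=BinningSpec(0)))
            assert np.array_equal(snn_map.values, alg_map.values)

    def test_matches_brute_force_directly(self, rng):
        pts = random_point_set(rng, 10, 10, 6)
        topo = build_symmetry_network(10, 10, Metric.EUCLIDEAN)
        snn_map = detect_symmetry(run_symmetry(topo, pts))
        want = brute_force_density(pts.coords, (10, 10), "euclidean", 0)
        assert np.array_equal(snn_map.values, want)


class TestDelayNoise:
    def test_zero_sd_identity(self):
        topo = build_symmetry_network(6, 6)
        assert add_delay_noise(topo, 0.0, seed=7) is topo

    def test_negative_sd(self):
        with pytest.raises(ValueError):
            add_delay_noise(build_symmetry_network(3, 3), -1.0)

    def test_deterministic_given_seed(self):
        topo = build_symmetry_network(6, 6)
        a = add_delay_noise(topo, 2.0, seed=5)
        b = add_delay_noise(topo, 2.0, seed=5)
        c = add_delay_noise(topo, 2.0, seed=6)
        assert np.array_equal(a.delays, b.delays)
        assert not np.array_equal(a.delays, c.delays)
        assert a.delays.min() >= topo.base

    def test_mse_grows_with_noise_sd(self):
        """Delay noise degrades the map more at sd=5 than sd=1 on average
        (Monte-Carlo, 10 seeds per level on a small symmetric outline)."""
        from symspike.density import density_mse, extract_points
        from symspike.fixtures import FixtureSpec, make_outline

        fld = make_outline(FixtureSpec("aircraft_like", 24))
        pts = extract_points(fld, 128.0)
        topo = build_symmetry_network(24, 24, Metric.EUCLIDEAN)
        clean = detect_symmetry(run_symmetry(topo, pts))
        means = {}
        for sd in (1.0, 5.0):
            vals = []
            for seed in range(10):
                noisy_topo = add_delay_noise(topo, sd, seed)
                noisy = detect_symmetry(run_symmetry(noisy_topo, pts))
                vals.append(density_mse(noisy, clean))
            means[sd] = np.mean(vals)
        assert means[5.0] > means[1.0]


def test_trace_csv_export(tmp_path):
    topo = build_symmetry_network(3, 1, Metric.MANHATTAN)
    trace = run_symmetry(topo, PointSet.from_points([(0, 0), (2, 0)]))
    path = tmp_path / "trace.csv"
    export_trace_csv(trace, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "cycle,neuron_kind,neuron_x,neuron_y,event,value"
    events = [ln.split(",")[4] for ln in lines[1:]]
    assert {"inject", "arrive", "fire"} <= set(events)
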