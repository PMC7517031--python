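import numpy as np
import pytest

from birhythm import (
    ConstantProtocol,
    GatedProtocol,
    NoStimulation,
    PeriodicProtocol,
    RandomTelegraphProtocol,
    constant_protocol,
    detect_plane_crossings,
    estimate_period,
    gated_protocol,
    integrate,
    make_protocol,
    periodic_protocol,
    random_protocol,
    stimulator_output,
)


class TestStimulatorOutput:
    @pytest.mark.parametrize("s_in, x, y, expected", [
        (0.0, 0.7, -1.2, 0.0),
        (4.0, 0.5, -0.5, -1.0),
        (4.0, 1.0, 1.0, 4.0),
    ])
    def test_bilinear_product(self, s_in, x, y, expected):
        assert stimulator_output(s_in, [x, y, 0.3]) == pytest.approx(expected)

    def test_linear_in_stimulus_and_odd_in_x(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, y = rng.uniform(-1.5, 1.5, size=2)
            a, b = rng.uniform(0, 4, size=2)
            st = [x, y, 0.0]
            assert stimulator_output(a + b, st) == pytest.approx(
                stimulator_output(a, st) + stimulator_output(b, st)
            )
            assert stimulator_output(a, [-x, y, 0.0]) == pytest.approx(
                -stimulator_output(a, st)
            )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stimulator_output(np.nan, [0.0, 0.0, 0.0])


class TestConstantProtocol:
    def test_zero_amplitude_equals_no_stimulation(self, config, slow_state):
        a = integrate(config, slow_state, constant_protocol(0.0), (0, 10), dt_out=0.1)
        b = integrate(config, slow_state, None, (0, 10), dt_out=0.1)
        np.testing.assert_allclose(a.states, b.states, atol=1e-12)

    def test_zero_mean_interface_output_over_whole_periods(self, config, slow_state):
        # x*y averages to ~0 over the orbit: constant stimulation has no
        # sustained effect on dz/dt
        traj = integrate(config, slow_state, None, (0.0, 100.0), dt_out=0.01)
        period = estimate_period(traj).period
        n_per = int(100.0 / period)
        mask = traj.t <= n_per * period
        s_out = 4.0 * traj.x[mask] * traj.y[mask]
        radius_sq = (traj.x ** 2 + traj.y ** 2).max()
        assert abs(s_out.mean()) < 0.05 * 4.0 * radius_sq

    def test_no_separatrix_crossing_from_either_attractor(
            self, config, slow_state, fast_state):
        for state in (slow_state, fast_state):
            traj = integrate(config, state, constant_protocol(4.0),
                             (0.0, 200.0), dt_out=0.05, tol=1e-7)
            assert detect_plane_crossings(traj, "z", 0.0) == []

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            constant_protocol(-1.0)


class TestRandomTelegraph:
    def test_seed_reproducibility(self):
        p1 = random_protocol(4.0, switch_rate=2.0, seed=42)
        p2 = random_protocol(4.0, switch_rate=2.0, seed=42)
        ts = np.linspace(0, 50, 501)
        np.testing.assert_array_equal([p1.s_in(t) for t in ts],
                                      [p2.s_in(t) for t in ts])
        np.testing.assert_array_equal(p1.breakpoints(0, 50), p2.breakpoints(0, 50))

    def test_long_run_on_fraction_is_half(self):
        # symmetric telegraph process: on and off each ~50% of the time
        p = random_protocol(1.0, switch_rate=1.0, seed=3)
        bps = np.concatenate([[0.0], p.breakpoints(0.0, 10000.0), [10000.0]])
        mids = 0.5 * (bps[:-1] + bps[1:])
        durations = np.diff(bps)
        on = np.array([p.s_in(t) > 0 for t in mids])
        frac = durations[on].sum() / durations.sum()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_holding_times_exponential_mean(self):
        p = random_protocol(1.0, switch_rate=4.0, seed=11)
        gaps = np.diff(np.concatenate([[0.0], p.breakpoints(0.0, 2000.0)]))
        assert gaps.mean() == pytest.approx(0.25, rel=0.1)

    def test_consistency_between_s_in_and_breakpoints(self):
        p = random_protocol(2.0, switch_rate=3.0, seed=9)
        bps = p.breakpoints(0.0, 20.0)
        for a, b in zip(bps[:-1], bps[1:]):
            mid = 0.5 * (a + b)
            assert p.s_in(mid) in (0.0, 2.0)
            # value flips across each breakpoint
            assert p.s_in(a - 1e-9) != p.s_in(a + 1e-9)


class TestPeriodicProtocol:
    def test_full_duty_degenerates_to_constant(self):
        assert isinstance(periodic_protocol(4.0, period=2.0, duty=1.0),
                          ConstantProtocol)

    def test_square_wave_values_and_edges(self):
        p = periodic_protocol(4.0, period=2.0, duty=0.25)
        assert p.s_in(0.1) == 4.0
        assert p.s_in(0.6) == 0.0
        assert p.s_in(2.1) == 4.0
        bps = p.breakpoints(0.0, 6.0)
        np.testing.assert_allclose(bps, [0.5, 2.0, 2.5, 4.0, 4.5], atol=1e-12)

    def test_integration_advances_through_many_cycles(self, config, slow_state):
        # regression guard: edge-time arithmetic must always advance time
        p = periodic_protocol(4.0, period=1.0, duty=0.5)
        traj = integrate(config, slow_state, p, (0.0, 20.0), dt_out=0.1)
        assert traj.t[-1] == pytest.approx(20.0)

    def test_tuned_periodic_stimulation_fails_to_transition(self, config,
                                                            slow_state):
        # even a square wave tuned to the unperturbed slow period cannot
        # cross the separatrix: any z displacement detunes the oscillation
        # frequency and breaks the phase lock
        slow_period = 16.625
        for phase in (0.0, slow_period / 3, 2 * slow_period / 3):
            p = periodic_protocol(4.0, period=slow_period, duty=0.5,
                                  phase=phase)
            traj = integrate(config, slow_state, p, (0.0, 100.0),
                             dt_out=0.05, tol=1e-7)
            assert detect_plane_crossings(traj, "z", 0.0) == []

    def test_invalid_duty_rejected(self):
        with pytest.raises(ValueError):
            PeriodicProtocol(period=1.0, duty=0.0)
        with pytest.raises(ValueError):
            PeriodicProtocol(period=-1.0)


class TestGatedProtocol:
    def test_rectification_signs(self):
        slow_to_fast = gated_protocol(4.0, "slow_to_fast")
        fast_to_slow = gated_protocol(4.0, "fast_to_slow")
        # x*y > 0: raw S_out positive -> blocked for slow->fast
        assert slow_to_fast.s_out(4.0, 0.5, 0.5) == 0.0
        assert slow_to_fast.s_out(4.0, 0.5, -0.5) == pytest.approx(-1.0)
        assert fast_to_slow.s_out(4.0, 0.5, 0.5) == pytest.approx(1.0)
        assert fast_to_slow.s_out(4.0, 0.5, -0.5) == 0.0

    def test_diode_drop_attenuates_and_blocks(self):
        p = gated_protocol(4.0, "slow_to_fast", diode_drop=0.6)
        assert p.s_out(4.0, 0.5, -0.5) == pytest.approx(-0.4)
        assert p.s_out(4.0, 0.1, -0.1) == 0.0  # |raw| = 0.04 < drop

    def test_transitions_both_directions(self, config, slow_state, fast_state,
                                         zstar):
        down = integrate(config, slow_state, gated_protocol(4.0, "slow_to_fast"),
                         (0.0, 200.0), dt_out=0.05, tol=1e-7)
        assert any(d < 0 for _, d in detect_plane_crossings(down, "z", 0.0))
        up = integrate(config, fast_state, gated_protocol(4.0, "fast_to_slow"),
                       (0.0, 200.0), dt_out=0.05, tol=1e-7)
        assert any(d > 0 for _, d in detect_plane_crossings(up, "z", 0.0))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gated_protocol(0.0, "slow_to_fast")
        with pytest.raises(ValueError):
            gated_protocol(4.0, "sideways")
        with pytest.raises(ValueError):
            GatedProtocol(amplitude=4.0, diode_drop=-0.1)


class TestMakeProtocol:
    def test_round_trip_through_spec(self):
        for proto in (ConstantProtocol(3.0),
                      RandomTelegraphProtocol(4.0, 2.0, seed=5),
                      PeriodicProtocol(4.0, 2.0, 0.25),
                      GatedProtocol(4.0, "fast_to_slow", 0.6),
                      NoStimulation()):
            rebuilt = make_protocol(proto.spec(), seed=5)
            assert rebuilt.spec() == proto.spec()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown protocol kind"):
            make_protocol({"kind": "sinusoidal"})
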