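import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from birhythm import (
    BirhythmicConfig,
    GRUParameters,
    birhythmic_rhs,
    birhythmic_rhs_batch,
    find_fixed_points,
    gru_rhs,
    jacobian_at,
    make_birhythmic_config,
    z_fixed_point,
)
from birhythm.dynamics import rotation_matrix


def bisect_tanh_root(g, lo=1e-9, hi=2.0, iters=200):
    """Independent bisection oracle for the positive root of z = tanh(g z)."""
    f = lambda z: math.tanh(g * z) - z
    assert f(lo) > 0 and f(hi) < 0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestGruRhs:
    def test_zero_parameters_sigmoid_gates(self):
        z2 = np.zeros((2, 2))
        b2 = np.zeros(2)
        p = GRUParameters(Us=z2, Ur=z2, Uh=z2, bs=b2, br=b2, bh=b2)
        # s = r = sigma(0) = 1/2, T = tanh(0) = 0 => dh/dt = -h/2
        np.testing.assert_allclose(gru_rhs([1.0, 0.0], p), [-0.5, 0.0])
        np.testing.assert_allclose(gru_rhs([0.0, 0.0], p), [0.0, 0.0])

    def test_origin_fixed_for_any_zero_bias(self):
        rng = np.random.default_rng(1)
        p = GRUParameters(
            Us=rng.normal(size=(3, 3)), Ur=rng.normal(size=(3, 3)),
            Uh=rng.normal(size=(3, 3)),
            bs=np.zeros(3), br=np.zeros(3), bh=np.zeros(3),
        )
        np.testing.assert_allclose(gru_rhs(np.zeros(3), p), np.zeros(3))

    def test_dimension_mismatch_raises(self):
        z2 = np.zeros((2, 2))
        p = GRUParameters(Us=z2, Ur=z2, Uh=z2, bs=np.zeros(2),
                          br=np.zeros(2), bh=np.zeros(2))
        with pytest.raises(ValueError, match="shape"):
            gru_rhs([1.0, 0.0, 0.0], p)
        with pytest.raises(ValueError, match="non-finite"):
            gru_rhs([np.nan, 0.0], p)

    def test_bad_parameter_shapes_rejected(self):
        with pytest.raises(ValueError):
            GRUParameters(Us=np.zeros((2, 3)), Ur=np.zeros((2, 2)),
                          Uh=np.zeros((2, 2)), bs=np.zeros(2),
                          br=np.zeros(2), bh=np.zeros(2))

    def test_matches_explicit_system_at_gamma_one(self):
        cfg = BirhythmicConfig(gamma=1.0)
        p = cfg.to_gru_parameters()
        rng = np.random.default_rng(42)
        for _ in range(50):
            h = rng.uniform(-1.5, 1.5, size=3)
            np.testing.assert_allclose(
                gru_rhs(h, p), birhythmic_rhs(h, cfg), atol=1e-12
            )

    def test_matches_explicit_system_with_time_constant(self):
        # the GRU rendering is the gamma = 1 normalization; dz scales by gamma
        cfg = BirhythmicConfig()  # gamma = 50
        p = cfg.to_gru_parameters()
        h = np.array([0.1, 0.0, 0.9])
        got = gru_rhs(h, p)
        want = birhythmic_rhs(h, cfg) * np.array([1.0, 1.0, cfg.gamma])
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestBirhythmicRhs:
    def test_origin_is_fixed_point(self, config):
        np.testing.assert_array_equal(
            birhythmic_rhs([0.0, 0.0, 0.0], config), np.zeros(3)
        )

    def test_z_axis_invariant(self, config):
        for z in (-1.2, -0.3, 0.5, 1.4):
            d = birhythmic_rhs([0.0, 0.0, z], config)
            assert d[0] == 0.0 and d[1] == 0.0

    def test_hand_evaluated_point(self):
        # independent arithmetic oracle at (0.5, 0.5, 0), alpha=pi/5, g=3, gamma=1
        cfg = BirhythmicConfig(gamma=1.0)
        a = math.pi / 5
        dx = 1.5 * (math.tanh(3 * (0.5 * math.cos(a) - 0.5 * math.sin(a))) - 0.5)
        dy = 1.5 * (math.tanh(3 * (0.5 * math.sin(a) + 0.5 * math.cos(a))) - 0.5)
        dz = 0.5 * (math.tanh(0.0) - 0.0)
        np.testing.assert_allclose(
            birhythmic_rhs([0.5, 0.5, 0.0], cfg), [dx, dy, dz], rtol=1e-14
        )

    def test_stimulus_enters_z_equation_only(self, config):
        h = [0.4, -0.2, 0.6]
        d0 = birhythmic_rhs(h, config, stim_out=0.0)
        d1 = birhythmic_rhs(h, config, stim_out=2.0)
        assert d1[0] == d0[0] and d1[1] == d0[1]
        assert d1[2] - d0[2] == pytest.approx(
            config.stim_gain * 2.0 / config.gamma, rel=1e-12
        )

    def test_batch_agrees_with_scalar(self, config):
        rng = np.random.default_rng(0)
        states = rng.uniform(-1.5, 1.5, size=(20, 3))
        batch = birhythmic_rhs_batch(states, config)
        for h, d in zip(states, batch):
            np.testing.assert_allclose(d, birhythmic_rhs(h, config), rtol=1e-13)


class TestConfigValidation:
    def test_defaults(self):
        cfg = make_birhythmic_config()
        assert cfg.alpha == pytest.approx(math.pi / 5)
        assert cfg.g_xy == 3.0 and cfg.g_z == 1.5

    def test_linear_gate_speed_factors(self):
        # 1 - s must equal (3/2 - z, 3/2 - z, 1/2) under the linear gate
        cfg = BirhythmicConfig(gamma=1.0)
        p = cfg.to_gru_parameters()
        for z in (-1.0, 0.0, 0.7, 1.4):
            h = np.array([0.3, -0.8, z])
            one_minus_s = 1.0 - (p.Us @ h + p.bs)
            np.testing.assert_allclose(one_minus_s, [1.5 - z, 1.5 - z, 0.5],
                                       rtol=1e-14)

    @pytest.mark.parametrize("bad", [
        dict(alpha=math.pi / 2),
        dict(alpha=0.1),
        dict(g_xy=1.0),          # g_xy cos(alpha) <= 1
        dict(gamma=-1.0),
        dict(g_z=0.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            make_birhythmic_config(**{k: v for k, v in bad.items()})

    def test_unvalidated_constructor_skips_checks(self):
        cfg = BirhythmicConfig.unvalidated(g_xy=0.8)
        assert cfg.g_xy == 0.8


class TestZFixedPoint:
    def test_subcritical_gain_gives_origin_only(self):
        assert z_fixed_point(0.5) == 0.0
        assert z_fixed_point(1.0) == 0.0

    @pytest.mark.parametrize("g", [1.5, 3.0, 2.0])
    def test_matches_bisection_oracle(self, g):
        assert z_fixed_point(g) == pytest.approx(bisect_tanh_root(g), abs=1e-10)

    def test_reference_gain_levels(self):
        # g_z = 3/2 puts the sinks at 0.8586; g_z = 3 near 0.995
        assert z_fixed_point(1.5) == pytest.approx(0.85856, abs=5e-6)
        assert z_fixed_point(3.0) == pytest.approx(0.99490, abs=5e-5)


class TestFixedPoints:
    def test_default_config_three_on_z_axis(self, config, zstar):
        fps = find_fixed_points(config)
        assert len(fps) == 3
        zs = sorted(fp.state[2] for fp in fps)
        np.testing.assert_allclose(zs, [-zstar, 0.0, zstar], atol=1e-10)
        for fp in fps:
            assert fp.state[0] == 0.0 and fp.state[1] == 0.0

    def test_origin_fully_unstable_sinks_are_saddle_foci(self, config):
        by_z = {round(fp.state[2], 3): fp for fp in find_fixed_points(config)}
        origin = by_z[0.0]
        assert origin.stability == "unstable" and origin.n_unstable == 3
        for zk, fp in by_z.items():
            if zk != 0.0:
                assert fp.stability == "saddle-focus"
                # stable in z, unstable focus in the planar directions
                assert fp.n_unstable == 2

    def test_origin_planar_growth_rate_closed_form(self, config):
        origin = [fp for fp in find_fixed_points(config)
                  if fp.state[2] == 0.0][0]
        expected = 1.5 * (config.g_xy * math.cos(config.alpha) - 1.0)
        pair = sorted(origin.eigenvalues, key=lambda e: abs(e.imag))[-2:]
        for e in pair:
            assert e.real == pytest.approx(expected, rel=1e-5)

    def test_subcritical_z_gain_leaves_only_origin(self):
        cfg = BirhythmicConfig(g_z=0.5)
        assert len(find_fixed_points(cfg)) == 1


class TestJacobian:
    def test_origin_planar_block_closed_form(self, config):
        J = jacobian_at([0.0, 0.0, 0.0], config)
        expected = 1.5 * (config.g_xy * rotation_matrix(config.alpha) - np.eye(2))
        np.testing.assert_allclose(J[:2, :2], expected, atol=1e-6)

    def test_origin_z_derivative_closed_form(self, config):
        J = jacobian_at([0.0, 0.0, 0.0], config)
        assert J[2, 2] == pytest.approx(
            0.5 * (config.g_z - 1.0) / config.gamma, abs=1e-8
        )

    def test_z_row_decoupled_from_planar_state(self, config, zstar):
        J = jacobian_at([0.3, -0.4, zstar], config)
        assert abs(J[2, 0]) < 1e-8 and abs(J[2, 1]) < 1e-8


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.floats(-1.5, 1.5), y=st.floats(-1.5, 1.5),
    x2=st.floats(-1.5, 1.5), y2=st.floats(-1.5, 1.5),
    z=st.floats(-1.4, 1.4),
)
def test_z_equation_independent_of_planar_state(x, y, x2, y2, z):
    cfg = BirhythmicConfig()
    d1 = birhythmic_rhs([x, y, z], cfg)
    d2 = birhythmic_rhs([x2, y2, z], cfg)
    assert d1[2] == d2[2]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.floats(-1.5, 1.5), y=st.floats(-1.5, 1.5),
    z1=st.floats(-1.4, 1.3), z2=st.floats(-1.4, 1.3),
)
def test_planar_flow_rescales_with_z(x, y, z1, z2):
    # identical (x, y): planar derivatives are parallel with speed ratio
    cfg = BirhythmicConfig()
    d1 = birhythmic_rhs([x, y, z1], cfg)[:2]
    d2 = birhythmic_rhs([x, y, z2], cfg)[:2]
    np.testing.assert_allclose(d1 * (1.5 - z2), d2 * (1.5 - z1),
                               atol=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(z=st.floats(-1.45, 1.45))
def test_z_subsystem_odd_symmetry(z):
    cfg = BirhythmicConfig()
    dz_pos = birhythmic_rhs([0.2, 0.1, z], cfg)[2]
    dz_neg = birhythmic_rhs([0.2, 0.1, -z], cfg)[2]
    assert dz_pos == pytest.approx(-dz_neg, abs=1e-15)
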