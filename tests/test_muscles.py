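"""Hill muscle model: activation dynamics, moment-arm-consistent
musculotendon kinematics, force generation and torque mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import posturesim as ps
from posturesim import muscles
from posturesim.model import initial_state
from posturesim.params import MUSCLES, deg2rad


def test_activation_fixed_points():
    assert muscles.activation_dynamics(0.5, 0.5) == pytest.approx(0.0)
    assert muscles.activation_dynamics(0.0, 0.0) == pytest.approx(0.0)


def test_activation_step_matches_exponential():
    """Step excitation 0 -> 1: a(t) follows 1 - exp(-t/tau_act)."""
    tau = 0.010
    a, h = 0.0, 1e-5
    for _ in range(int(0.02 / h)):          # 2 time constants
        a += h * muscles.activation_dynamics(1.0, a, tau_act=tau)
    assert a == pytest.approx(1.0 - np.exp(-0.02 / tau), abs=1e-4)


def test_activation_clamps_out_of_range_input(caplog):
    import logging
    with caplog.at_level(logging.WARNING):
        da = muscles.activation_dynamics(1.5, 0.5)
    assert "clamping" in caplog.text
    assert da == pytest.approx(muscles.activation_dynamics(1.0, 0.5))


def test_reference_posture_gives_reference_lengths(pm):
    q0, qd0 = initial_state(pm)
    lm, lmd = muscles.musculotendon_kinematics(pm, q0, qd0)
    assert np.allclose(lm, pm.lmref)
    assert np.allclose(lmd, 0.0)


def test_constant_moment_arm_linear_length_change(pm, model_config):
    """Constant moment arm r: joint excursion dtheta changes normalized
    length by +r dtheta / l_opt (dL/dtheta = -r, fiber shortens toward
    the muscle)."""
    q0, _ = initial_state(pm)
    i = MUSCLES.index("sol")
    r = model_config.muscles["sol"].moment_arms["ankle"][0]
    dth = 0.2
    q = q0.copy()
    q[5] += dth
    lm, _ = muscles.musculotendon_kinematics(pm, q)
    expected = pm.lmref[i] - r * dth / pm.lopt[i]
    assert lm[i] == pytest.approx(expected, abs=1e-12)


def test_length_derivative_matches_moment_arm_polynomial():
    """For polynomial moment arms, dL/dtheta = -r(theta) to FD accuracy."""
    cfg = ps.ModelConfig()
    cfg.muscles["sol"].moment_arms["ankle"] = (-0.048, 0.01)
    pm2 = ps.pack_model(cfg)
    i = MUSCLES.index("sol")
    q0, _ = initial_state(pm2)
    eps = 1e-6
    qp, qm = q0.copy(), q0.copy()
    qp[5] += eps
    qm[5] -= eps
    lp, _ = muscles.musculotendon_kinematics(pm2, qp)
    lm_, _ = muscles.musculotendon_kinematics(pm2, qm)
    dL_dth = (lp[i] - lm_[i]) / (2 * eps) * pm2.lopt[i]
    r_here = -0.048 + 0.01 * q0[5]
    assert dL_dth == pytest.approx(-r_here, abs=1e-8)


def test_velocity_from_moment_arm(pm):
    q0, _ = initial_state(pm)
    qd = np.zeros(6)
    qd[5] = 1.5
    i = MUSCLES.index("ta")
    r = pm.r0[i, 2]
    _, lmd = muscles.musculotendon_kinematics(pm, q0, qd)
    assert lmd[i] == pytest.approx(-r * 1.5 / pm.lopt[i], abs=1e-12)


def test_force_normalization_endpoints(pm):
    n = len(MUSCLES)
    ones, zeros = np.ones(n), np.zeros(n)
    # a=1, lm=1, lmdot=0 -> F = f_max
    F, Fn = muscles.muscle_force(pm, ones, ones, zeros)
    assert np.allclose(F, pm.fmax)
    assert np.allclose(Fn, 1.0)
    # a=0, lm <= 1 -> no force at all
    F, Fn = muscles.muscle_force(pm, zeros, 0.9 * ones, zeros)
    assert np.allclose(F, 0.0)
    # maximal shortening kills active force
    F, Fn = muscles.muscle_force(pm, ones, ones, -pm.vmax)
    assert np.allclose(F, 0.0, atol=1e-9)


def test_joint_torques_zero_and_single_muscle(pm):
    q0, _ = initial_state(pm)
    tau = muscles.joint_torques(pm, np.zeros(9), q0)
    assert np.allclose(tau, 0.0)
    f = np.zeros(9)
    i = MUSCLES.index("sol")
    f[i] = 100.0
    tau = muscles.joint_torques(pm, f, q0)
    assert tau[2] == pytest.approx(pm.r0[i, 2] * 100.0)
    assert tau[0] == 0.0 and tau[1] == 0.0


def test_joint_torques_superposition(pm, rng):
    q0, _ = initial_state(pm)
    f1 = rng.uniform(0, 500, 9)
    f2 = rng.uniform(0, 500, 9)
    t1 = muscles.joint_torques(pm, f1, q0)
    t2 = muscles.joint_torques(pm, f2, q0)
    t12 = muscles.joint_torques(pm, f1 + f2, q0)
    assert np.allclose(t12, t1 + t2, atol=1e-9)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(lm=st.floats(0.3, 1.8), v=st.floats(-12.0, 12.0))
def test_hill_curves_properties(lm, v):
    """Force-length peaks at optimum; force-velocity is nonnegative,
    zero at maximal shortening, one at rest and monotone."""
    fl = muscles.force_length(lm)
    assert 0.0 <= fl <= muscles.force_length(1.0) == 1.0
    fv = muscles.force_velocity(v)
    assert fv >= 0.0
    assert muscles.force_velocity(-10.0) == pytest.approx(0.0)
    assert muscles.force_velocity(0.0) == pytest.approx(1.0)
    assert muscles.force_velocity(v + 0.1) >= fv - 1e-12
    # passive curve engages only above optimal length
    assert muscles.force_passive(min(lm, 1.0)) == 0.0


def test_muscle_params_spanned_joint_invariant():
    bad = ps.MuscleParams("ham", f_max=100.0, l_opt=0.1,
                          moment_arms={"hip": (-0.06, 0.0)})
    with pytest.raises(ValueError):
        bad.validate()
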