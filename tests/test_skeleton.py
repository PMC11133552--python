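"""Skeletal dynamics: closed-form pendulum, energy conservation, COM,
head kinematics and structural properties of the equations of motion."""

import math

import numpy as np
import pytest

import posturesim as ps
from posturesim import _kernel, skeleton
from posturesim.model import initial_state
from posturesim.params import deg2rad
from posturesim.skeleton import GeneralizedState


def _state(q, qd=None):
    return GeneralizedState(np.asarray(q, float),
                            np.zeros(6) if qd is None else np.asarray(qd, float))


def test_zero_gravity_equilibrium(pm):
    """Static state, zero gravity, zero torques gives zero accelerations."""
    q0, qd0 = initial_state(pm)
    qdd = skeleton.forward_dynamics(pm, _state(q0), gravity=0.0)
    assert np.allclose(qdd, 0.0, atol=1e-12)


def test_locked_chain_pendulum_closed_form(pm, model_config):
    """All joints locked, only pelvis tilt free: the rigid body rotating
    about the fixed hip point obeys the compound-pendulum closed form
    thetaddot = (m g d / I) sin(theta) computed independently from the
    segment table."""
    lean = math.radians(5.0)
    q = np.zeros(6)
    q[1] = 1.0
    q[2] = lean          # straight column, tilted
    qdd = skeleton.forward_dynamics(
        pm, _state(q), locked=("pelvis_x", "pelvis_z", "hip", "knee", "ankle"))

    # independent oracle: hand-built segment COM positions for the straight
    # pose (all relative joint angles zero, common orientation = lean)
    segs = model_config.segments
    ct = segs["trunk"].com_offset
    lth, cth = segs["thigh"].length, segs["thigh"].com_offset
    lsh, csh = segs["shank"].length, segs["shank"].com_offset
    fc = np.asarray(model_config.foot_com)
    s, c = math.sin(lean), math.cos(lean)
    R = np.array([[c, -s], [s, c]])
    down = np.array([s, -c])
    up = np.array([-s, c])
    coms = {
        "trunk": ct * up,
        "thigh": cth * down,
        "shank": lth * down + csh * down,
        "foot": (lth + lsh) * down + R @ fc,
    }
    mult = {"trunk": 1.0, "thigh": 2.0, "shank": 2.0, "foot": 2.0}
    I_hip, torque = 0.0, 0.0
    g = model_config.gravity
    for name, r in coms.items():
        m = mult[name] * segs[name].mass
        I_hip += mult[name] * segs[name].inertia + m * (r @ r)
        # generalized gravity force on the tilt coordinate: -m g dz/dtheta
        torque += -m * g * r[0]
    expected = torque / I_hip
    assert qdd[2] == pytest.approx(expected, rel=1e-6)
    assert np.allclose(qdd[[0, 1, 3, 4, 5]], 0.0)


def test_energy_conservation_passive_swing(pm):
    """Unactuated swing with contact disabled conserves mechanical energy
    to better than 0.1% over 1 s at the default integrator resolution."""
    q0, _ = initial_state(pm)
    q = q0.copy()
    qd = np.array([0.0, 0.0, 0.3, -0.5, 0.4, 0.2])
    e0 = skeleton.mechanical_energy(pm, _state(q, qd))

    h = 0.005 / 10
    for _ in range(2000):
        # RK4 on (q, qd) with the pure passive skeleton
        def f(qq, vv):
            return vv, skeleton.forward_dynamics(pm, _state(qq, vv))
        k1q, k1v = f(q, qd)
        k2q, k2v = f(q + 0.5 * h * k1q, qd + 0.5 * h * k1v)
        k3q, k3v = f(q + 0.5 * h * k2q, qd + 0.5 * h * k2v)
        k4q, k4v = f(q + h * k3q, qd + h * k3v)
        q = q + h / 6 * (k1q + 2 * k2q + 2 * k3q + k4q)
        qd = qd + h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
    e1 = skeleton.mechanical_energy(pm, _state(q, qd))
    assert abs(e1 - e0) / abs(e0) < 1e-3


def test_mass_matrix_symmetric_positive_definite(pm, rng):
    for _ in range(10):
        q = rng.normal(0.0, 0.6, 6)
        st = _state(q, rng.normal(0.0, 1.0, 6))
        M = skeleton.mass_matrix(pm, st)
        assert np.allclose(M, M.T, atol=1e-12)
        assert np.linalg.eigvalsh(M).min() > 0.0


def test_gravity_force_matches_potential_gradient(pm, rng):
    """Analytic generalized gravity force equals -dV/dq by central FD."""
    q = rng.normal(0.0, 0.5, 6)
    M, h, Qg = _kernel.mass_bias_grav(q, np.zeros(6), pm.seg, pm.foot_com,
                                      pm.g)
    eps = 1e-6
    for j in range(6):
        qp, qm = q.copy(), q.copy()
        qp[j] += eps
        qm[j] -= eps
        _, pep = _kernel.mech_energy(qp, np.zeros(6), pm.seg, pm.foot_com, pm.g)
        _, pem = _kernel.mech_energy(qm, np.zeros(6), pm.seg, pm.foot_com, pm.g)
        assert Qg[j] == pytest.approx(-(pep - pem) / (2 * eps), abs=1e-4)


def test_com_velocity_matches_finite_difference(pm, rng):
    """COM Jacobian (via the kinetic terms) agrees with a central finite
    difference of the COM position along the state velocity."""
    q = rng.normal(0.0, 0.5, 6)
    qd = rng.normal(0.0, 1.0, 6)
    eps = 1e-6
    cxp, czp, _ = _kernel.com_position(q + eps * qd, pm.seg, pm.foot_com)
    cxm, czm, _ = _kernel.com_position(q - eps * qd, pm.seg, pm.foot_com)
    v_fd = np.array([cxp - cxm, czp - czm]) / (2 * eps)
    # analytic: momentum / mass from the mass matrix row structure
    M, h, Qg = _kernel.mass_bias_grav(q, qd, pm.seg, pm.foot_com, pm.g)
    mtot = pm.total_mass()
    # rows 0 and 1 of M qd are the total linear momentum components
    p = M[:2, :] @ qd
    assert np.allclose(p / mtot, v_fd, atol=1e-5)


def test_compute_com_two_segment_hand_value():
    """Hand-computed mass-weighted average for a simplified mass layout."""
    cfg = ps.ModelConfig()
    for name in ("shank", "foot"):
        cfg.segments[name].mass = 1e-9
    cfg.segments["trunk"].mass = 60.0
    cfg.segments["thigh"].mass = 10.0
    pm2 = ps.pack_model(cfg)
    q = np.zeros(6)
    q[1] = 1.0
    cx, cz = skeleton.compute_com(pm2, _state(q))
    ct = cfg.segments["trunk"].com_offset
    cth = cfg.segments["thigh"].com_offset
    m_tr, m_th = 60.0, 2 * 10.0
    cz_hand = (m_tr * (1.0 + ct) + m_th * (1.0 - cth)) / (m_tr + m_th)
    assert cz == pytest.approx(cz_hand, abs=1e-9)
    assert cx == pytest.approx(0.0, abs=1e-9)


def test_com_invariant_under_uniform_mass_scaling(model_config):
    cfg = ps.ModelConfig()
    for s in cfg.segments.values():
        s.mass *= 2.0
    pm2 = ps.pack_model(cfg)
    pm1 = ps.pack_model(ps.ModelConfig())
    q = np.array([0.1, 1.0, -0.2, 0.3, -0.3, 0.1])
    assert skeleton.compute_com(pm1, _state(q)) == pytest.approx(
        skeleton.compute_com(pm2, _state(q)))


def test_head_kinematics_static_and_translation(pm):
    q0, _ = initial_state(pm)
    hs = skeleton.head_kinematics(pm, _state(q0))
    assert hs.xdot == 0.0 and hs.xddot == 0.0 and hs.phiddot == 0.0
    # pure pelvis translation at constant velocity
    qd = np.array([0.7, 0.0, 0.0, 0.0, 0.0, 0.0])
    hs = skeleton.head_kinematics(pm, _state(q0, qd))
    assert hs.xdot == pytest.approx(0.7)
    assert hs.phi == pytest.approx(float(np.degrees(q0[2])))


def test_head_speed_under_rigid_rotation_about_ankle(pm):
    """Locked body rotating about the ankle at rate w: the head's AP
    velocity equals -w times its height above the (stationary) ankle."""
    q0, _ = initial_state(pm)
    hip, knee, ankle, compos, eps = skeleton.fk_points(pm, _state(q0))
    w = 0.8
    qd = np.zeros(6)
    qd[0] = -w * (hip[1] - ankle[1])
    qd[1] = w * (hip[0] - ankle[0])
    qd[2] = w
    hs = skeleton.head_kinematics(pm, _state(q0, qd))
    head_z = hip[1] + pm.head_h * math.cos(q0[2])
    assert hs.xdot == pytest.approx(-w * (head_z - ankle[1]), rel=1e-6)


def test_mirror_symmetry_of_accelerations(rng):
    """Reflecting the model and state about the frontal plane mirrors the
    accelerations (x-translation and all angles negate)."""
    cfg = ps.ModelConfig()
    pm1 = ps.pack_model(cfg)
    cfgm = ps.ModelConfig()
    cfgm.foot_com = (-cfg.foot_com[0], cfg.foot_com[1])
    for s, sm in zip(cfg.spheres, cfgm.spheres):
        sm.offset = (-s.offset[0], s.offset[1])
    pm2 = ps.pack_model(cfgm)

    mirror = np.array([-1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
    for _ in range(5):
        q = rng.normal(0.0, 0.4, 6)
        qd = rng.normal(0.0, 0.8, 6)
        tau = rng.normal(0.0, 10.0, 6)
        qdd = skeleton.forward_dynamics(pm1, _state(q, qd), joint_torques=tau)
        qdd_m = skeleton.forward_dynamics(
            pm2, _state(mirror * q, mirror * qd), joint_torques=mirror * tau)
        assert np.allclose(qdd_m, mirror * qdd, atol=1e-9)


def test_forward_dynamics_rejects_nonfinite_state(pm):
    q = np.zeros(6)
    q[0] = np.nan
    with pytest.raises(ValueError):
        skeleton.forward_dynamics(pm, _state(q))


def test_segment_params_invariants():
    with pytest.raises(ValueError):
        ps.SegmentParams("bad", mass=-1.0, length=0.4, com_offset=0.1,
                         inertia=0.1).validate()
    with pytest.raises(ValueError):
        ps.SegmentParams("bad", mass=1.0, length=0.4, com_offset=0.5,
                         inertia=0.1).validate()
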