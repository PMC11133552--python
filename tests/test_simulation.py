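"""Closed-loop simulation: falls, contracts, determinism, causality,
mirror symmetry and settled ground-reaction forces."""

import copy

import numpy as np
import pytest

import posturesim as ps
from posturesim.params import MUSCLES
from posturesim.perturbation import PlatformSignal, Scenario
from posturesim.simulation import detect_fall

TOY = ("hip", "knee")   # ankle-strategy variant used for standing checks


def test_detect_fall_threshold():
    assert not detect_fall(0.61, 1.0)
    assert detect_fall(0.59, 1.0)
    assert not detect_fall(1.0, 1.0)


def test_zero_controller_falls(pm):
    """With all gains and feedforward zero the skeleton collapses: standing
    is produced by the controller, not by the passive dynamics."""
    sim = ps.SimConfig(duration=75.0)
    sim.noise = ps.NoiseModel(base=0.0, slope=0.0)
    traj = ps.run_simulation(pm, ps.ControllerParams.zero(),
                             ps.quiet_scenario(75.0), sim)
    assert traj.fall_time is not None
    assert traj.fall_time < 75.0
    assert np.all(traj.u == 0.0)


def test_excitations_and_activations_bounded(pm, standing_guess):
    sim = ps.SimConfig(duration=5.0, noise_seed=3)
    traj = ps.run_simulation(pm, standing_guess, ps.quiet_scenario(5.0), sim,
                             locked_coords=TOY)
    assert np.all((traj.u >= 0.0) & (traj.u <= 1.0))
    assert np.all((traj.a >= 0.0) & (traj.a <= 1.0))


def test_bit_identical_reproducibility(pm, standing_guess):
    sim = ps.SimConfig(duration=3.0, noise_seed=9)
    t1 = ps.run_simulation(pm, standing_guess, ps.quiet_scenario(3.0), sim)
    t2 = ps.run_simulation(pm, standing_guess, ps.quiet_scenario(3.0), sim)
    for f in ("q", "qd", "u", "a", "grf", "cop", "com", "head"):
        assert np.array_equal(getattr(t1, f), getattr(t2, f))
    sim2 = ps.SimConfig(duration=3.0, noise_seed=10)
    t3 = ps.run_simulation(pm, standing_guess, ps.quiet_scenario(3.0), sim2)
    assert not np.array_equal(t1.u, t3.u)


def test_settled_quiet_standing_grf_matches_weight(pm, standing_guess):
    """During settled quiet standing the mean vertical GRF is the body
    weight to within 2%."""
    sim = ps.SimConfig(duration=10.0)
    traj = ps.run_simulation(pm, standing_guess, ps.quiet_scenario(10.0),
                             sim, locked_coords=TOY)
    assert traj.fall_time is None
    settled = traj.t >= 5.0
    assert traj.grf[settled, 1].mean() == pytest.approx(
        pm.total_mass() * pm.g, rel=0.02)


def test_causality_future_platform_does_not_affect_past(pm, standing_guess):
    """Two runs whose platform signals agree up to t* produce identical
    trajectories up to t*: the controller uses no future information."""
    sim = ps.SimConfig(duration=4.0, noise_seed=1)
    n = sim.n_steps
    t = np.arange(n + 1) * sim.dt
    tstar = 2.0
    k = int(tstar / sim.dt)
    pos1 = np.zeros(n + 1)
    vel1 = np.zeros(n)
    pos2, vel2 = pos1.copy(), vel1.copy()
    vel2[k:] = 0.2
    pos2[k + 1:] = np.cumsum(vel2[k:]) * sim.dt
    s1 = Scenario("a", PlatformSignal(t, pos1, vel1, sim.control_rate))
    s2 = Scenario("b", PlatformSignal(t, pos2, vel2, sim.control_rate))
    t1 = ps.run_simulation(pm, standing_guess, s1, sim, locked_coords=TOY)
    t2 = ps.run_simulation(pm, standing_guess, s2, sim, locked_coords=TOY)
    assert np.array_equal(t1.q[:k + 1], t2.q[:k + 1])
    assert np.array_equal(t1.u[:k], t2.u[:k])
    assert not np.array_equal(t1.q[k + 1:], t2.q[k + 1:])


def _mirror_setup(params):
    """Mirror the model geometry and controller about the frontal plane."""
    cfg = ps.ModelConfig()
    cfg.foot_com = (-cfg.foot_com[0], cfg.foot_com[1])
    for s in cfg.spheres:
        s.offset = (-s.offset[0], s.offset[1])
    for m in cfg.muscles.values():
        m.moment_arms = {j: (-r0, -r1) for j, (r0, r1) in m.moment_arms.items()}
    cfg.reference_pose_deg = tuple(-a for a in cfg.reference_pose_deg)
    cfg.joint_stop_deg = {j: (-hi, -lo)
                          for j, (lo, hi) in cfg.joint_stop_deg.items()}
    p = copy.deepcopy(params)
    for m in MUSCLES:
        g = p.gains[m]
        for f in ("k_cop", "k_xddot", "k_phi", "k_phiddot", "k_x", "k_xdot"):
            setattr(g, f, -getattr(g, f))
    return ps.pack_model(cfg), p


def test_mirrored_world_gives_mirrored_trajectory(pm, standing_guess):
    """Reflecting geometry, controller signs and initial posture about the
    frontal plane mirrors the whole trajectory (noise disabled)."""
    sim = ps.SimConfig(duration=3.0)
    sim.noise = ps.NoiseModel(base=0.0, slope=0.0)
    t1 = ps.run_simulation(pm, standing_guess, ps.quiet_scenario(3.0), sim,
                           locked_coords=TOY)
    pm_m, params_m = _mirror_setup(standing_guess)
    t2 = ps.run_simulation(pm_m, params_m, ps.quiet_scenario(3.0), sim,
                           locked_coords=TOY)
    mirror = np.array([-1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
    assert t1.fall_flag == t2.fall_flag
    assert np.allclose(t2.q, t1.q * mirror, atol=1e-9)
    assert np.allclose(t2.u, t1.u, atol=1e-9)


def test_trajectory_frame_and_roundtrip(pm, standing_guess, tmp_path):
    sim = ps.SimConfig(duration=1.0)
    traj = ps.run_simulation(pm, standing_guess, ps.quiet_scenario(1.0), sim,
                             locked_coords=TOY)
    df = traj.to_frame()
    assert len(df) == traj.n
    assert "ankle_deg" in df.columns and "cop_x" in df.columns
    path = tmp_path / "traj.tsv"
    traj.save(path)
    import pandas as pd
    back = pd.read_csv(path, sep="\t")
    assert np.allclose(back["ankle_deg"], df["ankle_deg"], atol=1e-8)


def test_diverging_run_is_flagged(pm):
    """A controller driving the model to divergence is recorded as a fall
    with the distinct non-finite flag or a plain fall, never silently."""
    sim = ps.SimConfig(duration=5.0, substeps=1)  # coarse on purpose
    p = ps.ControllerParams.zero()
    traj = ps.run_simulation(pm, p, ps.quiet_scenario(5.0), sim)
    assert traj.fall_flag in (1, 2)
    assert traj.fall_time is not None or traj.fall_flag == 2
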