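"""Deterministic synthetic fixtures for tests and worked examples.

These construct small synthetic :class:`Trajectory` objects (not simulator
output) with analytically known properties: a falling COM, joint-limit
violations, and sinusoidal reference series with known ROM/RMSE.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ReferenceSeries
from .params import deg2rad
from .simulation import Trajectory


def _base_trajectory(duration=10.0, rate=200.0, hip_deg=20.0, knee_deg=-15.0,
                     com_height=0.95, activations=0.0) -> Trajectory:
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    q = np.zeros((n, 6))
    q[:, 1] = 0.9
    q[:, 2] = deg2rad(-10.0)
    q[:, 3] = deg2rad(hip_deg)
    q[:, 4] = deg2rad(knee_deg)
    q[:, 5] = deg2rad(10.0)
    com = np.zeros((n, 2))
    com[:, 1] = com_height
    a = np.full((n, 9), float(activations))
    zeros9 = np.zeros((n, 9))
    return Trajectory(
        t=t, q=q, qd=np.zeros((n, 6)), u=a.copy(), a=a,
        lm=np.ones((n, 9)), lmd=zeros9.copy(), fm=zeros9.copy(),
        grf=np.zeros((n, 2)), cop=np.zeros(n),
        cop_valid=np.ones(n, dtype=bool), sphere_forces=np.zeros((n, 2)),
        com=com, head=np.zeros((n, 5)), platform=np.zeros(n),
        dt=1.0 / rate, eval_start=0.0)


def fallen_trajectory(duration=10.0, rate=200.0) -> Trajectory:
    """Synthetic trajectory whose COM sinks below 60% of its initial height
    midway; zero activations; knee and hip inside their limit ranges."""
    traj = _base_trajectory(duration, rate)
    n = traj.n
    drop = np.linspace(1.0, 0.5, n)
    traj.com[:, 1] = traj.com[0, 1] * drop
    fall = np.argmax(drop < 0.6)
    traj.fall_time = float(traj.t[fall])
    traj.fall_flag = 1
    return traj


def knee_violation_trajectory(duration=10.0, rate=200.0,
                              knee_deg=10.0) -> Trajectory:
    """Standing trajectory with the knee fixed outside (-30, 0) deg for the
    whole window while the hip stays inside its range."""
    return _base_trajectory(duration, rate, knee_deg=knee_deg)


def hip_violation_trajectory(duration=10.0, rate=200.0,
                             hip_deg=50.0) -> Trajectory:
    """Standing trajectory with hip flexion fixed outside (-20, 40) deg for
    the whole window while the knee stays inside its range."""
    return _base_trajectory(duration, rate, hip_deg=hip_deg)


def half_window_knee_violation(duration=10.0, rate=200.0) -> Trajectory:
    """Knee outside its limits for exactly the second half of the samples."""
    traj = _base_trajectory(duration, rate)
    n = traj.n
    traj.q[n // 2:, 4] = deg2rad(10.0)
    return traj


def sine_reference(amplitude_deg=2.0, period=5.0, duration=20.0,
                   rate=100.0, mean_deg=5.0) -> ReferenceSeries:
    """Sinusoidal joint-angle reference with ROM exactly 2*amplitude."""
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    w = 2.0 * np.pi / period
    chan = {name: mean_deg + amplitude_deg * np.sin(w * t + k)
            for k, name in enumerate(("pelvis_tilt", "hip", "knee", "ankle"))}
    return ReferenceSeries(t, chan, provenance="synthetic sine fixture")


def make_fixtures(seed: int = 0) -> dict:
    """All standard fixtures, keyed by name.  Deterministic in ``seed``
    (the sine phase jitter is the only random element)."""
    rng = np.random.default_rng(seed)
    period = 4.0 + rng.uniform(0.0, 2.0)
    return {
        "fallen": fallen_trajectory(),
        "knee_violation": knee_violation_trajectory(),
        "hip_violation": hip_violation_trajectory(),
        "half_window_knee": half_window_knee_violation(),
        "sine_reference": sine_reference(period=period),
    }
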