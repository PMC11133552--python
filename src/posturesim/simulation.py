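"""Closed-loop single-shooting simulation.

Integrates skeleton + muscles + contact under the delayed-feedback
controller for a scenario, producing a :class:`Trajectory`; detects falls
(COM below a fraction of its initial height) and terminates early.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel
from .controller import delay_steps
from .model import PackedModel, initial_state, pack_model
from .params import (GAIN_FIELDS, MUSCLES, ControllerParams, ModelConfig,
                     SimConfig, deg2rad, rad2deg)
from .perturbation import Scenario, quiet_scenario
from .skeleton import COORDS, locked_mask


@dataclass
class Trajectory:
    """Time-indexed record of one simulation at the 200 Hz control grid.

    Angles and head orientation are stored in radians; ``to_frame`` exports
    degrees.  For fallen runs the arrays cover only the realized portion.
    """

    t: np.ndarray               # (n,)
    q: np.ndarray               # (n, 6)
    qd: np.ndarray              # (n, 6)
    u: np.ndarray               # (n, 9) excitations
    a: np.ndarray               # (n, 9) activations
    lm: np.ndarray              # (n, 9) normalized fiber lengths
    lmd: np.ndarray             # (n, 9) normalized velocities
    fm: np.ndarray              # (n, 9) normalized forces
    grf: np.ndarray             # (n, 2) total ground reaction (fx, fz)
    cop: np.ndarray             # (n,) world AP COP
    cop_valid: np.ndarray       # (n,) bool
    sphere_forces: np.ndarray   # (n, 2) heel/forefoot normal force, one foot
    com: np.ndarray             # (n, 2)
    head: np.ndarray            # (n, 5) x, xdot, xddot, phi, phiddot (SI/rad)
    platform: np.ndarray        # (n,) platform position
    fall_time: Optional[float] = None
    fall_flag: int = 0          # 0 completed, 1 COM fell, 2 diverged
    dt: float = 0.005
    eval_start: float = 15.0

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1]) if self.n else 0.0

    @property
    def fell(self) -> bool:
        return self.fall_flag != 0

    def angles_deg(self) -> np.ndarray:
        """(n, 4) pelvis tilt, hip, knee, ankle in degrees."""
        return rad2deg(self.q[:, 2:6])

    def window_mask(self, start: Optional[float] = None,
                    end: Optional[float] = None) -> np.ndarray:
        start = self.eval_start if start is None else start
        end = self.t[-1] if end is None else end
        return (self.t >= start - 1e-12) & (self.t <= end + 1e-12)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.t}
        for j, name in enumerate(COORDS):
            if j < 2:
                cols[name] = self.q[:, j]
                cols[name + "_vel"] = self.qd[:, j]
            else:
                cols[name + "_deg"] = rad2deg(self.q[:, j])
                cols[name + "_vel_deg"] = rad2deg(self.qd[:, j])
        cols["com_x"] = self.com[:, 0]
        cols["com_z"] = self.com[:, 1]
        for k, nm in enumerate(("head_x", "head_xdot", "head_xddot")):
            cols[nm] = self.head[:, k]
        cols["head_phi_deg"] = rad2deg(self.head[:, 3])
        cols["head_phiddot_deg"] = rad2deg(self.head[:, 4])
        cols["grf_x"] = self.grf[:, 0]
        cols["grf_z"] = self.grf[:, 1]
        cols["cop_x"] = self.cop
        cols["cop_valid"] = self.cop_valid.astype(int)
        cols["platform_x"] = self.platform
        for i, m in enumerate(MUSCLES):
            cols[f"u_{m}"] = self.u[:, i]
            cols[f"a_{m}"] = self.a[:, i]
            cols[f"lm_{m}"] = self.lm[:, i]
            cols[f"lmdot_{m}"] = self.lmd[:, i]
            cols[f"fm_{m}"] = self.fm[:, i]
        return pd.DataFrame(cols)

    def save(self, path) -> None:
        """Delimited-text trajectory, one row per control step."""
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.9g")

    def summary(self) -> dict:
        return {
            "duration_s": self.duration,
            "fall_time_s": self.fall_time,
            "fall_flag": int(self.fall_flag),
            "mean_grf_z": float(self.grf[:, 1].mean()) if self.n else 0.0,
        }


def detect_fall(com_height: float, initial_com_height: float,
                fraction: float = 0.6) -> bool:
    """True iff the COM has dropped below ``fraction`` of its initial height."""
    return bool(com_height < fraction * initial_com_height)


def _resolve_refs(pm: PackedModel, params: ControllerParams,
                  q0: np.ndarray) -> np.ndarray:
    """(x_cop0, phi0 [rad], x0) with None fields taken from the initial state.

    The COP feedback signal is foot-relative (midpoint between the heel and
    forefoot contact points maps to 0), so the default reference is 0.
    """
    x_cop0 = 0.0 if params.x_cop0 is None else float(params.x_cop0)
    if params.phi0_deg is None:
        phi0 = float(q0[2])
    else:
        phi0 = float(deg2rad(params.phi0_deg))
    if params.x0 is None:
        x0, _, _, _, _ = _kernel.head_state(q0, np.zeros(6), np.zeros(6),
                                            pm.head_h)
    else:
        x0 = float(params.x0)
    return np.array([x_cop0, phi0, x0])


def _pack_gains(params: ControllerParams) -> tuple[np.ndarray, np.ndarray]:
    gains = np.zeros((len(MUSCLES), 10))
    lm0 = np.zeros(len(MUSCLES))
    for i, m in enumerate(MUSCLES):
        g = params.gains[m]
        vec = g.as_vector()
        gains[i, :] = vec[:10]
        lm0[i] = vec[10]
    return gains, lm0


def run_simulation(model, controller_params: ControllerParams,
                   scenario: Optional[Scenario] = None,
                   sim_config: Optional[SimConfig] = None,
                   locked_coords: tuple[str, ...] = ()) -> Trajectory:
    """Forward-simulate the standing task under the feedback controller.

    Fully reproducible given ``sim_config.noise_seed`` and the scenario
    seed.  Stops at the configured duration or at the first fall; a
    diverging (non-finite) state is recorded as a fall with flag 2.
    """
    pm = model if isinstance(model, PackedModel) else pack_model(model)
    sim = sim_config or SimConfig()
    sim.validate()
    scenario = scenario or quiet_scenario(sim.duration)

    n = min(sim.n_steps, len(scenario.signal.vel))
    plat_pos = scenario.signal.pos[:n + 1].astype(float)
    plat_vel = scenario.signal.vel[:n].astype(float)

    q0, qd0 = initial_state(pm, sim.initial_posture_deg,
                            sim.settle_penetration)
    gains, lm0 = _pack_gains(controller_params)
    a0 = np.clip(gains[:, 0], 0.0, 1.0)
    refs = _resolve_refs(pm, controller_params, q0)
    delays = delay_steps(sim.dt)
    noise_par = np.array([sim.noise.base, sim.noise.slope])

    rng = np.random.default_rng(sim.noise_seed)
    if sim.noise.base == 0.0 and sim.noise.slope == 0.0:
        noise_sens = np.zeros((n, _kernel.N_CHANNELS))
        noise_act = np.zeros((n, _kernel.N_MUSCLES))
    else:
        noise_sens = rng.standard_normal((n, _kernel.N_CHANNELS))
        noise_act = rng.standard_normal((n, _kernel.N_MUSCLES))

    nm = _kernel.N_MUSCLES
    out_q = np.zeros((n + 1, 6))
    out_qd = np.zeros((n + 1, 6))
    out_u = np.zeros((n + 1, nm))
    out_a = np.zeros((n + 1, nm))
    out_lm = np.zeros((n + 1, nm))
    out_lmd = np.zeros((n + 1, nm))
    out_fm = np.zeros((n + 1, nm))
    out_grf = np.zeros((n + 1, 2))
    out_cop = np.zeros(n + 1)
    out_copv = np.zeros(n + 1)
    out_fns = np.zeros((n + 1, 2))
    out_com = np.zeros((n + 1, 2))
    out_head = np.zeros((n + 1, 5))

    fall_step, fall_flag = _kernel.run_loop(
        q0, qd0, a0,
        pm.seg, pm.foot_com, pm.g, pm.head_h,
        pm.sph_off, pm.sph_r, pm.sph_par, pm.vreg, pm.min_force,
        pm.fmax, pm.lopt, pm.vmax, pm.lmref, pm.tact, pm.tdeact,
        pm.r0, pm.r1, pm.qref, pm.curve, pm.jlim, pm.jstop,
        gains, lm0, refs, delays, noise_par,
        noise_sens, noise_act, plat_pos, plat_vel,
        sim.dt, sim.substeps, n, sim.fall_fraction,
        locked_mask(locked_coords),
        out_q, out_qd, out_u, out_a, out_lm, out_lmd, out_fm,
        out_grf, out_cop, out_copv, out_fns, out_com, out_head)

    if fall_flag == 0:
        nrec = n + 1
        fall_time = None
    elif fall_flag == 1:
        nrec = fall_step + 1
        fall_time = fall_step * sim.dt
    else:
        nrec = max(fall_step, 1)
        fall_time = fall_step * sim.dt

    sl = slice(0, nrec)
    t = np.arange(nrec) * sim.dt
    return Trajectory(
        t=t, q=out_q[sl], qd=out_qd[sl], u=out_u[sl], a=out_a[sl],
        lm=out_lm[sl], lmd=out_lmd[sl], fm=out_fm[sl],
        grf=out_grf[sl], cop=out_cop[sl],
        cop_valid=out_copv[sl].astype(bool), sphere_forces=out_fns[sl],
        com=out_com[sl], head=out_head[sl], platform=plat_pos[sl],
        fall_time=fall_time, fall_flag=fall_flag, dt=sim.dt,
        eval_start=sim.eval_start)
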