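"""Controller parameter search: CMA-ES over the feedback gains, offsets and
feedforward excitations, minimizing a composite effort / fall / joint-limit
cost evaluated by single shooting.

Cost:  J = 100 J_fall + 0.01 J_effort + 10 J_knee + 0.1 J_hip with
J_fall in {0,1} (COM below 60% of its initial height), J_effort the
time-averaged sum of cubed activations over all 18 muscles, and the joint
terms the fraction of the costed window spent outside the knee (-30, 0)
deg / hip (-20, 40) deg ranges (the binary limit indicators of the cost
definition, time-averaged so the optimizer sees a graded signal).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cmaes import CMAES
from .params import (GAIN_FIELDS, MUSCLES, ControllerParams, CostBreakdown,
                     ModelConfig, MuscleGains, OptConfig, SimConfig,
                     gain_bounds, rad2deg)
from .model import PackedModel, pack_model
from .perturbation import Scenario, quiet_scenario
from .simulation import Trajectory, run_simulation

log = logging.getLogger(__name__)

KNEE_LIMITS_DEG = (-30.0, 0.0)
HIP_LIMITS_DEG = (-20.0, 40.0)

#: number of muscles entering the effort cost (both legs)
N_MUSC_TOTAL = 18


# ---------------------------------------------------------------------------
# cost terms
# ---------------------------------------------------------------------------

def effort_cost(traj: Trajectory, window=(0.0, None)) -> float:
    """Time-averaged cubed-activation effort over all 18 muscles."""
    mask = traj.window_mask(window[0], window[1])
    t = traj.t[mask]
    if len(t) < 2:
        return 0.0
    integrand = 2.0 * np.sum(traj.a[mask] ** 3, axis=1)  # 9 pairs -> 18
    total = np.trapezoid(integrand, t)
    return float(total / (t[-1] - t[0]))


def joint_limit_costs(traj: Trajectory, window=(0.0, None)) -> tuple[float, float]:
    """Fraction of the costed window with knee outside (-30, 0) deg and hip
    outside (-20, 40) deg.  0 when always inside, 1 when outside throughout."""
    mask = traj.window_mask(window[0], window[1])
    hip = rad2deg(traj.q[mask, 3])
    knee = rad2deg(traj.q[mask, 4])
    if len(hip) == 0:
        return 0.0, 0.0
    knee_out = (knee <= KNEE_LIMITS_DEG[0]) | (knee >= KNEE_LIMITS_DEG[1])
    hip_out = (hip <= HIP_LIMITS_DEG[0]) | (hip >= HIP_LIMITS_DEG[1])
    return float(knee_out.mean()), float(hip_out.mean())


def fall_cost(traj: Trajectory, fraction: float = 0.6) -> float:
    """1 if the COM ever dropped below ``fraction`` of its initial height."""
    if traj.fell:
        return 1.0
    com_z = traj.com[:, 1]
    return 1.0 if np.any(com_z < fraction * com_z[0]) else 0.0


def total_cost(traj: Trajectory, window=(0.0, None)) -> CostBreakdown:
    """Composite cost breakdown for one simulated trajectory."""
    j_knee, j_hip = joint_limit_costs(traj, window)
    return CostBreakdown(j_fall=fall_cost(traj),
                         j_effort=effort_cost(traj, window),
                         j_knee=j_knee, j_hip=j_hip)


# ---------------------------------------------------------------------------
# parameter vector packing
# ---------------------------------------------------------------------------

def _vector_fields(opt: OptConfig):
    return [(m, f) for m in opt.muscles for f in GAIN_FIELDS]


def params_to_vector(params: ControllerParams, opt: OptConfig) -> np.ndarray:
    return np.array([getattr(params.gains[m], f)
                     for m, f in _vector_fields(opt)])


def vector_to_params(x: np.ndarray, opt: OptConfig,
                     template: Optional[ControllerParams] = None
                     ) -> ControllerParams:
    params = copy.deepcopy(template) if template else ControllerParams()
    for (m, f), v in zip(_vector_fields(opt), x):
        setattr(params.gains[m], f, float(v))
    return params


def vector_bounds(opt: OptConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for m, f in _vector_fields(opt):
        b = gain_bounds(f)
        lo.append(b[0])
        hi.append(b[1])
    return np.array(lo), np.array(hi)


# ---------------------------------------------------------------------------
# initial guess
# ---------------------------------------------------------------------------

def static_feedforward(model, posture_deg=None, ridge: float = 20.0,
                       clip_bounds: bool = True) -> np.ndarray:
    """Per-muscle feedforward excitations balancing gravity at a posture.

    Solves the joint torques required for zero hip/knee/ankle acceleration
    at the settled initial state and distributes them over the muscles by
    non-negative least squares (a small ridge spreads the load over
    synergists).  Returns activations clipped to the feedforward bounds;
    at steady state activation equals excitation, so these serve as u0.
    """
    from scipy.optimize import nnls

    from . import _kernel
    from .model import initial_state

    pm = model if isinstance(model, PackedModel) else pack_model(model)
    q0, qd0 = initial_state(pm, posture_deg)
    M, h, Qg = _kernel.mass_bias_grav(q0, qd0, pm.seg, pm.foot_com, pm.g)
    res = _kernel.contact_terms(q0, qd0, pm.seg, pm.foot_com, pm.sph_off,
                                pm.sph_r, pm.sph_par, pm.vreg, pm.min_force,
                                0.0)
    tau_req = -(Qg + res[0])[3:6]
    A = (2.0 * pm.r0 * pm.fmax[:, None]).T          # (3, 9), both legs
    A_aug = np.vstack([A, ridge * np.eye(len(MUSCLES))])
    b_aug = np.concatenate([tau_req, np.zeros(len(MUSCLES))])
    u0, _ = nnls(A_aug, b_aug)
    if clip_bounds:
        lo, hi = gain_bounds("u0")
        u0 = np.clip(u0, lo, hi)
    return u0


def initial_guess(model, opt: Optional[OptConfig] = None) -> ControllerParams:
    """Physiologically motivated starting controller.

    Per-modality feedback weights follow the 50:33:17 proprioceptive :
    visual : vestibular weighting of healthy sensory integration, applied
    as scale factors on each modality's gains (the visual gains split the
    modality weight between position and velocity; within-modality
    derivative/force channels get fixed fractions of the lead gain).
    Signs are set so each pathway opposes the sway it senses: stretch
    reflexes are positive, and the COP / head-sway channels excite the
    muscles whose joint torque pushes the body back (the sign of the
    muscle's net moment arm).  CMA-ES refines from here.
    """
    pm = model if isinstance(model, PackedModel) else pack_model(model)
    opt = opt or OptConfig()
    b = opt.guess_base
    w_som, w_vis, w_ves = opt.weight_som, opt.weight_vis, opt.weight_ves
    u0 = static_feedforward(pm)
    params = ControllerParams()
    for i, m in enumerate(MUSCLES):
        net_arm = float(np.sum(pm.r0[i]))
        stab = -np.sign(net_arm) if net_arm != 0.0 else 1.0
        g = MuscleGains(
            u0=float(u0[i]),
            k_l=w_som * b,
            k_ldot=0.2 * w_som * b,
            k_f=0.02 * w_som * b,
            k_cop=0.35 * w_som * b * stab,
            k_xddot=0.01 * w_ves * b * stab,
            k_phi=-w_ves * b * stab,
            k_phiddot=-0.002 * w_ves * b * stab,
            k_x=0.5 * w_vis * b * stab,
            k_xdot=0.5 * w_vis * b * stab,
            lm0=0.995,
        )
        params.gains[m] = g
    params.validate()
    return params


# ---------------------------------------------------------------------------
# CMA-ES single shooting
# ---------------------------------------------------------------------------

@dataclass
class OptResult:
    params: ControllerParams
    cost: float
    breakdown: CostBreakdown
    trace: pd.DataFrame
    seed: int
    stopped: str = ""


def optimize(model, scenario: Optional[Scenario] = None,
             opt_config: Optional[OptConfig] = None,
             seed: int = 0,
             sim_config: Optional[SimConfig] = None,
             x0: Optional[ControllerParams] = None,
             locked_coords: tuple[str, ...] = ()) -> OptResult:
    """One CMA-ES run in the normalized [0,1]^n parameter box.

    Each candidate is scored by a full forward simulation; within a
    generation all candidates share one noise seed so ranking reflects the
    parameters, not the noise realization.  Terminates when the mean
    best-cost improvement over ``stop_window`` generations falls below
    ``stop_tol``, or at the generation cap.
    """
    pm = model if isinstance(model, PackedModel) else pack_model(model)
    opt = opt_config or OptConfig()
    opt.validate()
    sim = copy.deepcopy(sim_config) if sim_config else SimConfig()
    if opt.horizon is not None:
        sim.duration = opt.horizon
    scenario = scenario or quiet_scenario(sim.duration)

    guess = x0 or initial_guess(pm, opt)
    lo, hi = vector_bounds(opt)
    z0 = (params_to_vector(guess, opt) - lo) / (hi - lo)
    es = CMAES(z0, opt.sigma0, popsize=opt.popsize, seed=seed)

    def evaluate(z, noise_seed):
        z = np.clip(z, 0.0, 1.0)
        cand = vector_to_params(lo + z * (hi - lo), opt, template=guess)
        sim.noise_seed = noise_seed
        traj = run_simulation(pm, cand, scenario, sim,
                              locked_coords=locked_coords)
        cost = total_cost(traj).total
        if not np.isfinite(cost):
            log.warning("non-finite cost replaced by penalty")
            cost = 1e6
        return cost

    best_hist: list[float] = []
    rows = []
    stopped = "max_generations"
    rng = np.random.default_rng(seed)
    best_z = np.clip(z0, 0.0, 1.0)
    best_cost = evaluate(best_z, int(rng.integers(2 ** 31)))
    for gen in range(opt.max_generations):
        gen_noise_seed = int(rng.integers(2 ** 31))
        Z = es.ask()
        f = np.array([evaluate(z, gen_noise_seed) for z in Z])
        es.tell(Z, f)
        if es.best_f < best_cost:
            best_cost = float(es.best_f)
            best_z = np.clip(es.best_x, 0.0, 1.0)
        best_hist.append(best_cost)
        rows.append((gen, best_cost, float(f.mean()), float(f.min()),
                     es.sigma))
        if len(best_hist) > opt.stop_window:
            drop = (best_hist[-opt.stop_window - 1] - best_hist[-1]) / opt.stop_window
            if drop < opt.stop_tol:
                stopped = "tolerance"
                break

    best_params = vector_to_params(lo + best_z * (hi - lo), opt,
                                   template=guess)
    sim.noise_seed = seed
    traj = run_simulation(pm, best_params, scenario, sim,
                          locked_coords=locked_coords)
    breakdown = total_cost(traj)
    trace = pd.DataFrame(rows, columns=["generation", "best_cost",
                                        "mean_cost", "gen_best_cost",
                                        "sigma"])
    return OptResult(best_params, best_cost, breakdown, trace, seed, stopped)


def multi_seed_optimize(model, scenario: Optional[Scenario] = None,
                        opt_config: Optional[OptConfig] = None,
                        base_seed: int = 0, **kwargs):
    """Independent CMA-ES restarts with different seeds; returns the
    lowest-cost result and all individual results (order-independent)."""
    opt = opt_config or OptConfig()
    results = [optimize(model, scenario, opt, seed=base_seed + i, **kwargs)
               for i in range(opt.n_seeds)]
    best = min(results, key=lambda r: r.cost)
    return best, results
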