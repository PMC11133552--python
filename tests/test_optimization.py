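"""Composite cost function, CMA-ES machinery and the single-shooting
parameter search at reduced scale."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import posturesim as ps
from posturesim import fixtures, optimization
from posturesim.cmaes import CMAES
from posturesim.params import GAIN_FIELDS, MUSCLES, CostBreakdown, OptConfig


# -- cost terms --------------------------------------------------------------

def test_effort_cost_constant_activations():
    zero = fixtures._base_trajectory(activations=0.0)
    assert optimization.effort_cost(zero) == pytest.approx(0.0)
    full = fixtures._base_trajectory(activations=1.0)
    assert optimization.effort_cost(full) == pytest.approx(18.0, abs=1e-12)
    half = fixtures._base_trajectory(activations=0.5)
    assert optimization.effort_cost(half) == pytest.approx(2.25, abs=1e-12)


def test_joint_limit_costs_inside_outside():
    inside = fixtures._base_trajectory(knee_deg=-15.0, hip_deg=20.0)
    assert optimization.joint_limit_costs(inside) == (0.0, 0.0)
    hip_out = fixtures.hip_violation_trajectory()
    assert optimization.joint_limit_costs(hip_out) == (0.0, 1.0)
    knee_out = fixtures.knee_violation_trajectory()
    assert optimization.joint_limit_costs(knee_out) == (1.0, 0.0)


def test_joint_limit_half_window():
    traj = fixtures.half_window_knee_violation()
    j_knee, j_hip = optimization.joint_limit_costs(traj)
    assert j_knee == pytest.approx(0.5, abs=1e-3)
    assert j_hip == 0.0


def test_total_cost_weighted_components():
    fall = fixtures.fallen_trajectory()
    assert optimization.total_cost(fall).total == pytest.approx(100.0)
    knee = fixtures.knee_violation_trajectory()
    assert optimization.total_cost(knee).total == pytest.approx(10.0)
    hip = fixtures.hip_violation_trajectory()
    assert optimization.total_cost(hip).total == pytest.approx(0.1)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(jf=st.sampled_from([0.0, 1.0]), je=st.floats(0, 20),
       jk=st.floats(0, 1), jh=st.floats(0, 1))
def test_cost_decomposition_identity(jf, je, jk, jh):
    cb = CostBreakdown(jf, je, jk, jh)
    assert cb.total == 100 * jf + 0.01 * je + 10 * jk + 0.1 * jh


# -- parameter packing -------------------------------------------------------

def test_vector_roundtrip_and_bounds():
    opt = OptConfig()
    p = ps.ControllerParams()
    p.gains["sol"].k_l = 1.25
    v = optimization.params_to_vector(p, opt)
    assert len(v) == 9 * len(GAIN_FIELDS)
    p2 = optimization.vector_to_params(v, opt)
    assert optimization.params_to_vector(p2, opt) == pytest.approx(v)
    lo, hi = optimization.vector_bounds(opt)
    assert np.all(lo < hi)


def test_initial_guess_bounds_and_modality_weighting(pm):
    """Guess respects the optimization bounds and applies the 50:33:17
    proprioceptive:visual:vestibular modality weights as documented (lead
    stretch gain : summed visual gains : orientation gain)."""
    opt = OptConfig()
    g = ps.initial_guess(pm, opt)
    g.validate()     # raises if outside bounds
    for m in MUSCLES:
        mg = g.gains[m]
        w_som = abs(mg.k_l)
        w_vis = abs(mg.k_x) + abs(mg.k_xdot)
        w_ves = abs(mg.k_phi)
        assert w_som / w_vis == pytest.approx(0.50 / 0.33, rel=1e-9)
        assert w_som / w_ves == pytest.approx(0.50 / 0.17, rel=1e-9)


def test_static_feedforward_balances_joint_torques(pm):
    """NNLS feedforward reproduces the required static joint torques."""
    from posturesim import _kernel
    from posturesim.model import initial_state

    u0 = optimization.static_feedforward(pm, ridge=0.0, clip_bounds=False)
    q0, qd0 = initial_state(pm)
    M, h, Qg = _kernel.mass_bias_grav(q0, qd0, pm.seg, pm.foot_com, pm.g)
    res = _kernel.contact_terms(q0, qd0, pm.seg, pm.foot_com, pm.sph_off,
                                pm.sph_r, pm.sph_par, pm.vreg, pm.min_force,
                                0.0)
    tau_req = -(Qg + res[0])[3:6]
    tau_mus = 2.0 * (pm.r0 * pm.fmax[:, None]).T @ u0
    assert tau_mus == pytest.approx(tau_req, abs=1e-6)


# -- CMA-ES ------------------------------------------------------------------

def test_cmaes_minimizes_quadratic():
    rng_target = np.array([0.3, -0.2, 0.5, 0.1, -0.4])
    es = CMAES(np.zeros(5), sigma0=0.3, seed=1)
    for _ in range(200):
        X = es.ask()
        es.tell(X, [np.sum((x - rng_target) ** 2) for x in X])
    assert es.best_f < 1e-8
    assert np.allclose(es.best_x, rng_target, atol=1e-3)


def test_cmaes_deterministic_given_seed():
    def run():
        es = CMAES(np.zeros(3), 0.5, seed=4)
        for _ in range(20):
            X = es.ask()
            es.tell(X, [float(np.sum(x ** 2)) for x in X])
        return es.best_f, es.best_x
    f1, x1 = run()
    f2, x2 = run()
    assert f1 == f2 and np.array_equal(x1, x2)


# -- reduced-scale search ----------------------------------------------------

def _smoke_opt_config():
    return OptConfig(popsize=4, max_generations=3, horizon=3.0,
                     muscles=("gas", "sol", "ta"), n_seeds=2)


def test_optimize_smoke_improves_on_guess(pm):
    """Best-ever cost never exceeds the initial-guess cost, and the
    returned parameters respect the bounds."""
    opt = _smoke_opt_config()
    res = optimization.optimize(pm, opt_config=opt, seed=0,
                                locked_coords=("hip", "knee"))
    # best-ever cost is monotone: never above the first generation's best
    assert res.cost <= res.trace.best_cost.iloc[0] + 1e-12
    assert np.isfinite(res.cost)
    res.params.validate()
    assert len(res.trace) >= 1


def test_multi_seed_returns_best_and_reduces_to_single(pm):
    opt = _smoke_opt_config()
    best, results = optimization.multi_seed_optimize(
        pm, opt_config=opt, base_seed=0, locked_coords=("hip", "knee"))
    assert len(results) == opt.n_seeds
    assert best.cost == min(r.cost for r in results)
    opt1 = _smoke_opt_config()
    opt1.n_seeds = 1
    best1, results1 = optimization.multi_seed_optimize(
        pm, opt_config=opt1, base_seed=0, locked_coords=("hip", "knee"))
    single = optimization.optimize(pm, opt_config=opt1, seed=0,
                                   locked_coords=("hip", "knee"))
    assert best1.cost == single.cost
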