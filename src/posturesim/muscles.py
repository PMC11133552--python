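"""Hill-type musculotendon actuators (rigid tendon).

Nine muscles per leg (GLU, HAM, IL, RECT, BFSH, VAS, GAS, SOL, TA) produce
joint torques and the normalized length / velocity / force signals the
feedback controller consumes.  Musculotendon geometry is defined entirely
by the moment-arm functions: dL/dtheta = -r(theta) holds exactly, so no
separate path-point engine is needed.
"""

from __future__ import annotations

import logging

import numpy as np

from . import _kernel
from .model import PackedModel, pack_model
from .params import MUSCLES

log = logging.getLogger(__name__)


def _packed(model) -> PackedModel:
    return model if isinstance(model, PackedModel) else pack_model(model)


# -- Hill curves -------------------------------------------------------------

def force_length(lm, width=0.45):
    """Active force-length curve, normalized to 1 at optimal length."""
    lm = np.asarray(lm, dtype=float)
    return np.exp(-((lm - 1.0) / width) ** 2)


def force_velocity(lmdot, v_max=10.0, shape=0.25, ecc=1.5):
    """Force-velocity curve: 0 at maximal shortening (-v_max), 1 at rest,
    saturating at the eccentric plateau ``ecc`` for lengthening."""
    v = np.asarray(lmdot, dtype=float)
    out = np.empty_like(v)
    short = v < 0
    out[short] = np.clip((v_max + v[short]) / (v_max - v[short] / shape),
                         0.0, None)
    c = shape * v_max
    out[~short] = ecc - (ecc - 1.0) * c / (c + v[~short])
    return out


def force_passive(lm, width=0.5):
    """Passive elastic curve: zero at and below optimal length."""
    lm = np.asarray(lm, dtype=float)
    return np.where(lm > 1.0, ((lm - 1.0) / width) ** 2, 0.0)


# -- operations --------------------------------------------------------------

def activation_dynamics(u, a, tau_act=0.010, tau_deact=0.040):
    """First-order activation dynamics da/dt.

    Activation rises toward the excitation with time constant ``tau_act``
    and decays with ``tau_deact``.  Inputs outside [0, 1] are clamped with
    a logged warning.
    """
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(u < 0) or np.any(u > 1) or np.any(a < 0) or np.any(a > 1):
        log.warning("activation_dynamics: excitation/activation outside "
                    "[0, 1]; clamping")
        u = np.clip(u, 0.0, 1.0)
        a = np.clip(a, 0.0, 1.0)
    tau = np.where(u >= a, tau_act, tau_deact)
    return (u - a) / tau


def musculotendon_kinematics(model, q, qdot=None):
    """Normalized fiber lengths and lengthening velocities for all muscles.

    ``q``/``qdot`` are the 6 generalized coordinates (radians).  Lengths
    equal each muscle's configured reference normalized length at the
    model's reference posture and integrate -r(theta) over the spanned
    joints away from it.
    """
    pm = _packed(model)
    q = np.asarray(q, dtype=float)
    qdot = np.zeros(6) if qdot is None else np.asarray(qdot, dtype=float)
    lm, lmd = _kernel.muscle_lengths(q, qdot, pm.r0, pm.r1, pm.qref,
                                     pm.lopt, pm.lmref)
    return lm, lmd


def muscle_force(model, a, lm, lmdot):
    """Tendon forces [N] and normalized forces for all muscles."""
    pm = _packed(model)
    F, Fn = _kernel.muscle_forces(np.asarray(a, float), np.asarray(lm, float),
                                  np.asarray(lmdot, float),
                                  pm.fmax, pm.vmax, pm.curve)
    return F, Fn


def joint_torques(model, forces, q):
    """Single-leg joint torques (hip, knee, ankle) from muscle forces.

    tau_j = sum_i r_ij(theta_j) F_i; linear in the forces.  The symmetric
    model applies twice this to the shared joint coordinates.
    """
    pm = _packed(model)
    return _kernel.muscle_joint_torques(np.asarray(forces, float),
                                        np.asarray(q, float), pm.r0, pm.r1)


def muscle_index(name: str) -> int:
    return MUSCLES.index(name)
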