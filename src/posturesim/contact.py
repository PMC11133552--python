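"""Hunt-Crossley sphere-ground contact, ground reaction forces and COP.

Two viscoelastic spheres per foot (heel, forefoot) contact the plane
z = 0, which translates horizontally as the (kinematically prescribed,
infinitely massive) platform.  Horizontal platform motion perturbs the
model through the regularized friction law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .model import PackedModel, pack_model


@dataclass
class PlatformState:
    """Prescribed platform kinematics (anterior-posterior translation)."""

    x_p: float = 0.0    # m
    v_p: float = 0.0    # m/s


@dataclass
class CopRecord:
    """Anterior-posterior COP and the per-sphere normal loads behind it."""

    x_cop: float
    normal_forces: np.ndarray
    valid: bool


def hunt_crossley_normal(delta, delta_dot, stiffness, exponent, damping):
    """Normal force k * d^n * (1 + c * d_dot), zero out of contact and
    clamped at zero (no adhesion)."""
    delta = np.asarray(delta, dtype=float)
    delta_dot = np.asarray(delta_dot, dtype=float)
    f = np.where(delta > 0.0,
                 stiffness * np.abs(delta) ** exponent
                 * (1.0 + damping * delta_dot),
                 0.0)
    return np.clip(f, 0.0, None)


def friction_force(normal, v_rel, mu, v_reg=0.05):
    """Regularized Coulomb friction opposing sliding relative to the platform."""
    return -mu * np.asarray(normal, float) * np.tanh(
        np.asarray(v_rel, float) / v_reg)


def contact_force(delta, delta_dot, v_rel, stiffness=4e5, exponent=1.5,
                  damping=1.0, mu=0.9, v_reg=0.05):
    """(tangential, normal) force on one sphere from its kinematics."""
    fn = hunt_crossley_normal(delta, delta_dot, stiffness, exponent, damping)
    ft = friction_force(fn, v_rel, mu, v_reg)
    return ft, fn


def compute_cop(normal_forces, x_positions, min_force=1.0) -> CopRecord:
    """Normal-force-weighted COP of the loaded contact points.

    Flagged invalid (and excluded from range statistics downstream) when
    the total load does not exceed ``min_force``.
    """
    f = np.asarray(normal_forces, dtype=float)
    x = np.asarray(x_positions, dtype=float)
    total = f.sum()
    if total <= min_force:
        return CopRecord(float("nan"), f, False)
    return CopRecord(float((f * x).sum() / total), f, True)


def ground_reaction(model, q, qd, platform: PlatformState = PlatformState()):
    """Generalized contact force, total GRF, and COP for the current state."""
    pm = model if isinstance(model, PackedModel) else pack_model(model)
    Qc, gx, gz, cop, coprel, valid, fns = _kernel.contact_terms(
        np.asarray(q, float), np.asarray(qd, float), pm.seg, pm.foot_com,
        pm.sph_off, pm.sph_r, pm.sph_par, pm.vreg, pm.min_force,
        platform.v_p)
    return Qc, (gx, gz), CopRecord(cop if valid else float("nan"), fns, valid)
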