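"""Planar rigid-body dynamics of the 7-segment standing model.

The skeleton has three pelvis-ground DOF plus hip/knee/ankle shared by the
two (mirrored) legs, i.e. six effective generalized coordinates.  See
``params`` for the sign conventions; all functions here take radians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .model import PackedModel, pack_model
from .params import ModelConfig, deg2rad, rad2deg

COORDS = ("pelvis_x", "pelvis_z", "pelvis_tilt", "hip", "knee", "ankle")


@dataclass
class GeneralizedState:
    """Generalized coordinates (radians internally) and their rates."""

    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if self.q.shape != (6,) or self.qdot.shape != (6,):
            raise ValueError("GeneralizedState needs 6 coordinates and 6 rates")

    @classmethod
    def from_degrees(cls, pelvis_x, pelvis_z, tilt_deg, hip_deg, knee_deg,
                     ankle_deg, qdot=None):
        q = np.array([pelvis_x, pelvis_z, *deg2rad(
            [tilt_deg, hip_deg, knee_deg, ankle_deg])])
        return cls(q, np.zeros(6) if qdot is None else qdot)

    @property
    def angles_deg(self) -> np.ndarray:
        """Pelvis tilt, hip, knee, ankle in degrees."""
        return rad2deg(self.q[2:6])


@dataclass
class HeadState:
    """Head point kinematics (degrees at this interface)."""

    x: float          # m, anterior-posterior position
    xdot: float       # m/s
    xddot: float      # m/s^2
    phi: float        # deg, orientation
    phiddot: float    # deg/s^2


def _packed(model) -> PackedModel:
    return model if isinstance(model, PackedModel) else pack_model(model)


def locked_mask(locked_coords: Sequence[str]) -> np.ndarray:
    mask = np.zeros(6, dtype=np.bool_)
    for name in locked_coords:
        if name not in COORDS:
            raise ValueError(f"unknown coordinate {name!r}")
        mask[COORDS.index(name)] = True
    return mask


def mass_matrix(model, state: GeneralizedState) -> np.ndarray:
    pm = _packed(model)
    M, h, Qg = _kernel.mass_bias_grav(state.q, state.qdot, pm.seg,
                                      pm.foot_com, pm.g)
    return M


def forward_dynamics(model, state: GeneralizedState,
                     joint_torques: Optional[np.ndarray] = None,
                     contact_wrench: Optional[np.ndarray] = None,
                     platform_velocity: float = 0.0,
                     contact: bool = False,
                     gravity: Optional[float] = None,
                     locked: Sequence[str] = ()) -> np.ndarray:
    """Generalized accelerations under gravity, generalized joint torques,
    an optional externally supplied generalized contact wrench, and (when
    ``contact=True``) the model's own sphere-ground contact.

    ``joint_torques`` is a 6-vector of generalized forces (N or N m per
    coordinate).  Raises on non-finite input or a singular mass matrix.
    """
    pm = _packed(model)
    q, qd = state.q, state.qdot
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd))):
        raise ValueError("non-finite generalized state")
    g = pm.g if gravity is None else gravity
    M, h, Qg = _kernel.mass_bias_grav(q, qd, pm.seg, pm.foot_com, g)
    Q = Qg - h
    if joint_torques is not None:
        tau = np.asarray(joint_torques, dtype=float)
        if tau.shape != (6,):
            raise ValueError("joint_torques must match the 6 DOF")
        Q = Q + tau
    if contact_wrench is not None:
        Q = Q + np.asarray(contact_wrench, dtype=float)
    if contact:
        Qc, gx, gz, cop, coprel, valid, fns = _kernel.contact_terms(
            q, qd, pm.seg, pm.foot_com, pm.sph_off, pm.sph_r, pm.sph_par,
            pm.vreg, pm.min_force, platform_velocity)
        Q = Q + Qc
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("singular mass matrix")
    return _kernel.solve_accels(M, Q, locked_mask(locked))


def compute_com(model, state: GeneralizedState) -> tuple[float, float]:
    """Whole-body center of mass (x, height) [m]."""
    pm = _packed(model)
    cx, cz, mtot = _kernel.com_position(state.q, pm.seg, pm.foot_com)
    return cx, cz


def head_kinematics(model, state: GeneralizedState,
                    accelerations: Optional[np.ndarray] = None) -> HeadState:
    """Head point (fixed on the trunk axis, ``head_height`` above the hip)."""
    pm = _packed(model)
    qdd = np.zeros(6) if accelerations is None else np.asarray(accelerations,
                                                               dtype=float)
    x, xd, xdd, phi, phidd = _kernel.head_state(state.q, state.qdot, qdd,
                                                pm.head_h)
    return HeadState(x, xd, xdd, float(rad2deg(phi)), float(rad2deg(phidd)))


def fk_points(model, state: GeneralizedState):
    """Hip/knee/ankle joint positions, segment COMs and orientations [rad]."""
    pm = _packed(model)
    return _kernel.fk_points(state.q, pm.seg, pm.foot_com)


def mechanical_energy(model, state: GeneralizedState,
                      gravity: Optional[float] = None) -> float:
    """Kinetic plus gravitational potential energy [J]."""
    pm = _packed(model)
    g = pm.g if gravity is None else gravity
    ke, pe = _kernel.mech_energy(state.q, state.qdot, pm.seg, pm.foot_com, g)
    return ke + pe
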