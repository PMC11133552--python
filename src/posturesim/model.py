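"""Packing of :class:`~posturesim.params.ModelConfig` into the flat arrays
consumed by the numba kernels, plus initial-state construction."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .params import JOINTS, MUSCLES, ModelConfig, deg2rad


@dataclass
class PackedModel:
    """Flat-array view of a validated :class:`ModelConfig`."""

    config: ModelConfig
    seg: np.ndarray          # (4,4) mass, com offset, length, inertia
    foot_com: np.ndarray     # (2,)
    sph_off: np.ndarray      # (2,2) heel, forefoot
    sph_r: np.ndarray        # (2,)
    sph_par: np.ndarray      # (2,4) k, n, c, mu
    fmax: np.ndarray
    lopt: np.ndarray
    vmax: np.ndarray
    lmref: np.ndarray
    tact: np.ndarray
    tdeact: np.ndarray
    r0: np.ndarray           # (9,3) constant moment arm term per joint
    r1: np.ndarray           # (9,3) linear moment arm term
    qref: np.ndarray         # (3,) hip/knee/ankle reference angles [rad]
    curve: np.ndarray        # (4,) Hill curve constants
    jlim: np.ndarray         # (3,2) hip/knee/ankle passive stop range [rad]
    jstop: np.ndarray        # (2,) stop stiffness [N m/rad], damping [N m s/rad]

    @property
    def g(self) -> float:
        return self.config.gravity

    @property
    def head_h(self) -> float:
        return self.config.head_height

    @property
    def vreg(self) -> float:
        return self.config.friction_vel

    @property
    def min_force(self) -> float:
        return self.config.cop_min_force

    def total_mass(self) -> float:
        return self.config.total_mass()


def pack_model(config: ModelConfig) -> PackedModel:
    config.validate()
    seg = np.empty((4, 4))
    for i, name in enumerate(("trunk", "thigh", "shank", "foot")):
        s = config.segments[name]
        seg[i] = (s.mass, s.com_offset, s.length, s.inertia)

    spheres = sorted(config.spheres, key=lambda s: 0 if s.site == "heel" else 1)
    sph_off = np.array([s.offset for s in spheres], dtype=float)
    sph_r = np.array([s.radius for s in spheres], dtype=float)
    sph_par = np.array(
        [(s.stiffness, s.exponent, s.damping, s.friction) for s in spheres],
        dtype=float)

    n = len(MUSCLES)
    fmax = np.empty(n)
    lopt = np.empty(n)
    vmax = np.empty(n)
    lmref = np.empty(n)
    tact = np.empty(n)
    tdeact = np.empty(n)
    r0 = np.zeros((n, 3))
    r1 = np.zeros((n, 3))
    for i, name in enumerate(MUSCLES):
        m = config.muscles[name]
        fmax[i] = m.f_max
        lopt[i] = m.l_opt
        vmax[i] = m.v_max
        lmref[i] = m.lm_ref
        tact[i] = m.tau_act
        tdeact[i] = m.tau_deact
        for j, joint in enumerate(JOINTS):
            if joint in m.moment_arms:
                r0[i, j], r1[i, j] = m.moment_arms[joint]

    qref = deg2rad(np.asarray(config.reference_pose_deg[1:], dtype=float))
    curve = np.array([config.fl_width, config.fv_ecc,
                      config.fv_shape, config.fp_width])
    jlim = np.empty((3, 2))
    for j, joint in enumerate(JOINTS):
        lo, hi = config.joint_stop_deg[joint]
        jlim[j] = deg2rad(np.array([lo, hi]))
    jstop = np.array([config.joint_stop_stiffness, config.joint_stop_damping])
    return PackedModel(config, seg, np.asarray(config.foot_com, float),
                       sph_off, sph_r, sph_par, fmax, lopt, vmax, lmref,
                       tact, tdeact, r0, r1, qref, curve, jlim, jstop)


def initial_state(pm: PackedModel, posture_deg=None,
                  settle_penetration: bool = True):
    """Initial (q, qd) for the given posture (deg: tilt, hip, knee, ankle).

    The ankle is placed at x = 0 and the pelvis height is chosen so the
    contact spheres carry the body weight at their static Hunt-Crossley
    penetration (or just touch the ground when ``settle_penetration`` is
    off), which avoids an artificial drop transient.
    """
    if posture_deg is None:
        posture_deg = pm.config.reference_pose_deg
    ang = deg2rad(np.asarray(posture_deg, dtype=float))
    q = np.zeros(6)
    q[2:6] = ang
    hip, knee, ankle, compos, eps = _kernel.fk_points(q, pm.seg, pm.foot_com)
    q[0] -= ankle[0]

    # lowest sphere bottom at this posture with pelvis_z = 0
    hip, knee, ankle, compos, eps = _kernel.fk_points(q, pm.seg, pm.foot_com)
    e_f = eps[3]
    cf, sf = math.cos(e_f), math.sin(e_f)
    bottoms = []
    for i in range(2):
        ox, oz = pm.sph_off[i]
        pz = ankle[1] + sf * ox + cf * oz
        bottoms.append(pz - pm.sph_r[i])
    zmin = min(bottoms)

    delta = 0.0
    if settle_penetration:
        # even static load split over the four spheres (two feet)
        w = pm.total_mass() * pm.g / 4.0
        k, nexp = pm.sph_par[0, 0], pm.sph_par[0, 1]
        delta = (w / k) ** (1.0 / nexp)
    q[1] = -zmin - delta
    qd = np.zeros(6)
    return q, qd
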