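"""Parameter containers for the planar neuromusculoskeletal standing model.

Conventions (used everywhere in this package)
---------------------------------------------
* Sagittal plane, x anterior, z up, rotations positive counter-clockwise
  (seen from the model's left).
* Generalized coordinates ``q = (pelvis_x [m], pelvis_z [m], pelvis_tilt,
  hip_flexion, knee_angle, ankle_angle)``; angles are **degrees at every
  public interface and radians internally**.
* Segment orientations are cumulative: trunk = tilt, thigh = tilt + hip,
  shank = thigh + knee, foot = shank + ankle.  With the default standing
  posture (tilt -10, hip 20, knee -20, ankle 10 deg) the foot is exactly
  flat on the ground and the thigh/shank form a slightly flexed column.
* Hip flexion positive brings the knee anterior; knee flexion is negative;
  ankle dorsiflexion is positive.
* Left and right legs share one coordinate/excitation set (symmetric
  standing); leg segments, muscles and feet therefore enter the dynamics
  with multiplicity two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

#: canonical muscle order, one entry per leg muscle (mirrored on both legs)
MUSCLES = ("glu", "ham", "il", "rect", "bfsh", "vas", "gas", "sol", "ta")

MUSCLE_FULL_NAMES = {
    "glu": "gluteus maximus",
    "ham": "hamstrings",
    "il": "iliopsoas",
    "rect": "rectus femoris",
    "bfsh": "biceps femoris short head",
    "vas": "vastus intermedius",
    "gas": "gastrocnemius medialis",
    "sol": "soleus",
    "ta": "tibialis anterior",
}

JOINTS = ("hip", "knee", "ankle")

#: order of the per-muscle controller parameters in packed vectors
GAIN_FIELDS = (
    "u0", "k_l", "k_ldot", "k_f", "k_cop",
    "k_xddot", "k_phi", "k_phiddot", "k_x", "k_xdot", "lm0",
)

GAIN_BOUNDS = {
    "u0": (0.001, 0.2),
    "lm0": (0.1, 2.0),
    # every K_* gain
    "gain": (-3.0, 3.0),
}


def gain_bounds(field_name: str) -> tuple[float, float]:
    """Optimization bounds for one controller parameter field."""
    if field_name in GAIN_BOUNDS:
        return GAIN_BOUNDS[field_name]
    return GAIN_BOUNDS["gain"]


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

@dataclass
class SegmentParams:
    """Rigid segment: mass [kg], length [m], COM offset from the proximal
    joint along the segment axis [m], inertia about the COM [kg m^2]."""

    name: str
    mass: float
    length: float
    com_offset: float
    inertia: float

    def validate(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"segment {self.name}: mass must be > 0")
        if not self.length > 0:
            raise ValueError(f"segment {self.name}: length must be > 0")
        if not 0 <= self.com_offset <= self.length:
            raise ValueError(
                f"segment {self.name}: com_offset must lie in [0, length]")
        if not self.inertia > 0:
            raise ValueError(f"segment {self.name}: inertia must be > 0")


@dataclass
class ContactSphere:
    """Hunt-Crossley contact sphere attached to the foot frame.

    ``offset`` is the sphere center in the foot frame (origin at the ankle,
    x toward the toes) [m].  Normal force is k * d^n * (1 + c * d_dot),
    clamped at zero (no adhesion), with penetration depth d.
    """

    site: str                      # "heel" | "forefoot"
    offset: tuple[float, float]
    radius: float
    stiffness: float = 4.0e5       # N / m^n
    exponent: float = 1.5
    damping: float = 1.0           # s / m
    friction: float = 0.9
    foot: str = "both"             # legs are mirrored; one definition serves both

    def validate(self) -> None:
        if self.site not in ("heel", "forefoot"):
            raise ValueError(f"contact sphere site {self.site!r} unknown")
        if not self.radius > 0:
            raise ValueError("contact sphere radius must be > 0")
        if not self.stiffness > 0:
            raise ValueError("contact sphere stiffness must be > 0")


# ---------------------------------------------------------------------------
# muscles
# ---------------------------------------------------------------------------

@dataclass
class MuscleParams:
    """Hill-type musculotendon actuator (rigid tendon).

    ``moment_arms`` maps joint name -> (r0, r1): moment arm r(theta) =
    r0 + r1 * theta [m], theta in radians.  The musculotendon length is
    defined to be exactly consistent with the moment arms,
    dL/dtheta = -r(theta); normalized fiber length is ``lm_ref`` at the
    model's reference posture.
    """

    name: str
    f_max: float                   # N
    l_opt: float                   # m
    v_max: float = 10.0            # l_opt / s
    lm_ref: float = 1.0            # normalized length at the reference posture
    tau_act: float = 0.010         # s
    tau_deact: float = 0.040       # s
    moment_arms: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.name not in MUSCLES:
            raise ValueError(f"unknown muscle {self.name!r}")
        if not (self.f_max > 0 and self.l_opt > 0 and self.v_max > 0):
            raise ValueError(f"muscle {self.name}: f_max, l_opt, v_max must be > 0")
        n_joints = len(self.moment_arms)
        expected = 2 if self.name in ("ham", "rect", "gas") else 1
        if n_joints != expected:
            raise ValueError(
                f"muscle {self.name}: expected {expected} spanned joint(s), "
                f"got {n_joints}")
        for j in self.moment_arms:
            if j not in JOINTS:
                raise ValueError(f"muscle {self.name}: unknown joint {j!r}")


# ---------------------------------------------------------------------------
# controller
# ---------------------------------------------------------------------------

@dataclass
class MuscleGains:
    """Per-muscle feedforward and feedback parameters.

    All K_* gains act on SI/radian-valued signals (normalized muscle
    length/velocity/force, COP in m, head position in m, velocity in m/s,
    acceleration in m/s^2, orientation in rad, angular acceleration in
    rad/s^2).
    """

    u0: float = 0.05
    k_l: float = 0.0
    k_ldot: float = 0.0
    k_f: float = 0.0
    k_cop: float = 0.0
    k_xddot: float = 0.0
    k_phi: float = 0.0
    k_phiddot: float = 0.0
    k_x: float = 0.0
    k_xdot: float = 0.0
    lm0: float = 1.0

    def validate(self, name: str = "") -> None:
        for f in fields(self):
            lo, hi = gain_bounds(f.name)
            v = getattr(self, f.name)
            if not lo <= v <= hi:
                raise ValueError(
                    f"controller parameter {name}.{f.name} = {v} outside "
                    f"bounds [{lo}, {hi}]")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in GAIN_FIELDS], dtype=float)


@dataclass
class ControllerParams:
    """Full optimizable controller parameter set (shared by both legs).

    Reference values left as ``None`` are resolved from the initial state
    when a simulation starts: ``x_cop0`` defaults to the midpoint between
    the heel and forefoot contact points (expressed foot-relative, i.e. 0),
    ``phi0_deg`` and ``x0`` to the initial head orientation/position.
    """

    gains: dict[str, MuscleGains] = field(
        default_factory=lambda: {m: MuscleGains() for m in MUSCLES})
    x_cop0: Optional[float] = None     # m, foot-relative COP reference
    phi0_deg: Optional[float] = None   # deg, head orientation reference
    x0: Optional[float] = None         # m, head AP position reference

    def validate(self) -> None:
        for m in MUSCLES:
            if m not in self.gains:
                raise ValueError(f"controller parameters missing muscle {m!r}")
            self.gains[m].validate(m)

    # -- flat key-value serialization (also the optimizer checkpoint format)
    def to_text(self) -> str:
        lines = []
        for m in MUSCLES:
            g = self.gains[m]
            for f in GAIN_FIELDS:
                lines.append(f"{m}.{f} = {getattr(g, f):.17g}")
        for k in ("x_cop0", "phi0_deg", "x0"):
            v = getattr(self, k)
            lines.append(f"shared.{k} = {'none' if v is None else format(v, '.17g')}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ControllerParams":
        p = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            scope, _, name = key.partition(".")
            if scope == "shared":
                setattr(p, name, None if val == "none" else float(val))
            elif scope in MUSCLES and name in GAIN_FIELDS:
                setattr(p.gains[scope], name, float(val))
            else:
                raise ValueError(f"unknown controller parameter key {key!r}")
        return p

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "ControllerParams":
        with open(path) as fh:
            return cls.from_text(fh.read())

    @classmethod
    def zero(cls) -> "ControllerParams":
        """All gains and feedforward zero -- the falsification controller.

        Note u0 = 0 lies below the optimization bound on purpose: this
        parameter set exists to show that the skeleton alone cannot stand.
        """
        p = cls(gains={m: MuscleGains(u0=0.0) for m in MUSCLES})
        return p


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Signal-dependent Gaussian noise: x' = x + (base + slope*|s|) * R.

    ``base`` and ``slope`` default to the physiological sensor/actuator
    noise amplitudes 0.0005 and 0.0001; set both to 0 to disable noise.
    """

    seed: int = 0
    base: float = 0.0005
    slope: float = 0.0001

    def amplitude(self, s) -> float:
        """Noise standard deviation k_noise for signal amplitude s."""
        return self.base + self.slope * np.abs(s)


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

def _default_segments() -> dict[str, SegmentParams]:
    # 75 kg / 1.75 m generic adult; head+arms+trunk lumped into the
    # trunk-pelvis segment, leg segments per side (entered twice in the
    # dynamics).  Values follow standard anthropometric tables (de
    # Leva-like fractions), rounded; overridable via config.
    return {
        "trunk": SegmentParams("trunk", mass=50.6, length=0.55,
                               com_offset=0.32, inertia=3.0),
        "thigh": SegmentParams("thigh", mass=7.6, length=0.42,
                               com_offset=0.18, inertia=0.15),
        "shank": SegmentParams("shank", mass=3.5, length=0.43,
                               com_offset=0.19, inertia=0.055),
        "foot": SegmentParams("foot", mass=1.1, length=0.26,
                              com_offset=0.10, inertia=0.007),
    }


def _default_spheres() -> list[ContactSphere]:
    return [
        ContactSphere("heel", offset=(-0.05, -0.06), radius=0.03),
        ContactSphere("forefoot", offset=(0.16, -0.06), radius=0.03),
    ]


def _default_muscles() -> dict[str, MuscleParams]:
    # F_max / l_opt in the range of the Delp/Rajagopal lower-limb literature
    # (lumped per functional group); constant moment arms by default.
    def mk(name, f_max, l_opt, arms):
        return MuscleParams(name, f_max=f_max, l_opt=l_opt,
                            moment_arms={j: (r, 0.0) for j, r in arms.items()})
    return {
        "glu": mk("glu", 1600.0, 0.14, {"hip": -0.060}),
        "ham": mk("ham", 2000.0, 0.10, {"hip": -0.060, "knee": -0.030}),
        "il": mk("il", 1400.0, 0.11, {"hip": 0.050}),
        "rect": mk("rect", 1000.0, 0.084, {"hip": 0.040, "knee": 0.045}),
        "bfsh": mk("bfsh", 800.0, 0.12, {"knee": -0.035}),
        "vas": mk("vas", 3500.0, 0.09, {"knee": 0.045}),
        "gas": mk("gas", 1600.0, 0.06, {"knee": -0.020, "ankle": -0.050}),
        "sol": mk("sol", 3600.0, 0.05, {"ankle": -0.048}),
        "ta": mk("ta", 900.0, 0.098, {"ankle": 0.040}),
    }


@dataclass
class ModelConfig:
    """Full planar model: segments, muscles, contact, conventions."""

    segments: dict[str, SegmentParams] = field(default_factory=_default_segments)
    muscles: dict[str, MuscleParams] = field(default_factory=_default_muscles)
    spheres: list[ContactSphere] = field(default_factory=_default_spheres)
    foot_com: tuple[float, float] = (0.06, -0.03)   # foot COM in foot frame [m]
    head_height: float = 0.72       # head point above the hip on the trunk axis [m]
    gravity: float = 9.81           # m/s^2
    friction_vel: float = 0.05      # m/s, tanh friction regularization
    cop_min_force: float = 1.0      # N, below this total load the COP is invalid
    # reference posture (deg): pelvis tilt, hip flexion, knee, ankle --
    # defines lm_ref for the muscles and the default initial posture
    reference_pose_deg: tuple[float, float, float, float] = (-10.0, 20.0, -20.0, 10.0)
    # passive joint stops (soft end-range torques, per leg): deg ranges
    joint_stop_deg: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"hip": (-30.0, 120.0),
                                 "knee": (-140.0, 0.0),
                                 "ankle": (-50.0, 40.0)})
    joint_stop_stiffness: float = 300.0   # N m / rad beyond the range
    joint_stop_damping: float = 2.0       # N m s / rad, active outside range
    # Hill curve shape constants
    fl_width: float = 0.45          # active force-length Gaussian width
    fv_ecc: float = 1.5             # eccentric force plateau
    fv_shape: float = 0.25          # force-velocity curvature
    fp_width: float = 0.5           # passive curve: ((l-1)/fp_width)^2 above l=1

    def validate(self) -> None:
        for key in ("trunk", "thigh", "shank", "foot"):
            if key not in self.segments:
                raise ValueError(f"model is missing segment {key!r}")
            self.segments[key].validate()
        sites = [s.site for s in self.spheres]
        if sorted(sites) != ["forefoot", "heel"]:
            raise ValueError("model needs exactly one heel and one forefoot sphere")
        for s in self.spheres:
            s.validate()
        for m in MUSCLES:
            if m not in self.muscles:
                raise ValueError(f"model is missing muscle {m!r}")
            self.muscles[m].validate()
        if not self.gravity >= 0:
            raise ValueError("gravity must be >= 0")

    def total_mass(self) -> float:
        s = self.segments
        return (s["trunk"].mass
                + 2.0 * (s["thigh"].mass + s["shank"].mass + s["foot"].mass))


# ---------------------------------------------------------------------------
# scenario / simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class PerturbationSpec:
    """Random square platform-translation signal specification."""

    amplitudes_cm: tuple[float, ...] = (-5.0, -2.5, 0.0, 2.5, 5.0)
    stage_durations_s: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5)
    max_velocity: float = 0.22      # m/s
    duration: float = 75.0          # s
    seed: int = 0

    def validate(self) -> None:
        if not self.max_velocity > 0:
            raise ValueError("perturbation max_velocity must be > 0")
        if not self.duration > 0:
            raise ValueError("perturbation duration must be > 0")
        if len(self.amplitudes_cm) == 0 or len(self.stage_durations_s) == 0:
            raise ValueError("perturbation amplitude/duration sets must be non-empty")


@dataclass
class SimConfig:
    """Closed-loop simulation settings (control runs at 200 Hz)."""

    duration: float = 75.0          # s
    control_rate: float = 200.0     # Hz; 5 ms step, all neural delays are multiples
    substeps: int = 10              # integrator sub-steps per control step
    initial_posture_deg: Optional[tuple[float, float, float, float]] = None
    noise_seed: int = 0
    noise: NoiseModel = field(default_factory=NoiseModel)
    fall_fraction: float = 0.6      # COM height fall threshold
    eval_start: float = 15.0        # s, metrics window start
    settle_penetration: bool = True  # start with static contact penetration

    @property
    def dt(self) -> float:
        return 1.0 / self.control_rate

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * self.control_rate))

    def validate(self) -> None:
        if self.control_rate != 200.0:
            # delays from the neural-delay table must stay integer multiples
            step_ms = 1000.0 / self.control_rate
            from .controller import DELAY_TABLE_MS
            for row in DELAY_TABLE_MS.values():
                for tau in row:
                    if abs(tau / step_ms - round(tau / step_ms)) > 1e-9:
                        raise ValueError(
                            f"neural delay {tau} ms is not a multiple of the "
                            f"{step_ms} ms control step")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if not 0 < self.fall_fraction < 1:
            raise ValueError("fall_fraction must lie in (0, 1)")


@dataclass
class OptConfig:
    """CMA-ES single-shooting optimization settings."""

    n_seeds: int = 6
    popsize: Optional[int] = None    # None -> 4 + floor(3 ln n)
    sigma0: float = 0.15             # initial step in normalized [0,1] space
    stop_tol: float = 1e-5           # mean best-cost improvement threshold
    stop_window: int = 20            # generations in the stopping average
    max_generations: int = 300
    horizon: Optional[float] = None  # s; None -> scenario duration
    muscles: tuple[str, ...] = MUSCLES
    guess_base: float = 3.0          # overall initial feedback gain magnitude
    # Peterka sensory weighting used for the initial guess
    weight_som: float = 0.50
    weight_vis: float = 0.33
    weight_ves: float = 0.17

    def validate(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        for m in self.muscles:
            if m not in MUSCLES:
                raise ValueError(f"unknown muscle {m!r} in optimization config")


@dataclass
class CostBreakdown:
    """Composite simulation cost: 100*J_fall + 0.01*J_effort + 10*J_knee + 0.1*J_hip."""

    j_fall: float
    j_effort: float
    j_knee: float
    j_hip: float

    WEIGHTS = (100.0, 0.01, 10.0, 0.1)

    @property
    def total(self) -> float:
        w = self.WEIGHTS
        return (w[0] * self.j_fall + w[1] * self.j_effort
                + w[2] * self.j_knee + w[3] * self.j_hip)


def deg2rad(x):
    return np.asarray(x, dtype=float) * math.pi / 180.0


def rad2deg(x):
    return np.asarray(x, dtype=float) * 180.0 / math.pi
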