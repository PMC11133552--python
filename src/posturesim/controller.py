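"""Neural control law: per-muscle excitation from feedforward plus delayed
somatosensory, vestibular and visual feedback with signal-dependent noise.

    u(t) = u0 + u_som(t) + u_ves(t) + u_vis(t),  clamped to [0, 1]

    u_som = K_l max(0, l_m - l_m0) + K_ldot max(0, l_m_dot)
            + K_F F_m + K_cop (x_cop - x_cop0)          (delayed tau_som)
    u_ves = K_xddot xddot + K_phi (phi - phi0) + K_phiddot phiddot
                                                        (delayed tau_ves)
    u_vis = K_x (x - x0) + K_xdot xdot                  (delayed tau_vis)

All signals are delayed by lumped muscle- and modality-specific neural
delays (transmission + processing).  Sensor noise is applied before the
delay buffer (transduction noise); actuator noise is applied to the
clamped excitation and re-clamped.
"""

from __future__ import annotations

import numpy as np

from .params import MUSCLES, NoiseModel

MODALITIES = ("somatosensory", "vestibular", "visual")

#: lumped neural delays [ms] per muscle: somatosensory, vestibular, visual.
#: Proximal (hip/thigh) muscles 25 ms reflex delay, knee-spanning distal
#: thigh muscles 35 ms, shank muscles 50 ms; vestibular and visual
#: processing adds 100 ms to each.
DELAY_TABLE_MS = {
    "glu": (25.0, 125.0, 125.0),
    "ham": (25.0, 125.0, 125.0),
    "il": (25.0, 125.0, 125.0),
    "rect": (25.0, 125.0, 125.0),
    "bfsh": (35.0, 135.0, 135.0),
    "vas": (35.0, 135.0, 135.0),
    "gas": (50.0, 150.0, 150.0),
    "sol": (50.0, 150.0, 150.0),
    "ta": (50.0, 150.0, 150.0),
}


def delay_lookup(muscle: str, modality: str) -> float:
    """Neural delay [ms] for one muscle and sensory modality."""
    if muscle not in DELAY_TABLE_MS:
        raise KeyError(f"unknown muscle {muscle!r}")
    if modality not in MODALITIES:
        raise KeyError(f"unknown modality {modality!r}")
    return DELAY_TABLE_MS[muscle][MODALITIES.index(modality)]


def delay_steps(control_dt: float = 0.005) -> np.ndarray:
    """(9, 3) integer delay table in control steps; errors if any delay is
    not an exact multiple of the control step."""
    out = np.empty((len(MUSCLES), 3), dtype=np.int64)
    for i, m in enumerate(MUSCLES):
        for j in range(3):
            tau = DELAY_TABLE_MS[m][j] / 1000.0
            steps = tau / control_dt
            if abs(steps - round(steps)) > 1e-9:
                raise ValueError(
                    f"delay {DELAY_TABLE_MS[m][j]} ms is not a multiple of "
                    f"the {control_dt * 1000:g} ms control step")
            out[i, j] = int(round(steps))
    return out


class DelayBuffer:
    """Ring buffer returning the sample stored exactly ``delay_steps`` ago.

    Pre-filled with an initial value so reads before t = tau return the
    initial state.
    """

    def __init__(self, delay_steps: int, initial: float = 0.0):
        if delay_steps < 0:
            raise ValueError("delay must be >= 0")
        self.delay = int(delay_steps)
        self._buf = np.full(self.delay + 1, float(initial))
        self._k = 0

    def push(self, value: float) -> None:
        self._buf[self._k % len(self._buf)] = value
        self._k += 1

    def read(self) -> float:
        """Sample pushed ``delay`` steps before the most recent push."""
        return float(self._buf[(self._k - 1 - self.delay) % len(self._buf)])


# -- feedback laws -----------------------------------------------------------

def somatosensory_feedback(lm, lmdot, fm, x_cop, *, k_l, k_ldot, k_f, k_cop,
                           lm0, x_cop0=0.0):
    """Proprioceptive + tactile feedback from tau_som-delayed signals.

    Length and velocity terms are rectified (muscle spindles fire on
    stretch); force and COP terms are sign-preserving.
    """
    return (k_l * max(0.0, lm - lm0) + k_ldot * max(0.0, lmdot)
            + k_f * fm + k_cop * (x_cop - x_cop0))


def vestibular_feedback(xddot, phi, phiddot, *, k_xddot, k_phi, k_phiddot,
                        phi0=0.0):
    """Head linear-acceleration / orientation / angular-acceleration feedback
    (sign-preserving, no rectification)."""
    return k_xddot * xddot + k_phi * (phi - phi0) + k_phiddot * phiddot


def visual_feedback(x, xdot, *, k_x, k_xdot, x0=0.0):
    """Head position/velocity feedback relative to the environment."""
    return k_x * (x - x0) + k_xdot * xdot


def total_excitation(u0, u_som, u_ves, u_vis):
    """Feedforward plus feedback, clamped to the physiological range [0, 1]."""
    return float(np.clip(u0 + u_som + u_ves + u_vis, 0.0, 1.0))


def apply_noise(x, s, rng, noise: NoiseModel | None = None):
    """Signal-dependent Gaussian noise x' = x + (base + slope |s|) R.

    ``s`` is the signal amplitude (the signal value itself for sensors and
    excitations); R is a standard normal draw from ``rng``.
    """
    if noise is None:
        noise = NoiseModel()
    x = np.asarray(x, dtype=float)
    r = rng.standard_normal(x.shape) if x.shape else rng.standard_normal()
    return x + noise.amplitude(s) * r
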