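"""Scenario definitions: quiet standing and the random-square
platform-translation perturbation signal.

The platform follows a random square signal: plateau positions drawn
uniformly from a fixed amplitude set, held for stage durations drawn
uniformly from a fixed duration set.  A literal square wave implies
infinite platform velocity, so consecutive plateaus are joined by linear
ramps at the observed velocity limit (~0.22 m/s); when a stage is shorter
than the required ramp the plateau is truncated (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .params import PerturbationSpec

log = logging.getLogger(__name__)


@dataclass
class PlatformSignal:
    """Platform position [m] on the control grid and its exact derivative.

    ``pos`` has one more sample than ``vel``; pos[i+1] = pos[i] + vel[i] dt.
    """

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    rate: float

    def save(self, path) -> None:
        data = np.column_stack([self.t, self.pos])
        np.savetxt(path, data, fmt="%.9g", delimiter="\t",
                   header="time_s\tplatform_position_m", comments="")


@dataclass
class Scenario:
    """A standing task: name plus the prescribed platform signal."""

    name: str
    signal: PlatformSignal
    spec: PerturbationSpec | None = None

    @property
    def duration(self) -> float:
        return float(self.signal.t[-1])


def draw_stages(spec: PerturbationSpec, rng) -> list[tuple[float, float]]:
    """(amplitude [m], duration [s]) stage sequence covering the spec
    duration; both drawn uniformly and independently (repeats allowed)."""
    stages = []
    total = 0.0
    amps = np.asarray(spec.amplitudes_cm, dtype=float) / 100.0
    durs = np.asarray(spec.stage_durations_s, dtype=float)
    while total < spec.duration:
        amp = amps[rng.integers(len(amps))]
        dur = durs[rng.integers(len(durs))]
        stages.append((float(amp), float(dur)))
        total += dur
    return stages


def generate_platform_signal(spec: PerturbationSpec,
                             rate: float = 200.0) -> PlatformSignal:
    """Rate-limited random square platform signal on the control grid.

    Deterministic for a given ``spec.seed``; |position| never exceeds the
    largest amplitude and |velocity| never exceeds ``spec.max_velocity``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / rate
    n = int(round(spec.duration * rate))
    pos = np.zeros(n + 1)
    vel = np.zeros(n)
    stages = draw_stages(spec, rng)

    i = 0
    p = 0.0
    vmax_step = spec.max_velocity * dt
    for amp, dur in stages:
        n_stage = int(round(dur * rate))
        for _ in range(n_stage):
            if i >= n:
                break
            step = np.clip(amp - p, -vmax_step, vmax_step)
            vel[i] = step / dt
            p += step
            pos[i + 1] = p
            i += 1
        if abs(p - amp) > 1e-12:
            log.debug("perturbation stage to %.3f m truncated mid-ramp "
                      "(stage shorter than ramp time)", amp)
        if i >= n:
            break
    t = np.arange(n + 1) * dt
    return PlatformSignal(t, pos, vel, rate)


def perturbed_scenario(spec: PerturbationSpec | None = None,
                       rate: float = 200.0) -> Scenario:
    spec = spec or PerturbationSpec()
    return Scenario("platform", generate_platform_signal(spec, rate), spec)


def quiet_scenario(duration: float = 75.0, rate: float = 200.0) -> Scenario:
    """Quiet standing: identically zero platform motion."""
    n = int(round(duration * rate))
    t = np.arange(n + 1) / rate
    sig = PlatformSignal(t, np.zeros(n + 1), np.zeros(n), rate)
    return Scenario("quiet", sig, None)
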