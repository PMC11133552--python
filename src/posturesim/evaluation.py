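"""Balance metrics and signal processing: ROM, RMSE against reference
trajectories, COP range, EMG-style envelope extraction, Butterworth
filtering.

Reference series are delimited text with a one-line header naming the
channels (first column ``time``); angle channels are degrees, COP is mm.
Comparisons resample the reference onto the simulation grid by linear
interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulation import Trajectory

log = logging.getLogger(__name__)


@dataclass
class ReferenceSeries:
    """Named reference channels on a monotone time grid."""

    t: np.ndarray
    channels: dict[str, np.ndarray]
    provenance: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("reference time grid must be strictly increasing")
        for k, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.t.shape:
                raise ValueError(f"channel {k!r} length mismatch")
            self.channels[k] = v

    def resample(self, t_new: np.ndarray) -> "ReferenceSeries":
        return ReferenceSeries(
            t_new, {k: np.interp(t_new, self.t, v)
                    for k, v in self.channels.items()}, self.provenance)

    @classmethod
    def load(cls, path, provenance: str = "") -> "ReferenceSeries":
        df = pd.read_csv(path, sep=None, engine="python")
        tcol = df.columns[0]
        return cls(df[tcol].to_numpy(),
                   {c: df[c].to_numpy() for c in df.columns[1:]},
                   provenance or str(path))

    def save(self, path) -> None:
        df = pd.DataFrame({"time": self.t, **self.channels})
        df.to_csv(path, sep="\t", index=False, float_format="%.9g")


@dataclass
class MetricReport:
    """Per-channel ROM/RMSE plus COP range over an evaluation window."""

    window: tuple[float, float]
    rom: dict[str, float] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)
    cop_range_mm: Optional[float] = None

    def to_text(self) -> str:
        lines = [f"evaluation window: {self.window[0]:g}..{self.window[1]:g} s"]
        for k, v in self.rom.items():
            lines.append(f"rom.{k} = {v:.6g}")
        for k, v in self.rmse.items():
            lines.append(f"rmse.{k} = {v:.6g}")
        if self.cop_range_mm is not None:
            lines.append(f"cop_range_mm = {self.cop_range_mm:.6g}")
        return "\n".join(lines) + "\n"


def _window_mask(t, window):
    lo = t[0] if window[0] is None else window[0]
    hi = t[-1] if window[1] is None else window[1]
    return (t >= lo - 1e-12) & (t <= hi + 1e-12)


def compute_rom(values, t=None, window=(None, None)) -> float:
    """Range of motion: max - min over the window."""
    values = np.asarray(values, dtype=float)
    if t is not None:
        values = values[_window_mask(np.asarray(t, float), window)]
    if len(values) == 0:
        return 0.0
    return float(values.max() - values.min())


def compute_rmse(t_sim, values_sim, t_ref, values_ref,
                 window=(None, None)) -> float:
    """Root-mean-square pointwise difference; the reference is linearly
    resampled onto the simulation grid."""
    t_sim = np.asarray(t_sim, dtype=float)
    ref = np.interp(t_sim, np.asarray(t_ref, float),
                    np.asarray(values_ref, float))
    mask = _window_mask(t_sim, window)
    d = np.asarray(values_sim, float)[mask] - ref[mask]
    if len(d) == 0:
        return 0.0
    return float(np.sqrt(np.mean(d ** 2)))


def cop_range(traj: Trajectory, window=(None, None)) -> float:
    """COP excursion [mm] over the window, skipping invalid (unloaded)
    samples."""
    mask = _window_mask(traj.t, window) & traj.cop_valid.astype(bool)
    cop = traj.cop[mask]
    if len(cop) == 0:
        return 0.0
    return float((cop.max() - cop.min()) * 1000.0)


def butterworth_lowpass(values, rate, cutoff=6.0, order=3):
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(values, dtype=float))


def emg_preprocess(raw, rate, band=(20.0, 500.0), envelope_cutoff=6.0):
    """EMG envelope: zero-phase band-pass, full-wave rectification,
    zero-phase 6 Hz low-pass.

    The band upper edge is capped below Nyquist for low-rate signals (with
    a logged warning); the nominal 20-500 Hz band assumes >= 1 kHz EMG.
    """
    raw = np.asarray(raw, dtype=float)
    nyq = rate / 2.0
    hi = band[1]
    if hi >= nyq:
        hi = 0.9 * nyq
        log.warning("EMG band upper edge capped at %.1f Hz (Nyquist %.1f Hz)",
                    hi, nyq)
    sos = sps.butter(4, (band[0], hi), btype="bandpass", fs=rate,
                     output="sos")
    bp = sps.sosfiltfilt(sos, raw)
    rect = np.abs(bp)
    return butterworth_lowpass(rect, rate, cutoff=envelope_cutoff, order=3)


def evaluate_trajectory(traj: Trajectory,
                        reference: Optional[ReferenceSeries] = None,
                        window=(None, None)) -> MetricReport:
    """ROM (and RMSE against an optional reference) for the four sagittal
    angles plus the COP range, over the evaluation window."""
    lo = traj.eval_start if window[0] is None else window[0]
    hi = traj.t[-1] if window[1] is None else window[1]
    report = MetricReport(window=(lo, hi))
    ang = traj.angles_deg()
    names = ("pelvis_tilt", "hip", "knee", "ankle")
    for j, name in enumerate(names):
        report.rom[name] = compute_rom(ang[:, j], traj.t, (lo, hi))
    report.cop_range_mm = cop_range(traj, (lo, hi))
    if reference is not None:
        for name in names:
            if name in reference.channels:
                report.rmse[name] = compute_rmse(
                    traj.t, ang[:, names.index(name)],
                    reference.t, reference.channels[name], (lo, hi))
    return report
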