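"""Derived traces: AC-band activity, smoothed power, DC trend, baseline stats.

Analysis filtering is zero-phase (forward-backward) so that event onset
timing is not biased by filter delay, in contrast to the causal acquisition
model in :mod:`sdecog.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .simulate import ParameterError, Recording

__all__ = ["DerivedTraces", "bandpass_ac", "power_trace", "dc_trend", "baseline_stats", "derive"]


@dataclass
class DerivedTraces:
    """AC band (0.5-45 Hz) trace in mV, smoothed squared power in mV^2, and
    low-frequency DC trend in mV, all sample-aligned with the raw recording."""

    ac: np.ndarray
    power: np.ndarray
    dc: np.ndarray
    fs_hz: float


def _traces_fs(recording, fs_hz):
    if isinstance(recording, Recording):
        return recording.traces, recording.fs_hz
    if fs_hz is None:
        raise ParameterError("fs_hz required when passing a bare array")
    return np.atleast_2d(np.asarray(recording, dtype=float)), float(fs_hz)


def bandpass_ac(recording, lo_hz: float = 0.5, hi_hz: float = 45.0, fs_hz=None) -> np.ndarray:
    """Zero-phase 0.5-45 Hz band-pass of the raw near-DC trace(s)."""
    x, fs = _traces_fs(recording, fs_hz)
    if not (0 < lo_hz < hi_hz < fs / 2):
        raise ParameterError(f"invalid band ({lo_hz}, {hi_hz}) at fs={fs}")
    sos = sps.butter(4, [lo_hz, hi_hz], "bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, x, axis=-1)
    return out.reshape(np.shape(recording.traces if isinstance(recording, Recording) else recording))


def power_trace(ac: np.ndarray, fs_hz: float, window_s: float = 1.0) -> np.ndarray:
    """Moving-average of the squared AC trace over window_s (centered)."""
    if window_s <= 0:
        raise ParameterError("window_s must be > 0")
    ac = np.asarray(ac, dtype=float)
    size = int(round(window_s * fs_hz))
    if size > ac.shape[-1]:
        raise ParameterError("window longer than trace")
    return uniform_filter1d(ac**2, size=max(size, 1), axis=-1, mode="nearest")


def dc_trend(recording, cutoff_hz: float = 0.1, fs_hz=None) -> np.ndarray:
    """Zero-phase low-pass isolating the slow potential change."""
    x, fs = _traces_fs(recording, fs_hz)
    if not (0 < cutoff_hz < 0.5):
        raise ParameterError("cutoff_hz must be in (0, 0.5)")
    sos = sps.butter(4, cutoff_hz, "lowpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, x, axis=-1)
    return out.reshape(np.shape(recording.traces if isinstance(recording, Recording) else recording))


def baseline_stats(trace: np.ndarray, fs_hz: float, window: tuple[float, float],
                   marker_s=None) -> tuple[float, float, float]:
    """(mean, sd, rms) of the pre-marker baseline segment of one trace."""
    t0, t1 = window
    trace = np.asarray(trace, dtype=float)
    if marker_s is not None and t1 > marker_s:
        raise ParameterError("baseline window must end at or before the marker")
    if t1 - t0 < 10.0:
        raise ParameterError("baseline window must be at least 10 s")
    i0, i1 = int(round(t0 * fs_hz)), int(round(t1 * fs_hz))
    if i0 < 0 or i1 > trace.shape[-1] or i1 <= i0:
        raise ParameterError("baseline window outside trace")
    seg = trace[..., i0:i1]
    return float(np.mean(seg)), float(np.std(seg)), float(np.sqrt(np.mean(seg**2)))


def derive(recording: Recording, ac_band=(0.5, 45.0), power_window_s: float = 1.0,
           dc_cutoff_hz: float = 0.1) -> DerivedTraces:
    """Compute all derived traces for a recording in one pass."""
    ac = bandpass_ac(recording, *ac_band)
    power = power_trace(ac, recording.fs_hz, power_window_s)
    dc = dc_trend(recording, dc_cutoff_hz)
    return DerivedTraces(ac=ac, power=power, dc=dc, fs_hz=recording.fs_hz)
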