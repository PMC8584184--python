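"""Seeded simulation of multi-channel near-DC ECoG recordings.

The generator produces recordings that emulate the phenomenology of rodent
closed-head-injury electrocorticography: slow potential changes of spreading
depolarization (SD) propagating across the cortex at a few mm/min, the
spreading depression of AC-band activity that travels with them, non-spreading
(simultaneous) depression of activity (NSD) across both hemispheres and the
brainstem, terminal SDs without recovery, and rare electrographic seizures —
all superimposed on band-limited 1/f background activity and passed through a
causal model of the acquisition chain (0.02 Hz high-pass, 100 Hz low-pass,
60 Hz notch).

Every injected event is recorded in a :class:`GroundTruthLog` so that the
detection and classification stages can be validated against exact truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as sps

__all__ = [
    "Electrode",
    "ElectrodeLayout",
    "AmplifierSpec",
    "BackgroundSpec",
    "SDEventSpec",
    "NSDEventSpec",
    "SeizureEventSpec",
    "SimulationConfig",
    "Recording",
    "GroundTruthLog",
    "sd_waveform",
    "propagate_onsets",
    "apply_amplifier",
    "simulate_recording",
]

SITES = ("cortexL", "cortexR", "brainstem")


class ParameterError(ValueError):
    """Raised when an event or configuration parameter violates its contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Electrode:
    """A recording site: name, planar position in mm relative to bregma
    (x = lateral, right positive; y = anterior positive), and anatomical site."""

    name: str
    x_mm: float
    y_mm: float
    site: str = "cortexL"

    def __post_init__(self):
        if self.site not in SITES:
            raise ParameterError(f"unknown site {self.site!r}; expected one of {SITES}")
        if not (math.isfinite(self.x_mm) and math.isfinite(self.y_mm)):
            raise ParameterError("electrode coordinates must be finite")


@dataclass(frozen=True)
class ElectrodeLayout:
    channels: tuple[Electrode, ...]

    def __init__(self, channels: Sequence[Electrode]):
        channels = tuple(
            c if isinstance(c, Electrode) else Electrode(*c) for c in channels
        )
        if len(channels) == 0:
            raise ParameterError("layout needs at least one channel")
        names = [c.name for c in channels]
        if len(set(names)) != len(names):
            raise ParameterError("channel names must be unique")
        object.__setattr__(self, "channels", channels)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def positions(self) -> np.ndarray:
        return np.array([[c.x_mm, c.y_mm] for c in self.channels], dtype=float)

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, name: str) -> Electrode:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def distance_mm(self, a: str, b: str) -> float:
        ea, eb = self[a], self[b]
        return math.hypot(ea.x_mm - eb.x_mm, ea.y_mm - eb.y_mm)


def bilateral_layout(brainstem: bool = False) -> ElectrodeLayout:
    """Standard implant: one epidural screw per parietal bone, 3 mm lateral to
    the sagittal suture and 2 mm posterior to bregma; optional paired brainstem
    wires 12 mm posterior, +/-3 mm lateral (planar proxy for the 9 mm-deep
    insertion)."""
    chans = [
        Electrode("cortexL", -3.0, -2.0, "cortexL"),
        Electrode("cortexR", 3.0, -2.0, "cortexR"),
    ]
    if brainstem:
        chans.append(Electrode("brainstem", 3.0, -12.0, "brainstem"))
    return ElectrodeLayout(chans)


@dataclass(frozen=True)
class AmplifierSpec:
    """Causal model of the acquisition chain.

    Defaults follow a near-DC bio-amplifier: 0.02 Hz first-order high-pass,
    100 Hz fourth-order low-pass, 60 Hz notch, sampled at 1 kHz.
    """

    highpass_hz: float = 0.02
    lowpass_hz: float = 100.0
    notch_hz: Optional[float] = 60.0
    fs_hz: float = 1000.0

    def __post_init__(self):
        if not (0 < self.highpass_hz < self.lowpass_hz < self.fs_hz / 2):
            raise ParameterError(
                "require 0 < highpass_hz < lowpass_hz < fs_hz/2, got "
                f"{self.highpass_hz}, {self.lowpass_hz}, fs={self.fs_hz}"
            )
        if self.notch_hz is not None and not (0 < self.notch_hz < self.fs_hz / 2):
            raise ParameterError("notch_hz must lie below Nyquist")

    def sos(self) -> np.ndarray:
        """Second-order sections of the full causal chain."""
        hp = sps.butter(1, self.highpass_hz, "highpass", fs=self.fs_hz, output="sos")
        lp = sps.butter(4, self.lowpass_hz, "lowpass", fs=self.fs_hz, output="sos")
        secs = [hp, lp]
        if self.notch_hz is not None:
            b, a = sps.iirnotch(self.notch_hz, Q=30.0, fs=self.fs_hz)
            secs.append(sps.tf2sos(b, a))
        return np.vstack(secs)


@dataclass(frozen=True)
class BackgroundSpec:
    """Band-limited 1/f^alpha background activity.

    rms_mv is the time-domain RMS of the unmodulated background;
    anesthesia_recovery, if given, is (start_s, end_s, peak_gain): the
    amplitude gain ramps linearly from peak_gain at start_s down to 1 at
    end_s (emulating the high-amplitude activity seen on emergence from
    anesthesia).
    """

    rms_mv: float = 0.05
    spectral_exponent: float = 1.0
    band_hz: tuple[float, float] = (0.5, 45.0)
    anesthesia_recovery: Optional[tuple[float, float, float]] = None

    def __post_init__(self):
        if self.rms_mv < 0:
            raise ParameterError("rms_mv must be >= 0")


@dataclass(frozen=True)
class SDEventSpec:
    """A spreading depolarization: a propagating negative slow potential
    change with a trailing depression of AC activity.

    onset_s is the initiation time in seconds after the impact/stimulation
    marker; amplitude_mv is the peak negative deflection of the *recorded*
    (post-amplifier) trace; recovery=False makes the event terminal (the DC
    shift and the activity depression never recover).
    """

    onset_s: float
    origin: tuple[float, float] = (0.0, -2.0)
    amplitude_mv: float = 1.5
    duration_s: float = 60.0
    velocity_mm_per_min: float = 4.0
    depression_fraction: float = 0.2
    depression_duration_s: float = 300.0
    recovery: bool = True
    channels: Optional[tuple[str, ...]] = None  # None = all reachable

    def __post_init__(self):
        if self.amplitude_mv <= 0:
            raise ParameterError("amplitude_mv must be > 0")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.velocity_mm_per_min <= 0:
            raise ParameterError("velocity_mm_per_min must be > 0")
        if not (0 <= self.depression_fraction < 1):
            raise ParameterError("depression_fraction must be in [0, 1)")
        if self.onset_s < 0:
            raise ParameterError("onset_s must be >= 0 (seconds after marker)")


@dataclass(frozen=True)
class NSDEventSpec:
    """Non-spreading depression: simultaneous suppression of activity on all
    affected channels, followed either by recovery (recovery_delay_s) or by a
    terminal SD (terminal_sd_delay_s after NSD onset, per-channel lags).
    Exactly one of the two outcomes must be specified."""

    onset_s: float
    affected_channels: Optional[tuple[str, ...]] = None  # None = all
    recovery: bool = True
    recovery_delay_s: Optional[float] = 300.0
    terminal_sd_delay_s: Optional[float] = None
    terminal_sd_channel_lags_s: Optional[dict] = None
    terminal_sd_amplitude_mv: float = 1.5
    depression_fraction: float = 0.1

    def __post_init__(self):
        if self.onset_s < 0:
            raise ParameterError("onset_s must be >= 0")
        if self.recovery:
            if self.recovery_delay_s is None or self.terminal_sd_delay_s is not None:
                raise ParameterError(
                    "recovering NSD needs recovery_delay_s and no terminal_sd_delay_s"
                )
        else:
            if self.terminal_sd_delay_s is None:
                raise ParameterError("non-recovering NSD needs terminal_sd_delay_s")
        if not (0 <= self.depression_fraction < 1):
            raise ParameterError("depression_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SeizureEventSpec:
    """Electrographic seizure: rhythmic biphasic spikes."""

    onset_s: float
    duration_s: float = 30.0
    spike_rate_hz: float = 5.0
    spike_amplitude_mv: float = 0.5
    channels: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.spike_rate_hz <= 0:
            raise ParameterError("spike_rate_hz must be > 0")


EventSpec = Union[SDEventSpec, NSDEventSpec, SeizureEventSpec]


@dataclass(frozen=True)
class SimulationConfig:
    layout: ElectrodeLayout = field(default_factory=bilateral_layout)
    amplifier: AmplifierSpec = field(default_factory=AmplifierSpec)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    events: tuple[EventSpec, ...] = ()
    total_duration_s: float = 7200.0
    marker_s: float = 3600.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        if not (0 <= self.marker_s < self.total_duration_s):
            raise ParameterError("marker_s must lie within the recording")
        n_terminal = sum(
            1
            for e in self.events
            if (isinstance(e, SDEventSpec) and not e.recovery)
            or (isinstance(e, NSDEventSpec) and not e.recovery)
        )
        if n_terminal > 1:
            raise ParameterError("only one terminal episode per recording")
        for e in self.events:
            if self.marker_s + e.onset_s >= self.total_duration_s:
                raise ParameterError(
                    f"event onset {e.onset_s} s after marker falls outside recording"
                )


@dataclass
class Recording:
    """Multi-channel near-DC voltage traces in mV."""

    fs_hz: float
    traces: np.ndarray  # (n_channels, n_samples)
    layout: ElectrodeLayout
    marker_s: float
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2 or self.traces.shape[0] != len(self.layout):
            raise ParameterError("traces must be (n_channels, n_samples) matching layout")
        if np.isnan(self.traces).any():
            raise ParameterError("traces contain NaN")

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def channel(self, name: str) -> np.ndarray:
        return self.traces[self.layout.names.index(name)]


@dataclass
class GroundTruthLog:
    """Exact injected parameters, one record per event.

    Onsets are seconds after the marker; per-channel SD onsets follow the
    origin/velocity geometry of the layout."""

    events: list = field(default_factory=list)

    def of_type(self, kind: str) -> list:
        return [e for e in self.events if e["type"] == kind]


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def sd_waveform(
    amplitude_mv: float,
    duration_s: float,
    onset_s: float,
    time_grid: np.ndarray,
    ramp_s: float = 10.0,
    recover: bool = True,
) -> np.ndarray:
    """Single-channel SD slow-potential template.

    Piecewise raised-cosine fall (default 10 s), plateau at -amplitude_mv, and
    raised-cosine recovery, parameterized so the full width at half recovery
    equals duration_s. With recover=False (terminal SD) the trace stays at the
    plateau to the end of the grid.
    """
    if amplitude_mv <= 0:
        raise ParameterError("amplitude_mv must be > 0")
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    t = np.asarray(time_grid, dtype=float)
    ramp = min(ramp_s, duration_s / 2.0)
    plateau = duration_s - ramp  # FWHM = ramp/2 + plateau + ramp/2 = duration_s
    tau = t - onset_s
    y = np.zeros_like(t)
    m = (tau >= 0) & (tau < ramp)
    y[m] = -amplitude_mv / 2.0 * (1.0 - np.cos(np.pi * tau[m] / ramp))
    if recover:
        m = (tau >= ramp) & (tau < ramp + plateau)
        y[m] = -amplitude_mv
        m = (tau >= ramp + plateau) & (tau < 2 * ramp + plateau)
        y[m] = -amplitude_mv / 2.0 * (1.0 + np.cos(np.pi * (tau[m] - ramp - plateau) / ramp))
    else:
        y[tau >= ramp] = -amplitude_mv
    return y


def propagate_onsets(
    event: SDEventSpec,
    layout: ElectrodeLayout,
    t_end_s: Optional[float] = None,
) -> dict[str, float]:
    """Per-channel SD onset times (seconds after the marker).

    onset(channel) = event.onset_s + distance(origin, channel) / velocity.
    Channels that the wave cannot reach before t_end_s (if given) map to
    +inf ("unreached").
    """
    if len(layout) == 0:
        raise ParameterError("empty layout")
    if event.velocity_mm_per_min <= 0:
        raise ParameterError("velocity must be > 0")
    ox, oy = event.origin
    v_mm_per_s = event.velocity_mm_per_min / 60.0
    out: dict[str, float] = {}
    wanted = set(event.channels) if event.channels is not None else None
    for ch in layout.channels:
        if wanted is not None and ch.name not in wanted:
            continue
        d = math.hypot(ch.x_mm - ox, ch.y_mm - oy)
        onset = event.onset_s + d / v_mm_per_s
        if t_end_s is not None and onset > t_end_s:
            onset = math.inf
        out[ch.name] = onset
    return out


def apply_amplifier(raw_traces: np.ndarray, spec: AmplifierSpec) -> np.ndarray:
    """Pass raw traces through the causal acquisition chain.

    Output has the same shape as the input; DC offsets decay with the 0.02 Hz
    high-pass time constant; pass-band gain is ~1.
    """
    raw = np.atleast_2d(np.asarray(raw_traces, dtype=float))
    return sps.sosfilt(spec.sos(), raw, axis=-1).reshape(np.shape(raw_traces))


def _recorded_peak_ratio(
    duration_s: float, spec: AmplifierSpec, ramp_s: float = 10.0, recover: bool = True
) -> float:
    """|peak| of the amplifier response to a unit-amplitude SD template.

    Used to calibrate injected amplitudes so that the *recorded* trace reaches
    the requested peak negative deflection despite high-pass droop.
    """
    fs = spec.fs_hz
    ramp = min(ramp_s, duration_s / 2.0)
    pad = 4.0 * ramp + duration_s
    n = int(round(pad * fs)) + 1
    t = np.arange(n) / fs
    tpl = sd_waveform(1.0, duration_s, ramp, t, ramp_s=ramp_s, recover=recover)
    out = sps.sosfilt(spec.sos(), tpl)
    return float(-out.min())


def _pink_noise(
    n: int, fs: float, rng: np.random.Generator, spec: BackgroundSpec
) -> np.ndarray:
    """Seeded band-limited 1/f^alpha noise, unit RMS (scaled by caller)."""
    white = rng.standard_normal(n)
    if spec.rms_mv == 0:
        return np.zeros(n)
    F = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi = spec.band_hz
    shape = np.zeros_like(f)
    inband = (f >= lo) & (f <= hi)
    shape[inband] = f[inband] ** (-spec.spectral_exponent / 2.0)
    x = np.fft.irfft(F * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _smooth_envelope(
    n: int, fs: float, intervals: list[tuple[float, float, float]], edge_s: float = 1.0
) -> np.ndarray:
    """Multiplicative amplitude envelope: 1 outside depression intervals,
    `fraction` inside, raised-cosine edges of edge_s."""
    env = np.ones(n)
    t = np.arange(n) / fs
    for start, end, frac in intervals:
        dip = np.ones(n)
        a, b = start, min(end, t[-1] + 1.0 / fs)
        if b <= a:
            continue
        m = (t >= a) & (t < b)
        dip[m] = frac
        # cosine on-ramp [start, start+edge), off-ramp [end, end+edge)
        m = (t >= a) & (t < a + edge_s)
        x = (t[m] - a) / edge_s
        dip[m] = 1.0 + (frac - 1.0) * (1.0 - np.cos(np.pi * x)) / 2.0
        if end < t[-1]:
            m = (t >= b) & (t < b + edge_s)
            x = (t[m] - b) / edge_s
            dip[m] = frac + (1.0 - frac) * (1.0 - np.cos(np.pi * x)) / 2.0
        env = np.minimum(env, dip)
    return env


def _seizure_train(
    t: np.ndarray, onset_abs: float, ev: SeizureEventSpec
) -> np.ndarray:
    """Rhythmic biphasic spikes (one sine period per spike, 50 ms wide)."""
    y = np.zeros_like(t)
    width = min(0.05, 0.5 / ev.spike_rate_hz)
    n_spikes = int(ev.duration_s * ev.spike_rate_hz)
    period = 1.0 / ev.spike_rate_hz
    for k in range(n_spikes):
        t0 = onset_abs + k * period
        m = (t >= t0) & (t < t0 + width)
        y[m] = ev.spike_amplitude_mv * np.sin(2 * np.pi * (t[m] - t0) / width)
    return y


# ---------------------------------------------------------------------------
# full recording synthesis
# ---------------------------------------------------------------------------


def simulate_recording(config: SimulationConfig) -> tuple[Recording, GroundTruthLog]:
    """Synthesize a recording and its exact ground-truth event log.

    Per channel: background * depression envelope + slow potentials + seizure
    spikes, then the causal amplifier chain. Identical seeds give bit-identical
    output. Event onsets in the config and the log are seconds after the
    marker.
    """
    fs = config.amplifier.fs_hz
    n = int(round(config.total_duration_s * fs))
    t = np.arange(n) / fs
    t_end_rel = config.total_duration_s - config.marker_s
    rng = np.random.default_rng(config.seed)
    names = config.layout.names

    dc = np.zeros((len(names), n))
    envelopes: dict[str, list[tuple[float, float, float]]] = {nm: [] for nm in names}
    spikes = np.zeros_like(dc)
    log = GroundTruthLog()

    for ev in config.events:
        if isinstance(ev, SDEventSpec):
            onsets = propagate_onsets(ev, config.layout, t_end_s=t_end_rel)
            ratio = _recorded_peak_ratio(
                ev.duration_s, config.amplifier, recover=ev.recovery
            )
            amp_pre = ev.amplitude_mv / ratio
            for nm, on in onsets.items():
                if not math.isfinite(on):
                    continue
                i = names.index(nm)
                dc[i] += sd_waveform(
                    amp_pre, ev.duration_s, config.marker_s + on, t, recover=ev.recovery
                )
                dep_end = (
                    config.marker_s + on + ev.depression_duration_s
                    if ev.recovery
                    else config.total_duration_s + 1.0
                )
                if ev.depression_fraction < 1:
                    envelopes[nm].append(
                        (config.marker_s + on, dep_end, ev.depression_fraction)
                    )
            log.events.append(
                {
                    "type": "SD" if ev.recovery else "terminal_SD",
                    "spec": dataclasses.asdict(ev),
                    "per_channel_onset_s": {
                        k: v for k, v in onsets.items() if math.isfinite(v)
                    },
                    "amplitude_mv": ev.amplitude_mv,
                    "duration_s": ev.duration_s,
                    "velocity_mm_per_min": ev.velocity_mm_per_min,
                    "recovery": ev.recovery,
                }
            )
        elif isinstance(ev, NSDEventSpec):
            affected = (
                list(ev.affected_channels) if ev.affected_channels is not None else names
            )
            onset_abs = config.marker_s + ev.onset_s
            if ev.recovery:
                end_abs = onset_abs + float(ev.recovery_delay_s)
            else:
                end_abs = config.total_duration_s + 1.0
            for nm in affected:
                envelopes[nm].append((onset_abs, end_abs, ev.depression_fraction))
            rec: dict = {
                "type": "NSD",
                "spec": dataclasses.asdict(ev),
                "per_channel_onset_s": {nm: ev.onset_s for nm in affected},
                "recovery": ev.recovery,
            }
            if not ev.recovery:
                tsd_on = ev.onset_s + float(ev.terminal_sd_delay_s)
                lags = ev.terminal_sd_channel_lags_s or {}
                ratio = _recorded_peak_ratio(60.0, config.amplifier, recover=False)
                amp_pre = ev.terminal_sd_amplitude_mv / ratio
                tsd_onsets = {}
                for nm in affected:
                    on = tsd_on + float(lags.get(nm, 0.0))
                    tsd_onsets[nm] = on
                    i = names.index(nm)
                    dc[i] += sd_waveform(
                        amp_pre, 60.0, config.marker_s + on, t, recover=False
                    )
                rec["terminal_sd_per_channel_onset_s"] = tsd_onsets
                rec["terminal_sd_delay_s"] = float(ev.terminal_sd_delay_s)
                log.events.append(
                    {
                        "type": "terminal_SD",
                        "spec": dataclasses.asdict(ev),
                        "per_channel_onset_s": tsd_onsets,
                        "amplitude_mv": ev.terminal_sd_amplitude_mv,
                        "recovery": False,
                    }
                )
            log.events.insert(len(log.events) - (0 if ev.recovery else 1), rec)
        elif isinstance(ev, SeizureEventSpec):
            affected = list(ev.channels) if ev.channels is not None else names
            for nm in affected:
                i = names.index(nm)
                spikes[i] += _seizure_train(t, config.marker_s + ev.onset_s, ev)
            log.events.append(
                {
                    "type": "seizure",
                    "spec": dataclasses.asdict(ev),
                    "per_channel_onset_s": {nm: ev.onset_s for nm in affected},
                    "duration_s": ev.duration_s,
                }
            )
        else:  # pragma: no cover - guarded by SimulationConfig typing
            raise ParameterError(f"unknown event spec {type(ev)!r}")

    raw = np.zeros_like(dc)
    for i, nm in enumerate(names):
        bg = config.background.rms_mv * _pink_noise(n, fs, rng, config.background)
        if config.background.anesthesia_recovery is not None:
            s0, s1, gain = config.background.anesthesia_recovery
            ramp = np.interp(t, [s0, s1], [gain, 1.0], left=gain, right=1.0)
            bg = bg * ramp
        env = _smooth_envelope(n, fs, envelopes[nm])
        raw[i] = bg * env + dc[i] + spikes[i]

    traces = apply_amplifier(raw, config.amplifier)
    annotations = [{"onset_s": config.marker_s, "label": "marker"}]
    recording = Recording(
        fs_hz=fs,
        traces=traces,
        layout=config.layout,
        marker_s=config.marker_s,
        annotations=annotations,
    )
    return recording, log
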