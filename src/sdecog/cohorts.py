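"""Canonical scenario and cohort generators.

The builders here encode the study conditions of the source experiments:
mild closed-head impacts (SD after 53% of 71 impacts, onset 124 +/- 48 s,
amplitude 1.5 mV, rare seizures), severe impacts (SD after 46% of 37, onset
149 +/- 43 s, brainstem SD in 3, NSD after 11 with onset 47 +/- 40 s, of
which 9 progress to terminal SD after 125 +/- 77 s and death), and
electrically triggered SDs (onset 104 +/- 85 s, amplitude 0.26 mV,
velocity 4 mm/min).

Latency distributions: reported "mean +/- SD" values describe the observed
(positive) latencies, so draws come from a zero-truncated normal whose
parameters are solved so that the *truncated* distribution has the reported
mean and SD. Cohort draws are stratified over equal-probability quantile
bins by default so that small cohorts are representative of the reported
distribution; iid draws are available via sampling="iid".
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sstats

from .simulate import (
    AmplifierSpec,
    BackgroundSpec,
    ElectrodeLayout,
    NSDEventSpec,
    ParameterError,
    SDEventSpec,
    SeizureEventSpec,
    SimulationConfig,
    bilateral_layout,
)

__all__ = [
    "truncated_normal_matched",
    "sample_latencies",
    "scenario_sd",
    "scenario_sd_with_seizure",
    "scenario_severe_sd_brainstem",
    "scenario_nsd_recovery",
    "scenario_nsd_terminal",
    "scenario_sham",
    "scenario_triggered_sd",
    "mild_tbi_cohort",
    "severe_tbi_cohort",
    "MILD_SD_LATENCY",
    "SEVERE_SD_LATENCY",
    "TRIGGERED_SD_LATENCY",
    "NSD_LATENCY",
    "TERMINAL_SD_DELAY",
    "TBI_SD_AMPLITUDE_MV",
    "TRIGGERED_SD_AMPLITUDE_MV",
    "SD_VELOCITY_MM_PER_MIN",
]

# Reported study conditions (observed mean, observed SD), in seconds.
MILD_SD_LATENCY = (124.0, 48.0)
SEVERE_SD_LATENCY = (149.0, 43.0)
TRIGGERED_SD_LATENCY = (104.0, 85.0)
NSD_LATENCY = (47.0, 40.0)
TERMINAL_SD_DELAY = (125.0, 77.0)
TBI_SD_AMPLITUDE_MV = 1.5
TRIGGERED_SD_AMPLITUDE_MV = 0.26
SD_VELOCITY_MM_PER_MIN = 4.0

# Scaled problem sizes used throughout tests and examples: 250 Hz sampling,
# 60 s pre-impact baseline, 600 s post-impact window. The full experimental
# protocol (1 kHz, 1 h baseline, 2 h follow-up) is a configuration away.
DEFAULT_FS_HZ = 250.0
DEFAULT_BASELINE_S = 60.0
DEFAULT_POST_S = 600.0


def truncated_normal_matched(mean: float, sd: float):
    """Zero-truncated normal whose truncated mean/SD equal the given values.

    Solves for the parent (mu, sigma); the reported summary statistics of
    observed latencies are statistics of positive values, so matching the
    truncated moments (rather than the parent's) reproduces them. Requires
    sd < mean is not necessary, but sd/mean must be < 1 (the zero-truncated
    normal family's coefficient of variation is bounded by 1).
    """
    if mean <= 0 or sd <= 0:
        raise ParameterError("mean and sd must be > 0")
    if sd / mean >= 0.995:
        # CV outside the family's range; fall back to plain truncation
        return sstats.truncnorm(-mean / sd, np.inf, loc=mean, scale=sd)

    def resid(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        d = sstats.truncnorm(-mu / sigma, np.inf, loc=mu, scale=sigma)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(resid, x0=[mean, math.log(sd)], method="hybr")
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    if not sol.success:  # pragma: no cover - hybr converges on this family
        raise RuntimeError(f"moment matching failed: {sol.message}")
    return sstats.truncnorm(-mu / sigma, np.inf, loc=mu, scale=sigma)


def sample_latencies(
    mean: float,
    sd: float,
    n: int,
    rng: np.random.Generator,
    sampling: str = "stratified",
) -> np.ndarray:
    """Draw n positive latencies with observed moments (mean, sd).

    sampling="stratified": one inverse-CDF draw per equal-probability bin
    (jittered, shuffled) — small cohorts then carry the distribution's mean
    faithfully. sampling="iid": plain independent draws.
    """
    dist = truncated_normal_matched(mean, sd)
    if sampling == "stratified":
        u = (np.arange(n) + rng.uniform(0.0, 1.0, n)) / n
        rng.shuffle(u)
        return dist.ppf(u)
    if sampling == "iid":
        return dist.rvs(size=n, random_state=rng)
    raise ParameterError("sampling must be 'stratified' or 'iid'")


# ---------------------------------------------------------------------------
# canonical single-recording scenarios
# ---------------------------------------------------------------------------


def _config(layout, events, seed, fs_hz, baseline_s, post_s, rms_mv,
            anesthesia_recovery=None) -> SimulationConfig:
    return SimulationConfig(
        layout=layout,
        amplifier=AmplifierSpec(fs_hz=fs_hz),
        background=BackgroundSpec(rms_mv=rms_mv, anesthesia_recovery=anesthesia_recovery),
        events=tuple(events),
        total_duration_s=baseline_s + post_s,
        marker_s=baseline_s,
        seed=seed,
    )


def scenario_sd(
    latency_s: float = MILD_SD_LATENCY[0],
    amplitude_mv: float = TBI_SD_AMPLITUDE_MV,
    velocity_mm_per_min: float = SD_VELOCITY_MM_PER_MIN,
    duration_s: float = 60.0,
    origin: tuple[float, float] = (-3.0, -2.0),
    layout: Optional[ElectrodeLayout] = None,
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
    baseline_s: float = DEFAULT_BASELINE_S,
    post_s: float = DEFAULT_POST_S,
    rms_mv: float = 0.05,
) -> SimulationConfig:
    """Bilateral TBI-induced SD with trailing spreading depression."""
    layout = layout or bilateral_layout()
    sd = SDEventSpec(
        onset_s=latency_s,
        origin=origin,
        amplitude_mv=amplitude_mv,
        duration_s=duration_s,
        velocity_mm_per_min=velocity_mm_per_min,
    )
    return _config(layout, [sd], seed, fs_hz, baseline_s, post_s, rms_mv)


def scenario_sd_with_seizure(
    latency_s: float = MILD_SD_LATENCY[0],
    seizure_lead_s: float = 60.0,
    seizure_duration_s: float = 30.0,
    seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """SD with seizure activity immediately before the SD."""
    cfg = scenario_sd(latency_s=latency_s, seed=seed, **kwargs)
    seizure = SeizureEventSpec(
        onset_s=max(latency_s - seizure_lead_s, 1.0),
        duration_s=seizure_duration_s,
    )
    return SimulationConfig(
        layout=cfg.layout, amplifier=cfg.amplifier, background=cfg.background,
        events=cfg.events + (seizure,), total_duration_s=cfg.total_duration_s,
        marker_s=cfg.marker_s, seed=seed,
    )


def scenario_severe_sd_brainstem(
    latency_s: float = SEVERE_SD_LATENCY[0],
    seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """Severe-TBI SD reaching both cortices and the brainstem."""
    kwargs.setdefault("layout", bilateral_layout(brainstem=True))
    kwargs.setdefault("origin", (-3.0, -4.0))  # near left cortex electrode
    return scenario_sd(latency_s=latency_s, seed=seed, **kwargs)


def scenario_nsd_recovery(
    latency_s: float = NSD_LATENCY[0],
    recovery_delay_s: float = 300.0,
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
    baseline_s: float = DEFAULT_BASELINE_S,
    post_s: float = DEFAULT_POST_S,
    rms_mv: float = 0.05,
) -> SimulationConfig:
    """Simultaneous NSD on both cortices and brainstem; activity returns."""
    layout = bilateral_layout(brainstem=True)
    nsd = NSDEventSpec(onset_s=latency_s, recovery=True, recovery_delay_s=recovery_delay_s)
    return _config(layout, [nsd], seed, fs_hz, baseline_s, post_s, rms_mv)


def scenario_nsd_terminal(
    latency_s: float = NSD_LATENCY[0],
    terminal_delay_s: float = TERMINAL_SD_DELAY[0],
    channel_lags_s: Optional[dict] = None,
    terminal_amplitude_mv: float = TBI_SD_AMPLITUDE_MV,
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
    baseline_s: float = DEFAULT_BASELINE_S,
    post_s: float = DEFAULT_POST_S,
    rms_mv: float = 0.05,
) -> SimulationConfig:
    """Lasting NSD followed by staggered terminal SDs and death."""
    layout = bilateral_layout(brainstem=True)
    if channel_lags_s is None:
        channel_lags_s = {"cortexL": 0.0, "cortexR": 20.0, "brainstem": 45.0}
    nsd = NSDEventSpec(
        onset_s=latency_s,
        recovery=False,
        recovery_delay_s=None,
        terminal_sd_delay_s=terminal_delay_s,
        terminal_sd_channel_lags_s=channel_lags_s,
        terminal_sd_amplitude_mv=terminal_amplitude_mv,
    )
    return _config(layout, [nsd], seed, fs_hz, baseline_s, post_s, rms_mv)


def scenario_sham(
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
    baseline_s: float = DEFAULT_BASELINE_S,
    post_s: float = DEFAULT_POST_S,
    rms_mv: float = 0.05,
) -> SimulationConfig:
    """Non-injured control: background only, with the high-amplitude
    emergence-from-anesthesia ramp settling within 5 minutes."""
    layout = bilateral_layout()
    return _config(
        layout, [], seed, fs_hz, baseline_s, post_s, rms_mv,
        anesthesia_recovery=(baseline_s, baseline_s + 300.0, 2.0),
    )


def scenario_triggered_sd(
    latency_s: float = TRIGGERED_SD_LATENCY[0],
    amplitude_mv: float = TRIGGERED_SD_AMPLITUDE_MV,
    velocity_mm_per_min: float = SD_VELOCITY_MM_PER_MIN,
    channel_positions: Sequence[tuple[float, float]] = ((-3.0, -2.0), (-3.0, -6.0)),
    stim_site: tuple[float, float] = (-3.0, 2.0),
    seed: int = 0,
    fs_hz: float = DEFAULT_FS_HZ,
    baseline_s: float = DEFAULT_BASELINE_S,
    post_s: float = DEFAULT_POST_S,
    rms_mv: float = 0.0,
) -> SimulationConfig:
    """Electrically triggered SD: initiation at the frontal stimulation site,
    recorded by electrodes along the propagation path (default 4 mm apart)."""
    from .simulate import Electrode

    chans = [
        Electrode(f"ch{i+1}", x, y, "cortexL" if x <= 0 else "cortexR")
        for i, (x, y) in enumerate(channel_positions)
    ]
    layout = ElectrodeLayout(chans)
    sd = SDEventSpec(
        onset_s=latency_s,
        origin=stim_site,
        amplitude_mv=amplitude_mv,
        velocity_mm_per_min=velocity_mm_per_min,
    )
    return _config(layout, [sd], seed, fs_hz, baseline_s, post_s, rms_mv)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _grow_post_s(post_s: float, *event_end_times: float) -> float:
    """Extend the post-marker window to cover the latest injected event."""
    need = max(event_end_times) + 60.0
    return max(post_s, float(need))


def mild_tbi_cohort(
    n: int = 71,
    n_sd: int = 37,
    n_seizure: int = 3,
    latency: tuple[float, float] = MILD_SD_LATENCY,
    amplitude_mv: float = TBI_SD_AMPLITUDE_MV,
    seed: int = 0,
    sampling: str = "stratified",
    rms_mv: float = 0.05,
    fs_hz: float = DEFAULT_FS_HZ,
    post_s: float = DEFAULT_POST_S,
) -> list[SimulationConfig]:
    """Mild-impact cohort: n recordings, n_sd with an SD (latency drawn from
    the reported distribution), n_seizure of those with peri-SD seizures,
    the rest uneventful."""
    if not (0 <= n_seizure <= n_sd <= n):
        raise ParameterError("need n_seizure <= n_sd <= n")
    rng = np.random.default_rng(seed)
    lat = sample_latencies(*latency, n_sd, rng, sampling) if n_sd else np.array([])
    seeds = rng.integers(0, 2**31 - 1, size=n)
    configs = []
    for i in range(n):
        if i < n_sd:
            ps = _grow_post_s(post_s, lat[i] + 480.0)
            if i < n_seizure:
                cfg = scenario_sd_with_seizure(
                    latency_s=float(lat[i]), amplitude_mv=amplitude_mv,
                    seed=int(seeds[i]), rms_mv=rms_mv, fs_hz=fs_hz, post_s=ps,
                )
            else:
                cfg = scenario_sd(
                    latency_s=float(lat[i]), amplitude_mv=amplitude_mv,
                    seed=int(seeds[i]), rms_mv=rms_mv, fs_hz=fs_hz, post_s=ps,
                )
        else:
            cfg = _config(
                bilateral_layout(), [], int(seeds[i]), fs_hz,
                DEFAULT_BASELINE_S, post_s, rms_mv,
            )
        configs.append(cfg)
    return configs


def severe_tbi_cohort(
    n: int = 37,
    n_sd: int = 17,
    n_brainstem_sd: int = 3,
    n_nsd: int = 11,
    n_terminal: int = 9,
    sd_latency: tuple[float, float] = SEVERE_SD_LATENCY,
    nsd_latency: tuple[float, float] = NSD_LATENCY,
    terminal_delay: tuple[float, float] = TERMINAL_SD_DELAY,
    amplitude_mv: float = TBI_SD_AMPLITUDE_MV,
    seed: int = 0,
    sampling: str = "stratified",
    rms_mv: float = 0.05,
    fs_hz: float = DEFAULT_FS_HZ,
    post_s: float = DEFAULT_POST_S,
) -> list[SimulationConfig]:
    """Severe-impact cohort with brainstem monitoring: n_sd recordings with
    cortical SD (n_brainstem_sd of them reaching the brainstem), n_nsd with
    NSD of which n_terminal progress to terminal SD and death, the rest
    uneventful."""
    if n_sd + n_nsd > n or n_terminal > n_nsd or n_brainstem_sd > n_sd:
        raise ParameterError("inconsistent cohort composition")
    rng = np.random.default_rng(seed)
    sd_lat = sample_latencies(*sd_latency, n_sd, rng, sampling) if n_sd else np.array([])
    nsd_lat = sample_latencies(*nsd_latency, n_nsd, rng, sampling) if n_nsd else np.array([])
    delays = sample_latencies(*terminal_delay, n_terminal, rng, sampling) if n_terminal else np.array([])
    seeds = rng.integers(0, 2**31 - 1, size=n)
    layout = bilateral_layout(brainstem=True)
    configs = []
    for i in range(n):
        if i < n_sd:
            reach_brainstem = i < n_brainstem_sd
            channels = None if reach_brainstem else ("cortexL", "cortexR")
            lat = float(sd_lat[i])
            ps = _grow_post_s(post_s, lat + (600.0 if reach_brainstem else 520.0))
            sd = SDEventSpec(
                onset_s=lat, origin=(-3.0, -4.0), amplitude_mv=amplitude_mv,
                duration_s=60.0, velocity_mm_per_min=SD_VELOCITY_MM_PER_MIN,
                channels=channels,
            )
            cfg = _config(layout, [sd], int(seeds[i]), fs_hz, DEFAULT_BASELINE_S, ps, rms_mv)
        elif i < n_sd + n_nsd:
            j = i - n_sd
            lat = float(nsd_lat[j])
            if j < n_terminal:
                delay = float(delays[j])
                ps = _grow_post_s(post_s, lat + delay + 180.0)
                cfg = scenario_nsd_terminal(
                    latency_s=lat, terminal_delay_s=delay,
                    terminal_amplitude_mv=amplitude_mv,
                    seed=int(seeds[i]), rms_mv=rms_mv, fs_hz=fs_hz, post_s=ps,
                )
            else:
                ps = _grow_post_s(post_s, lat + 400.0)
                cfg = scenario_nsd_recovery(
                    latency_s=lat, seed=int(seeds[i]), rms_mv=rms_mv,
                    fs_hz=fs_hz, post_s=ps,
                )
        else:
            cfg = _config(layout, [], int(seeds[i]), fs_hz, DEFAULT_BASELINE_S, post_s, rms_mv)
        configs.append(cfg)
    return configs
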