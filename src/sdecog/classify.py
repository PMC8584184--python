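"""Event taxonomy: combine per-channel detections into SD, NSD, terminal SD
and seizure calls, measure latency and propagation velocity, label outcomes,
and tabulate cohort prevalence.

The key discriminator is timing across channels: spreading depression of
activity arrives sequentially at adjacent electrodes together with the SD
slow potential change, whereas non-spreading depression suppresses activity
on all monitored channels (both cortical hemispheres and the brainstem)
simultaneously and without a preceding DC shift.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .detect import ChannelDetection
from .simulate import ElectrodeLayout, ParameterError

__all__ = [
    "EventCall",
    "OutcomeLabel",
    "PrevalenceTable",
    "SimultaneityError",
    "classify_events",
    "estimate_velocity",
    "prevalence",
]


class SimultaneityError(ValueError):
    """Velocity requested for an event with no usable onset lag."""


@dataclass
class EventCall:
    type: str  # SD | NSD | terminal_SD | seizure
    channels: list
    per_channel_onset_s: dict
    latency_s: float  # first onset relative to marker
    amplitude_mv: Optional[float] = None  # max across channels
    duration_s: Optional[float] = None
    spread: Optional[str] = None  # spreading | simultaneous
    velocity_mm_per_min: Optional[float] = None
    recovered: bool = True

    def __post_init__(self):
        if self.type == "terminal_SD" and self.recovered:
            raise ParameterError("terminal_SD implies recovered=False")


@dataclass
class OutcomeLabel:
    survived: bool = True
    cause: str = "none"  # none | NSD_terminal_SD

    def __post_init__(self):
        if self.cause == "NSD_terminal_SD" and self.survived:
            raise ParameterError("NSD_terminal_SD cause implies survived=False")


@dataclass
class PrevalenceTable:
    cohort: str
    n_impacts: int
    n_SD: int = 0
    n_seizure: int = 0
    n_NSD: int = 0
    n_terminal_death: int = 0
    site: str = "cortex"

    def __post_init__(self):
        for f_ in ("n_SD", "n_seizure", "n_NSD", "n_terminal_death"):
            if getattr(self, f_) > self.n_impacts:
                raise ParameterError(f"{f_} exceeds n_impacts")

    def as_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "site": self.site,
            "n_impacts": self.n_impacts,
            "n_SD": self.n_SD,
            "n_seizure": self.n_seizure,
            "n_NSD": self.n_NSD,
            "n_terminal_death": self.n_terminal_death,
        }


def _pairwise_spread(onsets: dict) -> float:
    vals = [v for v in onsets.values() if math.isfinite(v)]
    return (max(vals) - min(vals)) if len(vals) > 1 else 0.0


def estimate_velocity(
    event: EventCall,
    layout: ElectrodeLayout,
    origin_xy: Optional[tuple[float, float]] = None,
    origin_onset_s: Optional[float] = None,
) -> float:
    """Propagation velocity in mm/min from inter-channel onset lags.

    With two channels this is separation / lag; with more, a least-squares
    fit of pairwise distance = v * lag through the origin. When the
    initiation site is known (triggered SD: the stimulation site) it can be
    supplied as an extra anchor point with its onset time.
    """
    pts: list[tuple[float, float, float]] = []  # (x, y, onset)
    for ch, onset in event.per_channel_onset_s.items():
        if math.isfinite(onset):
            e = layout[ch]
            pts.append((e.x_mm, e.y_mm, onset))
    if origin_xy is not None and origin_onset_s is not None:
        pts.append((origin_xy[0], origin_xy[1], origin_onset_s))
    if len(pts) < 2:
        raise ParameterError("velocity needs >= 2 channels with onsets")
    num = 0.0
    den = 0.0
    for (x1, y1, t1), (x2, y2, t2) in itertools.combinations(pts, 2):
        d = math.hypot(x1 - x2, y1 - y2)
        lag = abs(t1 - t2)
        num += d * lag
        den += lag * lag
    if den == 0.0:
        raise SimultaneityError(
            "all onsets coincide; no propagation lag (simultaneous event)"
        )
    return 60.0 * num / den  # mm/s -> mm/min


def classify_events(
    detections: dict[str, ChannelDetection],
    layout: ElectrodeLayout,
    theta_sim_s: float = 5.0,
    min_group_velocity_mm_per_min: float = 2.0,
    dc_precedence_margin_s: float = 2.0,
) -> tuple[list[EventCall], OutcomeLabel]:
    """Assemble per-channel detections into event calls plus an outcome.

    Rules:
      * depressions on all monitored channels with pairwise onset lags
        <= theta_sim_s and no DC shift at or before their onset -> NSD
        (a DC shift counts as "preceding" up to dc_precedence_margin_s after
        the depression onset: in an SD the depression trails the slow
        potential change, so the two onsets coincide within detection
        jitter, whereas a terminal SD after NSD starts clearly later);
      * DC shifts across channels are grouped into one wave when their lags
        are compatible with a physiological SD speed
        (>= min_group_velocity_mm_per_min over the layout diameter); a group
        with a co-located depression is an SD, spreading when the maximum
        pairwise lag exceeds theta_sim_s;
      * an unrecovered DC-shift group following an unrecovered NSD is a
        terminal SD, and the recording is labelled died
        (cause NSD -> terminal SD);
      * overlapping per-channel seizure intervals merge into one seizure call.
    """
    names = [n for n in layout.names if n in detections]
    if not names:
        raise ParameterError("no detections supplied")
    calls: list[EventCall] = []

    # --- NSD: simultaneous depression on every monitored channel -----------
    nsd_calls: list[EventCall] = []
    deps0 = detections[names[0]].depressions
    used_deps: set = set()
    for d0 in deps0:
        group = {names[0]: d0}
        for nm in names[1:]:
            match = None
            for d in detections[nm].depressions:
                if abs(d.onset_s - d0.onset_s) <= theta_sim_s:
                    match = d
                    break
            if match is None:
                break
            group[nm] = match
        if len(group) != len(names):
            continue
        onset = min(d.onset_s for d in group.values())
        # no DC shift preceding (or accompanying) the depression onset
        preceded = any(
            s.onset_s <= onset + dc_precedence_margin_s
            for nm in names
            for s in detections[nm].dc_shifts
        )
        if preceded:
            continue
        recovered = all(d.recovered for d in group.values())
        nsd_calls.append(
            EventCall(
                type="NSD",
                channels=list(group),
                per_channel_onset_s={nm: d.onset_s for nm, d in group.items()},
                latency_s=onset,
                duration_s=(
                    max(d.end_s for d in group.values()) - onset if recovered else None
                ),
                spread="simultaneous",
                recovered=recovered,
            )
        )
        used_deps.update((nm, d.onset_s) for nm, d in group.items())
    calls.extend(nsd_calls)

    # --- group DC shifts into waves ----------------------------------------
    pos = layout.positions
    diameter = 0.0
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            diameter = max(diameter, float(np.hypot(*(pos[i] - pos[j]))))
    max_lag = (
        60.0 * diameter / min_group_velocity_mm_per_min if diameter > 0 else theta_sim_s
    )
    shifts = sorted(
        (
            (s.onset_s, nm, s)
            for nm in names
            for s in detections[nm].dc_shifts
        ),
        key=lambda x: x[0],
    )
    groups: list[dict] = []
    for onset, nm, s in shifts:
        placed = False
        for g in groups:
            if nm not in g and onset - min(x.onset_s for x in g.values()) <= max_lag:
                g[nm] = s
                placed = True
                break
        if not placed:
            groups.append({nm: s})

    nsd_unrecovered = [c for c in nsd_calls if not c.recovered]
    outcome = OutcomeLabel()
    for g in groups:
        onsets = {nm: s.onset_s for nm, s in g.items()}
        first = min(onsets.values())
        spread = "spreading" if _pairwise_spread(onsets) > theta_sim_s else "simultaneous"
        # The acquisition high-pass makes even a terminal DC plateau droop
        # back toward baseline, so "terminal" is judged by the absence of
        # *activity* recovery: a DC-shift wave after an NSD whose depression
        # never lifts by end of record is a terminal SD.
        is_terminal = any(c.latency_s < first for c in nsd_unrecovered)
        group_recovered = (not is_terminal) and all(s.recovered for s in g.values())
        call = EventCall(
            type="terminal_SD" if is_terminal else "SD",
            channels=sorted(g, key=layout.names.index),
            per_channel_onset_s=onsets,
            latency_s=first,
            amplitude_mv=max(s.peak_mv for s in g.values()),
            duration_s=float(np.mean([s.duration_s for s in g.values()])),
            spread=spread,
            recovered=group_recovered,
        )
        if spread == "spreading" and len(g) >= 2:
            try:
                call.velocity_mm_per_min = estimate_velocity(call, layout)
            except (SimultaneityError, ParameterError):
                call.velocity_mm_per_min = None
        calls.append(call)
        if is_terminal:
            outcome = OutcomeLabel(survived=False, cause="NSD_terminal_SD")

    # --- seizures: merge overlapping channel intervals ----------------------
    seiz = sorted(
        ((s.onset_s, s.onset_s + s.duration_s, nm)
         for nm in names for s in detections[nm].seizures),
        key=lambda x: x[0],
    )
    merged: list[list] = []
    for a, b, nm in seiz:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
            merged[-1][2].setdefault(nm, a)
        else:
            merged.append([a, b, {nm: a}])
    for a, b, chans in merged:
        calls.append(
            EventCall(
                type="seizure",
                channels=list(chans),
                per_channel_onset_s=dict(chans),
                latency_s=a,
                duration_s=b - a,
                spread=None,
            )
        )

    calls.sort(key=lambda c: c.latency_s)
    return calls, outcome


def prevalence(
    cohort: list[tuple[list[EventCall], OutcomeLabel]],
    label: str = "cohort",
    site: str = "cortex",
    layout: Optional[ElectrodeLayout] = None,
) -> PrevalenceTable:
    """Per-cohort counts of impacts with at least one event of each type.

    site restricts SD counting to events involving a channel at that site
    ("cortex" matches both hemispheres); NSD/seizure/terminal counts are
    whole-recording properties.
    """
    if len(cohort) == 0:
        raise ParameterError("empty cohort")

    def at_site(call: EventCall) -> bool:
        if layout is None:
            if site == "cortex":
                return any(not ch.startswith("brainstem") for ch in call.channels)
            return any(ch.startswith(site) for ch in call.channels)
        sites = {layout[ch].site for ch in call.channels}
        if site == "cortex":
            return bool(sites & {"cortexL", "cortexR"})
        return site in sites

    table = PrevalenceTable(cohort=label, n_impacts=len(cohort), site=site)
    for calls, outcome in cohort:
        kinds = {c.type for c in calls if c.type != "SD" or at_site(c)}
        table.n_SD += "SD" in kinds
        table.n_seizure += "seizure" in kinds
        table.n_NSD += "NSD" in kinds
        table.n_terminal_death += (not outcome.survived) and outcome.cause == "NSD_terminal_SD"
    return table
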