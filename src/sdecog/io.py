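"""Reading and writing recordings, ground truth, detections and configs.

The lossless interchange format is CSV (long format: time_s, channel, mv)
with a YAML sidecar carrying the sampling rate, marker time and electrode
layout. EDF files are read through :mod:`mne` when it is installed; ground
truth and detections travel as JSON, simulation configs as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import EventCall, OutcomeLabel
from .detect import ChannelDetection, DCShift, Depression, Seizure
from .simulate import (
    AmplifierSpec,
    BackgroundSpec,
    Electrode,
    ElectrodeLayout,
    GroundTruthLog,
    NSDEventSpec,
    ParameterError,
    Recording,
    SDEventSpec,
    SeizureEventSpec,
    SimulationConfig,
)

__all__ = [
    "write_recording",
    "read_recording",
    "write_truth",
    "read_truth",
    "read_config",
    "write_config",
    "write_detections",
    "read_detections",
    "write_calls",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def _layout_to_obj(layout: ElectrodeLayout) -> list:
    return [
        {"name": c.name, "x_mm": c.x_mm, "y_mm": c.y_mm, "site": c.site}
        for c in layout.channels
    ]


def _layout_from_obj(obj) -> ElectrodeLayout:
    return ElectrodeLayout(
        [Electrode(c["name"], c["x_mm"], c["y_mm"], c.get("site", "cortexL")) for c in obj]
    )


def write_recording(recording: Recording, path) -> Path:
    """Write a recording to long-format CSV plus a YAML metadata sidecar."""
    path = Path(path)
    if path.suffix.lower() != ".csv":
        raise ParameterError(f"unsupported output format {path.suffix!r}; use .csv")
    names = recording.layout.names
    t = recording.times
    frames = [
        pd.DataFrame({"time_s": t, "channel": nm, "mv": recording.traces[i]})
        for i, nm in enumerate(names)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "fs_hz": float(recording.fs_hz),
        "marker_s": float(recording.marker_s),
        "layout": _layout_to_obj(recording.layout),
        "annotations": recording.annotations,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def _read_recording_csv(path: Path) -> Recording:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "channel", "mv"):
        if col not in df.columns:
            raise ParameterError(f"recording CSV missing column {col!r}")
    if df["mv"].isna().any():
        raise ParameterError("recording contains NaN samples")
    side = _sidecar(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text())
        fs = float(meta["fs_hz"])
        marker_s = float(meta["marker_s"])
        layout = _layout_from_obj(meta["layout"])
        annotations = meta.get("annotations", [])
    else:
        t = np.sort(df["time_s"].unique())
        if len(t) < 2:
            raise ParameterError("cannot infer sampling rate from a single sample")
        fs = 1.0 / float(np.median(np.diff(t)))
        layout = ElectrodeLayout(
            [Electrode(nm, float(i), 0.0) for i, nm in enumerate(df["channel"].unique())]
        )
        marker_s = 0.0
        annotations = []
    names = layout.names
    n = None
    traces = []
    for nm in names:
        seg = df.loc[df["channel"] == nm].sort_values("time_s")["mv"].to_numpy()
        if n is None:
            n = len(seg)
        elif len(seg) != n:
            raise ParameterError("channels have unequal sample counts (truncated file?)")
        traces.append(seg)
    expected = None
    if side.exists():
        # marker must be inside the record; a truncated CSV shows up here
        expected = int(round(fs * marker_s))
        if n is None or n <= expected:
            raise ParameterError("recording shorter than its marker time (truncated file?)")
    return Recording(fs_hz=fs, traces=np.vstack(traces), layout=layout,
                     marker_s=marker_s, annotations=annotations)


def _read_recording_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ParameterError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e3  # volts -> mV
    side = _sidecar(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text())
        layout = _layout_from_obj(meta["layout"])
        marker_s = float(meta.get("marker_s", 0.0))
    else:
        layout = ElectrodeLayout(
            [Electrode(nm, float(i), 0.0) for i, nm in enumerate(raw.ch_names)]
        )
        marker_s = 0.0
        for ann in raw.annotations:
            if str(ann["description"]).lower() == "marker":
                marker_s = float(ann["onset"])
    return Recording(fs_hz=float(raw.info["sfreq"]), traces=data, layout=layout,
                     marker_s=marker_s)


def read_recording(path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return _read_recording_csv(path)
    if suffix == ".edf":
        return _read_recording_edf(path)
    raise ParameterError(f"unknown recording format {suffix!r}")


# ---------------------------------------------------------------------------
# ground truth / configs
# ---------------------------------------------------------------------------


def write_truth(log: GroundTruthLog, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"events": log.events}, indent=2, default=float))
    return path


def read_truth(path) -> GroundTruthLog:
    obj = json.loads(Path(path).read_text())
    return GroundTruthLog(events=obj["events"])


_EVENT_TYPES = {"sd": SDEventSpec, "nsd": NSDEventSpec, "seizure": SeizureEventSpec}


def _event_to_obj(ev) -> dict:
    kind = {SDEventSpec: "sd", NSDEventSpec: "nsd", SeizureEventSpec: "seizure"}[type(ev)]
    d = dataclasses.asdict(ev)
    d["kind"] = kind
    return d


def _event_from_obj(obj: dict):
    obj = dict(obj)
    kind = obj.pop("kind")
    cls = _EVENT_TYPES[kind]
    for key in ("origin", "channels", "affected_channels"):
        if key in obj and isinstance(obj[key], list):
            obj[key] = tuple(obj[key])
    return cls(**obj)


def write_config(config: SimulationConfig, path) -> Path:
    obj = {
        "layout": _layout_to_obj(config.layout),
        "amplifier": dataclasses.asdict(config.amplifier),
        "background": dataclasses.asdict(config.background),
        "events": [_event_to_obj(e) for e in config.events],
        "total_duration_s": config.total_duration_s,
        "marker_s": config.marker_s,
        "seed": config.seed,
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def read_config(path, seed=None) -> SimulationConfig:
    obj = yaml.safe_load(Path(path).read_text())
    bg = dict(obj.get("background", {}))
    if bg.get("anesthesia_recovery") is not None:
        bg["anesthesia_recovery"] = tuple(bg["anesthesia_recovery"])
    if bg.get("band_hz") is not None:
        bg["band_hz"] = tuple(bg["band_hz"])
    return SimulationConfig(
        layout=_layout_from_obj(obj["layout"]),
        amplifier=AmplifierSpec(**obj.get("amplifier", {})),
        background=BackgroundSpec(**bg),
        events=tuple(_event_from_obj(e) for e in obj.get("events", [])),
        total_duration_s=float(obj["total_duration_s"]),
        marker_s=float(obj["marker_s"]),
        seed=int(obj["seed"] if seed is None else seed),
    )


# ---------------------------------------------------------------------------
# detections and calls
# ---------------------------------------------------------------------------


def write_detections(detections: dict[str, ChannelDetection], path) -> Path:
    obj = {
        ch: {
            "dc_shifts": [dataclasses.asdict(s) for s in det.dc_shifts],
            "depressions": [dataclasses.asdict(d) for d in det.depressions],
            "seizures": [dataclasses.asdict(s) for s in det.seizures],
        }
        for ch, det in detections.items()
    }
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=float))
    return path


def read_detections(path) -> dict[str, ChannelDetection]:
    obj = json.loads(Path(path).read_text())
    out = {}
    for ch, d in obj.items():
        det = ChannelDetection(channel=ch)
        det.dc_shifts = [DCShift(**s) for s in d["dc_shifts"]]
        det.depressions = [Depression(**x) for x in d["depressions"]]
        det.seizures = [Seizure(**s) for s in d["seizures"]]
        out[ch] = det
    return out


def calls_to_frame(calls: list[EventCall], outcome: OutcomeLabel) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "type": c.type,
                "channels": ";".join(c.channels),
                "latency_s": c.latency_s,
                "amplitude_mv": c.amplitude_mv,
                "duration_s": c.duration_s,
                "spread": c.spread,
                "velocity_mm_per_min": c.velocity_mm_per_min,
                "recovered": c.recovered,
                "survived": outcome.survived,
            }
        )
    return pd.DataFrame(rows)


def write_calls(calls: list[EventCall], outcome: OutcomeLabel, path) -> Path:
    path = Path(path)
    obj = {
        "events": [dataclasses.asdict(c) for c in calls],
        "outcome": dataclasses.asdict(outcome),
    }
    if path.suffix.lower() == ".csv":
        calls_to_frame(calls, outcome).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(obj, indent=2, default=float))
    return path
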