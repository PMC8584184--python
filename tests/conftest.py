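"""Shared fixtures: canonical scenario recordings, detections and calls.

Session-scoped because the simulations are the expensive part; every test
that needs a recording reuses these.
"""

from __future__ import annotations

import pytest

from sdecog import classify_events, detect_recording, simulate_recording
from sdecog.cohorts import (
    scenario_nsd_recovery,
    scenario_nsd_terminal,
    scenario_sd,
    scenario_sd_with_seizure,
    scenario_severe_sd_brainstem,
    scenario_sham,
    scenario_triggered_sd,
)

# The five canonical morphologies: bilateral SD, SD with peri-SD seizure,
# severe SD reaching the brainstem, NSD with recovery, NSD with terminal SD.
CANONICAL_SCENARIOS = {
    "sd_bilateral": (scenario_sd, {"seed": 101}, {"SD"}, True),
    "sd_seizure": (scenario_sd_with_seizure, {"seed": 102}, {"SD", "seizure"}, True),
    "sd_brainstem": (scenario_severe_sd_brainstem, {"seed": 103}, {"SD"}, True),
    "nsd_recovery": (scenario_nsd_recovery, {"seed": 104}, {"NSD"}, True),
    "nsd_terminal": (scenario_nsd_terminal, {"seed": 105}, {"NSD", "terminal_SD"}, False),
    "sham": (scenario_sham, {"seed": 106}, set(), True),
}


@pytest.fixture(scope="session")
def canonical():
    """name -> dict(recording, truth, detections, calls, outcome,
    expected_types, expected_survived)."""
    out = {}
    for name, (builder, kwargs, expected_types, survived) in CANONICAL_SCENARIOS.items():
        cfg = builder(**kwargs)
        rec, truth = simulate_recording(cfg)
        det = detect_recording(rec)
        calls, outcome = classify_events(det, rec.layout)
        out[name] = {
            "config": cfg,
            "recording": rec,
            "truth": truth,
            "detections": det,
            "calls": calls,
            "outcome": outcome,
            "expected_types": expected_types,
            "expected_survived": survived,
        }
    return out


@pytest.fixture(scope="session")
def sd_noisefree():
    """Noise-free bilateral SD (1.5 mV, 60 s) with its truth log and calls."""
    cfg = scenario_sd(latency_s=124.0, amplitude_mv=1.5, rms_mv=0.0, seed=0)
    rec, truth = simulate_recording(cfg)
    det = detect_recording(rec)
    calls, outcome = classify_events(det, rec.layout)
    return {"config": cfg, "recording": rec, "truth": truth,
            "detections": det, "calls": calls, "outcome": outcome}


@pytest.fixture(scope="session")
def triggered_noisefree():
    """Noise-free electrically triggered SD (0.26 mV) along a 4 mm path."""
    cfg = scenario_triggered_sd()
    rec, truth = simulate_recording(cfg)
    det = detect_recording(rec)
    calls, outcome = classify_events(det, rec.layout)
    return {"config": cfg, "recording": rec, "truth": truth,
            "detections": det, "calls": calls, "outcome": outcome}
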