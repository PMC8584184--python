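"""Generator unit and property tests: SD template geometry, propagation
geometry, amplifier response, reproducibility, depression modulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdecog import (
    AmplifierSpec,
    BackgroundSpec,
    Electrode,
    ElectrodeLayout,
    NSDEventSpec,
    ParameterError,
    SDEventSpec,
    SimulationConfig,
    apply_amplifier,
    bilateral_layout,
    propagate_onsets,
    sd_waveform,
    simulate_recording,
)
from sdecog.cohorts import scenario_nsd_recovery, scenario_sd
from sdecog.signals import bandpass_ac


class TestSDWaveform:
    def test_rejects_degenerate_parameters(self):
        t = np.arange(0, 10, 0.01)
        with pytest.raises(ParameterError):
            sd_waveform(0.0, 60.0, 1.0, t)
        with pytest.raises(ParameterError):
            sd_waveform(-1.0, 60.0, 1.0, t)
        with pytest.raises(ParameterError):
            sd_waveform(1.0, 0.0, 1.0, t)

    def test_template_geometry_on_dense_grid(self):
        # 1 ms grid; width at half recovery measured independently by
        # counting samples at or below half amplitude
        t = np.arange(0.0, 300.0, 0.001)
        y = sd_waveform(1.5, 60.0, 50.0, t)
        assert y.min() == pytest.approx(-1.5)
        assert np.all(y[t < 50.0] == 0.0)
        assert np.all(np.abs(y[t > 50.0 + 60.0 + 20.0]) < 1e-12)
        fwhm = np.sum(y <= -0.75) * 0.001
        assert fwhm == pytest.approx(60.0, abs=0.01)
        # smooth: no jump exceeding the steepest raised-cosine step
        max_step = 1.5 / 2 * np.pi / 10.0 * 0.001  # A/2 * pi/ramp * dt
        assert np.max(np.abs(np.diff(y))) <= max_step * 1.01

    def test_terminal_template_never_recovers(self):
        t = np.arange(0.0, 200.0, 0.01)
        y = sd_waveform(1.0, 60.0, 20.0, t, recover=False)
        assert y[-1] == pytest.approx(-1.0)
        assert np.all(y[t >= 30.0] == pytest.approx(-1.0))


class TestPropagation:
    def test_channel_at_origin_onsets_at_event_time(self):
        layout = ElectrodeLayout([Electrode("a", 1.0, -2.0)])
        ev = SDEventSpec(onset_s=30.0, origin=(1.0, -2.0))
        assert propagate_onsets(ev, layout)["a"] == pytest.approx(30.0)

    def test_four_mm_at_four_mm_per_min_lags_one_minute(self):
        layout = ElectrodeLayout([Electrode("a", 0.0, 0.0), Electrode("b", 4.0, 0.0)])
        ev = SDEventSpec(onset_s=10.0, origin=(0.0, 0.0), velocity_mm_per_min=4.0)
        on = propagate_onsets(ev, layout)
        assert on["b"] - on["a"] == pytest.approx(60.0)

    def test_unreachable_channel_marked(self):
        layout = ElectrodeLayout([Electrode("far", 100.0, 0.0)])
        ev = SDEventSpec(onset_s=0.0, origin=(0.0, 0.0), velocity_mm_per_min=4.0)
        assert propagate_onsets(ev, layout, t_end_s=60.0)["far"] == np.inf

    @settings(derandomize=True, max_examples=50)
    @given(
        xs=st.lists(st.floats(-10, 10), min_size=1, max_size=5),
        ys=st.lists(st.floats(-10, 10), min_size=1, max_size=5),
        vel=st.floats(0.5, 20.0),
        ox=st.floats(-5, 5),
        oy=st.floats(-5, 5),
    )
    def test_lag_times_velocity_equals_distance(self, xs, ys, vel, ox, oy):
        chans = [Electrode(f"c{i}", x, y) for i, (x, y) in enumerate(zip(xs, ys))]
        layout = ElectrodeLayout(chans)
        ev = SDEventSpec(onset_s=5.0, origin=(ox, oy), velocity_mm_per_min=vel)
        for ch in chans:
            lag = propagate_onsets(ev, layout)[ch.name] - 5.0
            dist = np.hypot(ch.x_mm - ox, ch.y_mm - oy)
            assert lag * vel / 60.0 == pytest.approx(dist, abs=1e-9)


class TestAmplifier:
    def test_zero_in_zero_out(self):
        spec = AmplifierSpec()
        out = apply_amplifier(np.zeros(5000), spec)
        assert np.allclose(out, 0.0)

    def test_step_response_matches_first_order_highpass(self):
        # closed form: first-order high-pass response to a unit step decays
        # as exp(-2*pi*fc*t); at t = 1/(2*pi*fc) it equals e^-1
        spec = AmplifierSpec()
        fs = spec.fs_hz
        x = np.zeros(int(20 * fs))
        x[int(fs):] = -1.0
        out = apply_amplifier(x, spec)
        t_e = 1.0 / (2 * np.pi * spec.highpass_hz)
        i = int(fs) + int(round(t_e * fs))
        assert out[i] == pytest.approx(-np.exp(-1.0), abs=5e-3)

    def test_notch_attenuates_60_hz_tenfold(self):
        spec = AmplifierSpec()
        fs = spec.fs_hz
        t = np.arange(int(30 * fs)) / fs
        for f, should_pass in ((60.0, False), (10.0, True)):
            out = apply_amplifier(np.sin(2 * np.pi * f * t), spec)
            rms = np.sqrt(np.mean(out[int(10 * fs):] ** 2))  # steady state
            if should_pass:
                ref = rms
        assert ref > 0.6  # pass band ~ 1/sqrt(2)
        out60 = apply_amplifier(np.sin(2 * np.pi * 60.0 * t), spec)
        rms60 = np.sqrt(np.mean(out60[int(10 * fs):] ** 2))
        assert rms60 * 10 < ref

    def test_invalid_band_rejected(self):
        with pytest.raises(ParameterError):
            AmplifierSpec(highpass_hz=200.0, lowpass_hz=100.0)


class TestSimulateRecording:
    def test_no_events_yields_background_only(self):
        cfg = SimulationConfig(
            layout=bilateral_layout(),
            amplifier=AmplifierSpec(fs_hz=250.0),
            background=BackgroundSpec(rms_mv=0.0),
            events=(),
            total_duration_s=120.0,
            marker_s=60.0,
            seed=0,
        )
        rec, log = simulate_recording(cfg)
        assert np.allclose(rec.traces, 0.0)
        assert log.events == []

    def test_bit_reproducible_under_fixed_seed(self):
        cfg = scenario_sd(latency_s=30.0, post_s=180.0, seed=42)
        rec1, log1 = simulate_recording(cfg)
        rec2, log2 = simulate_recording(cfg)
        assert np.array_equal(rec1.traces, rec2.traces)
        assert log1.events == log2.events

    def test_truth_log_matches_injected_specs(self):
        cfg = scenario_sd(latency_s=45.0, amplitude_mv=1.2, post_s=300.0, seed=7)
        _, log = simulate_recording(cfg)
        (ev,) = log.events
        spec = cfg.events[0]
        assert ev["type"] == "SD"
        assert ev["amplitude_mv"] == spec.amplitude_mv
        assert ev["duration_s"] == spec.duration_s
        assert ev["velocity_mm_per_min"] == spec.velocity_mm_per_min
        onsets = propagate_onsets(spec, cfg.layout)
        assert ev["per_channel_onset_s"] == pytest.approx(onsets)

    def test_only_one_terminal_episode_allowed(self):
        nsd = NSDEventSpec(onset_s=40.0, recovery=False, recovery_delay_s=None,
                           terminal_sd_delay_s=100.0)
        sd_terminal = SDEventSpec(onset_s=300.0, recovery=False)
        with pytest.raises(ParameterError):
            SimulationConfig(
                layout=bilateral_layout(brainstem=True),
                amplifier=AmplifierSpec(fs_hz=250.0),
                events=(nsd, sd_terminal),
                total_duration_s=600.0,
                marker_s=60.0,
            )

    def test_depression_modulates_ac_rms_by_fraction(self):
        # noise-free modulation check: AC-band RMS inside/outside the
        # depression interval recovers the depression fraction
        frac = 0.2
        cfg = scenario_nsd_recovery(latency_s=60.0, recovery_delay_s=120.0, seed=3)
        cfg = SimulationConfig(
            layout=cfg.layout, amplifier=cfg.amplifier,
            background=cfg.background,
            events=(NSDEventSpec(onset_s=60.0, recovery_delay_s=120.0,
                                 depression_fraction=frac),),
            total_duration_s=cfg.total_duration_s, marker_s=cfg.marker_s, seed=3,
        )
        rec, _ = simulate_recording(cfg)
        ac = bandpass_ac(rec)
        fs = rec.fs_hz
        m = rec.marker_s
        inside = ac[0, int((m + 70) * fs):int((m + 170) * fs)]
        outside = ac[0, int((m + 250) * fs):int((m + 350) * fs)]
        ratio = np.sqrt(np.mean(inside**2) / np.mean(outside**2))
        assert ratio == pytest.approx(frac, abs=0.05)

    def test_background_band_energy_scales_with_rms_squared(self):
        energies = []
        for rms in (0.05, 0.1):
            cfg = SimulationConfig(
                layout=bilateral_layout(),
                amplifier=AmplifierSpec(fs_hz=250.0),
                background=BackgroundSpec(rms_mv=rms),
                total_duration_s=240.0,
                marker_s=60.0,
                seed=11,
            )
            rec, _ = simulate_recording(cfg)
            ac = bandpass_ac(rec)
            energies.append(np.mean(ac**2))
        assert energies[1] / energies[0] == pytest.approx(4.0, rel=1e-6)
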