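"""Event-taxonomy tests: NSD vs spreading SD, terminal SD and death labels,
velocity estimation, and cohort prevalence."""

import pytest

from sdecog import (
    ChannelDetection,
    Electrode,
    ElectrodeLayout,
    EventCall,
    OutcomeLabel,
    ParameterError,
    SimultaneityError,
    classify_events,
    detect_recording,
    estimate_velocity,
    prevalence,
    simulate_recording,
)
from sdecog.cohorts import scenario_sd, scenario_triggered_sd


def _two_channel_layout(sep_mm=4.0):
    return ElectrodeLayout(
        [Electrode("a", 0.0, 0.0), Electrode("b", sep_mm, 0.0)]
    )


class TestClassification:
    def test_empty_detections_no_calls_survived(self):
        det = {"cortexL": ChannelDetection("cortexL"), "cortexR": ChannelDetection("cortexR")}
        from sdecog import bilateral_layout

        calls, outcome = classify_events(det, bilateral_layout())
        assert calls == []
        assert outcome.survived

    def test_confusion_matrix_identity_on_canonical_suite(self, canonical):
        """Injected and called event types agree 1:1 on all five
        canonical morphologies (and the sham control)."""
        for name, data in canonical.items():
            called = sorted(c.type for c in data["calls"])
            injected = sorted(e["type"] for e in data["truth"].events)
            assert called == injected, name
            assert data["outcome"].survived == data["expected_survived"], name

    def test_spreading_sd_has_lagged_onsets_and_velocity(self, canonical):
        (sd,) = [c for c in canonical["sd_bilateral"]["calls"] if c.type == "SD"]
        assert sd.spread == "spreading"
        lags = sd.per_channel_onset_s
        assert lags["cortexR"] - lags["cortexL"] == pytest.approx(90.0, abs=2.0)
        assert sd.velocity_mm_per_min == pytest.approx(4.0, rel=0.05)

    def test_nsd_is_simultaneous_and_survives(self, canonical):
        (nsd,) = canonical["nsd_recovery"]["calls"]
        assert nsd.type == "NSD"
        assert nsd.spread == "simultaneous"
        assert nsd.recovered
        assert canonical["nsd_recovery"]["outcome"].survived

    def test_terminal_sequence_labels_death(self, canonical):
        calls = canonical["nsd_terminal"]["calls"]
        types = [c.type for c in calls]
        assert types == ["NSD", "terminal_SD"]
        assert not calls[0].recovered
        assert not calls[1].recovered
        outcome = canonical["nsd_terminal"]["outcome"]
        assert not outcome.survived
        assert outcome.cause == "NSD_terminal_SD"

    def test_terminal_event_call_invariant(self):
        with pytest.raises(ParameterError):
            EventCall(type="terminal_SD", channels=["a"], per_channel_onset_s={"a": 1.0},
                      latency_s=1.0, recovered=True)
        with pytest.raises(ParameterError):
            OutcomeLabel(survived=True, cause="NSD_terminal_SD")


class TestVelocity:
    def test_four_mm_sixty_seconds_gives_four_mm_per_min(self):
        call = EventCall(type="SD", channels=["a", "b"],
                         per_channel_onset_s={"a": 100.0, "b": 160.0},
                         latency_s=100.0, spread="spreading")
        v = estimate_velocity(call, _two_channel_layout(4.0))
        assert v == pytest.approx(4.0)

    def test_zero_lag_raises_simultaneity_error(self):
        call = EventCall(type="SD", channels=["a", "b"],
                         per_channel_onset_s={"a": 100.0, "b": 100.0},
                         latency_s=100.0)
        with pytest.raises(SimultaneityError):
            estimate_velocity(call, _two_channel_layout(4.0))

    def test_single_channel_rejected(self):
        call = EventCall(type="SD", channels=["a"], per_channel_onset_s={"a": 1.0},
                         latency_s=1.0)
        with pytest.raises(ParameterError):
            estimate_velocity(call, _two_channel_layout())

    @pytest.mark.parametrize("velocity", [2.0, 3.5, 5.0, 8.0])
    def test_simulated_velocities_recovered_noise_free(self, velocity):
        cfg = scenario_triggered_sd(
            latency_s=30.0, velocity_mm_per_min=velocity, post_s=500.0,
        )
        rec, _ = simulate_recording(cfg)
        det = detect_recording(rec)
        calls, _ = classify_events(det, rec.layout)
        (sd,) = [c for c in calls if c.type == "SD"]
        assert sd.velocity_mm_per_min == pytest.approx(velocity, rel=0.05)

    def test_origin_anchor_matches_pairwise_estimate(self):
        call = EventCall(type="SD", channels=["a", "b"],
                         per_channel_onset_s={"a": 60.0, "b": 120.0},
                         latency_s=60.0, spread="spreading")
        layout = _two_channel_layout(4.0)
        v_anchor = estimate_velocity(call, layout, origin_xy=(-4.0, 0.0), origin_onset_s=0.0)
        assert v_anchor == pytest.approx(4.0, rel=1e-6)


class TestPrevalence:
    def _cohort(self, n_sd, n_total):
        sd_call = EventCall(type="SD", channels=["cortexL"],
                            per_channel_onset_s={"cortexL": 100.0}, latency_s=100.0)
        cohort = [([sd_call], OutcomeLabel()) for _ in range(n_sd)]
        cohort += [([], OutcomeLabel()) for _ in range(n_total - n_sd)]
        return cohort

    def test_counts_recordings_with_sd(self):
        table = prevalence(self._cohort(37, 71), label="mild")
        assert table.n_impacts == 71
        assert table.n_SD == 37

    def test_empty_cohort_errors(self):
        with pytest.raises(ParameterError):
            prevalence([])

    def test_brainstem_site_filter(self):
        bs_call = EventCall(type="SD", channels=["brainstem"],
                            per_channel_onset_s={"brainstem": 50.0}, latency_s=50.0)
        cohort = self._cohort(2, 5) + [([bs_call], OutcomeLabel())]
        assert prevalence(cohort, site="cortex").n_SD == 2
        assert prevalence(cohort, site="brainstem").n_SD == 1

    def test_injected_prevalence_recovered_exactly(self):
        """Small simulated cohort: detected prevalence equals injected."""
        cohort = []
        for i in range(3):
            cfg = scenario_sd(latency_s=60.0, post_s=300.0, seed=200 + i)
            rec, _ = simulate_recording(cfg)
            det = detect_recording(rec)
            cohort.append(classify_events(det, rec.layout))
        from sdecog.cohorts import scenario_sham

        for i in range(2):
            cfg = scenario_sham(seed=300 + i, post_s=300.0)
            rec, _ = simulate_recording(cfg)
            det = detect_recording(rec)
            cohort.append(classify_events(det, rec.layout))
        table = prevalence(cohort, label="mini")
        assert table.n_SD == 3
        assert table.n_impacts == 5
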