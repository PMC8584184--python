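"""Oxidative-stress scoring tests: MitoSOX thresholding, high-ROS fractions,
ABTS/Trolox capacity, and 2^-ddCt fold changes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdecog import ParameterError
from sdecog.oxidative import (
    CellIntensityTable,
    QPCRTable,
    antioxidant_capacity,
    ddct_fold_change,
    high_ros_fraction,
    high_ros_threshold,
    measure_lag_time,
    simulate_antioxidant_run,
    simulate_cell_intensities,
    simulate_qpcr_table,
)


class TestHighROSThreshold:
    def test_uniform_1_to_100(self):
        # independently: median 50.5; 5th percentile by linear interpolation
        # of sorted values = 1 + 0.05 * 99 = 5.95; threshold 95.05
        x = np.arange(1.0, 101.0)
        thr = high_ros_threshold(x)
        assert thr == pytest.approx(95.05)
        assert int((x >= thr).sum()) == 5

    def test_all_equal_scores_every_cell_high(self):
        x = np.full(50, 7.0)
        thr = high_ros_threshold(x)
        assert thr == 7.0
        assert np.all(x >= thr)

    def test_empty_errors_small_warns(self):
        with pytest.raises(ParameterError):
            high_ros_threshold([])
        with pytest.warns(UserWarning):
            high_ros_threshold(np.arange(5.0))

    @settings(derandomize=True, max_examples=50)
    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
        seed=st.integers(0, 100),
    )
    def test_translation_and_scale_equivariance(self, shift, scale, seed):
        x = np.random.default_rng(seed).lognormal(4.0, 0.5, 100)
        thr = high_ros_threshold(x)
        assert high_ros_threshold(x + shift) == pytest.approx(thr + shift, rel=1e-9, abs=1e-9)
        assert high_ros_threshold(x * scale) == pytest.approx(thr * scale, rel=1e-9)


class TestHighROSFraction:
    def test_fraction_monotonic_in_high_ros_proportion(self):
        fracs = []
        for q in (0.0, 0.05, 0.1, 0.2, 0.3):
            tab = simulate_cell_intensities(
                n_animals=3, high_ros_proportion=q, seed=7
            )
            _, per_animal = high_ros_fraction(tab)
            fracs.append(per_animal.mean())
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_all_cells_below_threshold_fraction_zero(self):
        # a left-skewed distribution: the lower tail pushes the threshold
        # above the maximum, so no cell scores high-ROS
        rng = np.random.default_rng(0)
        cells = pd.DataFrame({
            "animal": "a1", "region": "r1",
            "intensity": 100.0 - rng.exponential(5.0, 100),
        })
        dapi = pd.DataFrame([{"animal": "a1", "region": "r1", "dapi_total": 100}])
        regions, _ = high_ros_fraction(CellIntensityTable(cells, dapi))
        assert regions.loc[0, "n_high"] == 0
        assert regions.loc[0, "fraction"] == 0.0

    def test_dapi_total_divisor(self):
        cells = pd.DataFrame({
            "animal": "a1", "region": "r1", "intensity": np.arange(1.0, 101.0),
        })
        dapi = pd.DataFrame([{"animal": "a1", "region": "r1", "dapi_total": 200}])
        regions, per_animal = high_ros_fraction(CellIntensityTable(cells, dapi))
        assert regions.loc[0, "fraction"] == pytest.approx(5 / 200)
        assert per_animal["a1"] == pytest.approx(5 / 200)

    def test_dapi_smaller_than_measured_rejected(self):
        cells = pd.DataFrame({
            "animal": "a1", "region": "r1", "intensity": np.ones(30),
        })
        dapi = pd.DataFrame([{"animal": "a1", "region": "r1", "dapi_total": 10}])
        with pytest.raises(ParameterError):
            CellIntensityTable(cells, dapi)


class TestAntioxidantCapacity:
    def test_noiseless_exact_recovery(self):
        run = simulate_antioxidant_run(capacity_true=150.0)
        res = antioxidant_capacity(run)
        assert res.capacity == pytest.approx(150.0, rel=0.02)
        assert not res.extrapolated

    def test_sample_equal_to_standard_is_fixed_point(self):
        run = simulate_antioxidant_run(capacity_true=100.0)
        run.sample_lag_s = dict(run.standards)[100.0]
        res = antioxidant_capacity(run)
        assert res.capacity == pytest.approx(100.0, rel=1e-9)

    def test_extrapolation_flagged(self):
        run = simulate_antioxidant_run(capacity_true=100.0)
        run.sample_lag_s = 1.0  # below the lowest standard lag
        assert antioxidant_capacity(run).extrapolated

    def test_non_increasing_standards_rejected(self):
        run = simulate_antioxidant_run(capacity_true=100.0)
        run.standards = [(c, 100.0 - 0.1 * c) for c, _ in run.standards]
        with pytest.raises(ParameterError):
            antioxidant_capacity(run)

    def test_recovery_within_ten_percent_at_five_percent_lag_noise(self):
        errors = []
        for seed in range(8):
            run = simulate_antioxidant_run(
                capacity_true=200.0, lag_noise_frac=0.05, seed=seed
            )
            res = antioxidant_capacity(run)
            errors.append(abs(res.capacity - 200.0) / 200.0)
        assert np.median(errors) < 0.10

    def test_lag_interpolates_between_samples(self):
        t = np.array([0.0, 10.0, 20.0, 30.0])
        a = np.array([0.0, 0.0, 1.0, 1.0])
        # 10% of rise crossed at 10 + 0.1 * 10
        assert measure_lag_time(t, a) == pytest.approx(11.0)


class TestDdct:
    def test_hand_computed_example(self):
        # treated sample: Ct gene 26, Ct ref 20 -> dCt 6; control mean dCt 5
        # -> ddCt 1 -> fold 0.5
        rows = [
            {"sample": "c1", "group": "ctl", "gene": "18S", "ct": 20.0},
            {"sample": "c1", "group": "ctl", "gene": "g", "ct": 25.0},
            {"sample": "t1", "group": "tbi", "gene": "18S", "ct": 20.0},
            {"sample": "t1", "group": "tbi", "gene": "g", "ct": 26.0},
        ]
        res = ddct_fold_change(QPCRTable(pd.DataFrame(rows)), "ctl")
        t1 = res[res["sample"] == "t1"].iloc[0]
        assert t1["ddct"] == pytest.approx(1.0)
        assert t1["fold_change"] == pytest.approx(0.5)

    def test_control_group_mean_fold_is_one(self):
        table = simulate_qpcr_table(ct_noise_sd=0.3, seed=4)
        res = ddct_fold_change(table, "control")
        for _, g in res[res["group"] == "control"].groupby("gene"):
            assert g["ddct"].mean() == pytest.approx(0.0, abs=1e-9)
            assert np.exp(np.log(g["fold_change"]).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_known_halving_recovered_regardless_of_reference_level(self):
        for ref_ct in (12.0, 18.0, 25.0):
            table = simulate_qpcr_table(
                genes_fold={"SOD1": 0.5}, ref_ct_mean=ref_ct, seed=1
            )
            res = ddct_fold_change(table, "control")
            treated = res[(res["group"] == "TBI")]
            assert treated["fold_change"].mean() == pytest.approx(0.5, rel=1e-9)

    def test_per_sample_ct_offset_cancels(self):
        table = simulate_qpcr_table(ct_noise_sd=0.2, seed=2)
        res1 = ddct_fold_change(table, "control")
        shifted = table.data.copy()
        # add a sample-specific constant to every Ct (loading difference)
        offsets = {s: o for s, o in zip(
            shifted["sample"].unique(),
            np.linspace(-2, 2, shifted["sample"].nunique()),
        )}
        shifted["ct"] = shifted["ct"] + shifted["sample"].map(offsets)
        res2 = ddct_fold_change(QPCRTable(shifted), "control")
        assert np.allclose(res1["fold_change"], res2["fold_change"])

    def test_missing_reference_rejected(self):
        rows = [
            {"sample": "c1", "group": "ctl", "gene": "g", "ct": 25.0},
        ]
        with pytest.raises(ParameterError):
            QPCRTable(pd.DataFrame(rows))
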