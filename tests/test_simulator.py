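"""Synthetic stream/cohort generators and the bundled cohort table."""

import numpy as np
import pandas as pd
import pytest

from gsrstress import (
    ADC_SCALE,
    CohortConfig,
    ConfigError,
    KalmanParams,
    SimulatorConfig,
    StressLevel,
    classify,
    derive_profile,
    load_table2_fixture,
    simulate_cohort,
    simulate_subject_stream,
)
from gsrstress.simulator import TABLE2_BANDS


class TestSubjectStream:
    def test_quiet_config_gives_constant_baseline(self):
        """No noise, no SCRs, no drift: the stream is flat at baseline."""
        cfg = SimulatorConfig(
            seed=0, duration_s=10.0, noise_sd=0.0, scr_rate_per_min=0.0,
            drift_per_min=0.0, baseline_adc12=1200.0,
        )
        stream = simulate_subject_stream(cfg)
        assert np.all(stream.adc12 == 1200)
        assert np.allclose(stream.clean, 1200.0)

    def test_determinism(self):
        cfg = SimulatorConfig(seed=42, duration_s=30.0, noise_sd=15.0)
        a = simulate_subject_stream(cfg)
        b = simulate_subject_stream(cfg)
        assert np.array_equal(a.adc12, b.adc12)
        assert np.array_equal(a.clean, b.clean)
        assert np.array_equal(a.labels, b.labels)

    def test_different_seeds_differ(self):
        a = simulate_subject_stream(SimulatorConfig(seed=1, duration_s=30.0))
        b = simulate_subject_stream(SimulatorConfig(seed=2, duration_s=30.0))
        assert not np.array_equal(a.adc12, b.adc12)

    def test_noise_mean_clt_bound(self):
        """Mean of (samples - clean) over 10^4 points stays within the
        3-sigma CLT band around zero."""
        cfg = SimulatorConfig(
            seed=7, duration_s=1000.0, noise_sd=10.0, scr_rate_per_min=0.0,
        )
        stream = simulate_subject_stream(cfg)
        n = len(stream)
        assert n == 10_000
        residual_mean = float((stream.adc12 - stream.clean).mean())
        assert abs(residual_mean) <= 3.0 * cfg.noise_sd / 100.0 + 0.05  # + rounding

    def test_sample_invariants(self, scheduled_config):
        stream = simulate_subject_stream(scheduled_config(seed=3))
        assert len(stream.adc12) == len(stream.clean) == len(stream.labels)
        assert stream.adc12.min() >= 0 and stream.adc12.max() <= 4095
        assert np.all(np.diff(stream.t_ms) > 0)

    def test_schedule_labels_match_intervals(self, scheduled_config):
        stream = simulate_subject_stream(scheduled_config(seed=0))
        t_s = stream.t_ms / 1000.0
        assert np.all(stream.labels[t_s < 30.0] == int(StressLevel.NO_STRESS))
        in_minor = (t_s >= 30.0) & (t_s < 60.0)
        assert np.all(stream.labels[in_minor] == int(StressLevel.MINOR))
        assert np.all(stream.labels[t_s >= 90.0] == int(StressLevel.VERY_HIGH))

    def test_schedule_outside_duration_rejected(self):
        with pytest.raises(ConfigError, match="inside"):
            SimulatorConfig(
                duration_s=60.0,
                stress_schedule=((50.0, 70.0, StressLevel.HIGH),),
            )

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            SimulatorConfig(
                duration_s=60.0,
                stress_schedule=(
                    (0.0, 30.0, StressLevel.MINOR),
                    (20.0, 40.0, StressLevel.HIGH),
                ),
            )

    def test_physiological_direction_default_config(self):
        """Mean clean signal under HIGH stress exceeds the resting mean on
        every seeded trial."""
        for seed in range(50):
            cfg = SimulatorConfig(
                seed=seed, duration_s=60.0, noise_sd=0.0,
                stress_schedule=((30.0, 60.0, StressLevel.HIGH),),
            )
            stream = simulate_subject_stream(cfg)
            hi = stream.clean[stream.labels == int(StressLevel.HIGH)].mean()
            rest = stream.clean[stream.labels == int(StressLevel.NO_STRESS)].mean()
            assert hi > rest

    def test_physiological_direction_rate_only(self):
        """With the tonic term zeroed, the SCR-rate scaling alone still
        elevates the mean during stress (phasic channel)."""
        flat_tonic = {lv: 0.0 for lv in StressLevel}
        for seed in range(50):
            cfg = SimulatorConfig(
                seed=seed, duration_s=120.0, noise_sd=0.0,
                scr_rate_per_min=12.0, scr_amplitude=20.0, scr_decay_s=5.0,
                tonic_norm=flat_tonic,
                stress_schedule=((60.0, 120.0, StressLevel.HIGH),),
            )
            stream = simulate_subject_stream(cfg)
            hi = stream.clean[stream.labels == int(StressLevel.HIGH)].mean()
            rest = stream.clean[stream.labels == int(StressLevel.NO_STRESS)].mean()
            assert hi > rest

    def test_csv_round_trip(self, tmp_path, scheduled_config):
        from gsrstress import read_stream_csv

        stream = simulate_subject_stream(scheduled_config(seed=5))
        path = tmp_path / "stream.csv"
        stream.to_csv(path)
        samples = read_stream_csv(path)
        assert len(samples) == len(stream)
        assert samples[0].adc12 == int(stream.adc12[0])

    def test_derive_profile_anchors_resting_level(self):
        """The derived b_min sits close to the resting tonic level on the
        10-bit scale, and b_max spans the configured dynamic range."""
        cfg = SimulatorConfig(seed=11, duration_s=60.0, noise_sd=10.0)
        stream = simulate_subject_stream(cfg)
        e = cfg.noise_sd * ADC_SCALE
        profile = derive_profile(stream, KalmanParams(e_m=e, e_p0=e, q=0.25 * e), 30.0)
        truth = cfg.ground_truth_profile()
        assert profile.b_min == pytest.approx(truth.b_min, abs=2.0)
        assert profile.b_max - profile.b_min == pytest.approx(
            truth.b_max - truth.b_min, rel=1e-12
        )


class TestCohort:
    def test_record_count_640(self):
        values, labels = simulate_cohort(CohortConfig(n_subjects=32, samples_per_subject=20))
        assert values.size == 640
        assert labels.shape == values.shape

    def test_single_record(self):
        values, _ = simulate_cohort(CohortConfig(n_subjects=1, samples_per_subject=1, seed=3))
        assert values.size == 1

    def test_determinism(self):
        a, _ = simulate_cohort(CohortConfig(seed=9))
        b, _ = simulate_cohort(CohortConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_draws_classify_back_to_assigned_band(self):
        """Uniform in-band draws must classify into the band that labelled
        them."""
        values, labels = simulate_cohort(CohortConfig(seed=17))
        for col in values.columns:
            assigned = labels[col].iloc[0]
            for v in values[col]:
                assert classify(v).label == assigned

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_subjects=0)
        with pytest.raises(ConfigError):
            CohortConfig(samples_per_subject=0)


class TestBundledTable:
    def test_shape_and_columns(self):
        table = load_table2_fixture()
        assert list(table.columns) == [f"Person {i}" for i in range(1, 17)]
        assert len(table) == 14

    @pytest.mark.parametrize(
        "col, row, value",
        [("Person 1", 0, 432), ("Person 16", 0, 175), ("Person 4", 9, 140)],
    )
    def test_printed_values(self, col, row, value):
        assert load_table2_fixture()[col].iloc[row] == value

    def test_ragged_columns(self):
        """Persons 1-4 carry 14 readings; Persons 5-16 carry 13."""
        table = load_table2_fixture()
        for i in range(1, 5):
            assert table[f"Person {i}"].notna().sum() == 14
        for i in range(5, 17):
            assert table[f"Person {i}"].notna().sum() == 13

    def test_band_layout_cycles_every_four(self):
        assert TABLE2_BANDS["Person 1"] is StressLevel.VERY_HIGH
        assert TABLE2_BANDS["Person 6"] is StressLevel.HIGH
        assert TABLE2_BANDS["Person 11"] is StressLevel.MINOR
        assert TABLE2_BANDS["Person 16"] is StressLevel.NO_STRESS
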