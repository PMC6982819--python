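"""Trial generation, sensor corruption, and trial I/O."""

import numpy as np
import pytest

from comgait.synthetic_data import (
    LABEL_CHANNELS,
    CohortSpec,
    GenerationError,
    ImuTrial,
    NoiseModel,
    corrupt_to_imu,
    generate_cohort,
    generate_walking_trial,
    read_trial,
    trial_io,
    write_trial,
)
from comgait.synthetic_data.trial import TrialFormatError


class TestGenerator:
    def test_determinism(self, soft_params, moderate_trial):
        again = generate_walking_trial(soft_params, speed=1.42, n_steps=12, seed=3)
        assert np.array_equal(moderate_trial.ax, again.ax)
        assert np.array_equal(moderate_trial.ay, again.ay)
        assert np.array_equal(moderate_trial.truth.hs_t, again.truth.hs_t)

    def test_different_seed_differs(self, soft_params, moderate_trial):
        other = generate_walking_trial(soft_params, speed=1.42, n_steps=12, seed=4)
        assert not np.array_equal(moderate_trial.ay, other.ay)

    def test_n_steps_rows(self, soft_params):
        trial = generate_walking_trial(soft_params, speed=1.3, n_steps=10, seed=1)
        assert len(trial.truth) == 10
        assert len(trial.truth.hs_t) == 10 and len(trial.truth.to_t) == 10

    def test_event_ordering(self, moderate_trial):
        tr = moderate_trial.truth
        assert np.all(tr.apex_t < tr.hs_t)
        assert np.all(tr.hs_t < tr.to_t)

    def test_mean_forward_speed_within_2_percent(self, moderate_trial):
        com = moderate_trial.com
        t = moderate_trial.t
        mean_v = (com[-1, 0] - com[0, 0]) / (t[-1] - t[0])
        assert abs(mean_v - moderate_trial.speed) <= 0.02 * moderate_trial.speed

    def test_labels_shape_and_finiteness(self, moderate_trial):
        lab = moderate_trial.labels
        assert lab.values.shape[0] == len(LABEL_CHANNELS) == 11
        assert np.all(np.isfinite(lab.values))
        assert len(lab.steps) == len(moderate_trial.truth)

    def test_step_label_windows_match_truth(self, moderate_trial):
        tr = moderate_trial.truth
        # step blocks cover the stance of the round that recorded their TO
        for step in moderate_trial.labels.steps:
            assert step.t[-1] - step.t[0] > 0.3  # a stance, not a transition
            assert np.any(np.isclose(tr.to_t, step.t[-1], atol=0.01))

    def test_grfy_label_nonnegative_and_zero_at_edges(self, moderate_trial):
        for step in moderate_trial.labels.steps:
            fy = step.values[LABEL_CHANNELS.index("GRFy")]
            assert fy.min() >= -1e-9
            # edges fall on the first grid sample at/after the event, so
            # the transfer ramp has advanced by less than one sample
            assert fy[0] <= 0.01 * fy.max() and fy[-1] <= 0.01 * fy.max()

    def test_unstable_gait_raises(self, soft_params):
        from comgait.synthetic_data import GaitShape

        # absurd impact amplitude drives the integrated height oscillation
        # past the fall threshold
        shape = GaitShape(hs_impact_amp=4000.0)
        with pytest.raises(GenerationError, match="step"):
            generate_walking_trial(
                soft_params, speed=1.42, n_steps=8, seed=0, shape=shape
            )

    def test_bad_n_steps(self, soft_params):
        with pytest.raises(ValueError):
            generate_walking_trial(soft_params, speed=1.4, n_steps=1, seed=0)


class TestCohort:
    def test_layout(self, small_cohort):
        assert len(small_cohort) == 9  # 3 subjects x 3 speeds
        subjects = {t.subject_id for t in small_cohort}
        speeds = {t.speed_label for t in small_cohort}
        assert subjects == {"S1", "S2", "S3"}
        assert speeds == {"slow", "moderate", "fast"}

    def test_subject_heterogeneity(self, small_cohort):
        heights = {t.subject_id: t.height for t in small_cohort}
        assert len(set(heights.values())) == 3

    def test_cohort_determinism(self):
        a = generate_cohort(CohortSpec(n_subjects=2, n_steps=6, seed=5))
        b = generate_cohort(CohortSpec(n_subjects=2, n_steps=6, seed=5))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.ay, tb.ay)


class TestNoise:
    def test_zero_noise_identity(self, moderate_trial):
        out = corrupt_to_imu(moderate_trial, NoiseModel(0.0, 0.0, 0.0, seed=0))
        assert out is moderate_trial

    def test_constant_bias_closed_form(self, moderate_trial):
        b = 0.2
        out = corrupt_to_imu(
            moderate_trial, NoiseModel(0.0, bias=b, bias_drift_rate=0.0)
        )
        t = moderate_trial.t - moderate_trial.t[0]
        # trapezoidal integration of a constant bias is exactly b*t
        from scipy.integrate import cumulative_trapezoid

        verr = cumulative_trapezoid(out.ax - moderate_trial.ax, t, initial=0.0)
        np.testing.assert_allclose(verr, b * t, rtol=1e-12, atol=1e-12)

    def test_seeded_reproducibility(self, moderate_trial):
        n1 = corrupt_to_imu(moderate_trial, NoiseModel(0.1, seed=42))
        n2 = corrupt_to_imu(moderate_trial, NoiseModel(0.1, seed=42))
        n3 = corrupt_to_imu(moderate_trial, NoiseModel(0.1, seed=43))
        assert np.array_equal(n1.ax, n2.ax)
        assert not np.array_equal(n1.ax, n3.ax)

    def test_truth_unchanged(self, moderate_trial):
        out = corrupt_to_imu(moderate_trial, NoiseModel(0.1, seed=0))
        assert out.truth is moderate_trial.truth

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(accel_noise_sd=-1.0)


class TestTrialIO:
    def test_round_trip(self, moderate_trial, tmp_path):
        write_trial(moderate_trial, tmp_path / "trial")
        loaded = read_trial(tmp_path / "trial")
        np.testing.assert_allclose(loaded.ax, moderate_trial.ax, rtol=1e-9)
        np.testing.assert_allclose(loaded.ay, moderate_trial.ay, rtol=1e-9)
        np.testing.assert_allclose(
            loaded.truth.hs_t, moderate_trial.truth.hs_t, rtol=1e-9
        )
        np.testing.assert_allclose(
            loaded.labels.values, moderate_trial.labels.values, rtol=1e-9
        )
        assert len(loaded.labels.steps) == len(moderate_trial.labels.steps)
        assert loaded.subject_id == moderate_trial.subject_id
        assert loaded.speed == moderate_trial.speed

    def test_trial_io_dispatch(self, moderate_trial, tmp_path):
        trial_io(moderate_trial, tmp_path / "t", "write")
        loaded = trial_io(None, tmp_path / "t", "read")
        np.testing.assert_allclose(loaded.ay, moderate_trial.ay, rtol=1e-9)
        with pytest.raises(ValueError):
            trial_io(moderate_trial, tmp_path / "t", "sideways")

    def test_missing_column_error(self, tmp_path):
        d = tmp_path / "bad"
        d.mkdir()
        (d / "trial.csv").write_text("t,ax\n0.0,1.0\n0.01,1.0\n")
        with pytest.raises(TrialFormatError, match="missing column 'ay'"):
            read_trial(d)

    def test_non_uniform_timestamps_error(self, tmp_path):
        d = tmp_path / "bad2"
        d.mkdir()
        (d / "trial.csv").write_text(
            "t,ax,ay\n0.0,1,1\n0.01,1,1\n0.5,1,1\n"
        )
        with pytest.raises(TrialFormatError, match="row 2"):
            read_trial(d)

    def test_one_minute_trial_row_count(self, tmp_path):
        n = 6000  # fs * duration = 100 Hz * 60 s
        trial = ImuTrial(
            subject_id="S1", speed_label="moderate", fs=100.0,
            t=np.arange(n) / 100.0, ax=np.zeros(n), ay=np.zeros(n),
        )
        write_trial(trial, tmp_path / "minute")
        lines = (tmp_path / "minute" / "trial.csv").read_text().strip().splitlines()
        assert len(lines) == n + 1  # header + 6000 data rows
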