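"""Filtering, drift-removed integration, segmentation, speed offset, features."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comgait.preprocessing import (
    ChannelScaler,
    FitError,
    OffsetModel,
    StanceSegment,
    apply_speed_offset,
    assemble_features,
    fit_feature_scaler,
    fit_speed_offset_model,
    integrate_drift_removed,
    integrate_segment,
    lowpass_filter,
    raw_feature_rows,
    resample_phase,
)


class TestLowpass:
    def test_constant_maps_to_itself(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, fs=100, fc=10), x, rtol=1e-9)

    def test_gain_at_cutoff_is_half_power_squared(self):
        # forward-backward pass squares the magnitude response: |H|^2 at
        # fc is (1/sqrt(2))^2 = 0.5 for any Butterworth order
        fs, fc = 1000.0, 10.0
        t = np.arange(int(20 * fs / fc)) / fs
        x = np.sin(2 * np.pi * fc * t)
        y = lowpass_filter(x, fs=fs, fc=fc)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        gain = np.max(np.abs(y[mid])) / np.max(np.abs(x[mid]))
        assert gain == pytest.approx(0.5, abs=0.02)

    def test_strong_attenuation_at_4fc(self):
        fs, fc = 1000.0, 10.0
        t = np.arange(int(8 * fs / fc)) / fs
        x = np.sin(2 * np.pi * 4 * fc * t)
        y = lowpass_filter(x, fs=fs, fc=fc)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.max(np.abs(y[mid])) < 0.03

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(100), fs=100, fc=50)


class TestDriftRemoval:
    def test_constant_bias_cancels_exactly(self):
        fs, T = 100.0, 1.0
        a = np.full(int(T * fs) + 1, 0.31)
        v = integrate_drift_removed(a, T=T, fs=fs)
        np.testing.assert_allclose(v, 0.0, atol=1e-14)

    def test_zero_net_impulse_identity(self):
        fs, T = 100.0, 1.0
        t = np.arange(int(T * fs) + 1) / fs
        a = np.sin(2 * np.pi * t / T)  # integrates to ~0 over [0, T]
        from scipy.integrate import cumulative_trapezoid

        v_plain = cumulative_trapezoid(a, t, initial=0.0)
        v_hat = integrate_drift_removed(a, T=T, fs=fs)
        # correction is proportional to v(T) - v(0), itself ~ O(trapz error)
        np.testing.assert_allclose(v_hat, v_plain, atol=1e-6)

    def test_sine_matches_analytic_integral(self):
        fs, T = 1000.0, 1.0
        t = np.arange(int(T * fs) + 1) / fs
        a = np.sin(2 * np.pi * t / T)
        v_hat = integrate_drift_removed(a, T=T, fs=fs)
        analytic = (1 - np.cos(2 * np.pi * t / T)) * T / (2 * np.pi)
        # net velocity change over [0, T] is zero, so no ramp to subtract;
        # the bound is the trapezoid truncation error h^2/12 * max|a''| * 2
        np.testing.assert_allclose(v_hat, analytic, atol=1.1e-6)

    def test_endpoint_identity(self, rng):
        a = rng.normal(size=(101, 2))
        v = integrate_drift_removed(a, T=1.0, fs=100.0)
        np.testing.assert_allclose(v[-1], v[0], atol=1e-12)

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            integrate_drift_removed(np.zeros(10), T=0.0, fs=100.0)


@settings(max_examples=30, deadline=None)
@given(data=st.lists(st.floats(-50, 50), min_size=8, max_size=120))
def test_drift_removal_endpoint_property(data):
    a = np.asarray(data)
    n = len(a)
    fs = 100.0
    T = (n - 1) / fs
    v = integrate_drift_removed(a, T=T, fs=fs)
    assert abs(v[-1] - v[0]) <= 1e-9 * max(1.0, np.max(np.abs(v)))


def _segment(A=5.0, f=1.7, h=1.69, speed=None, n=80, fs=100.0):
    t = np.arange(n) / fs
    return StanceSegment(
        t=t, ax=np.zeros(n), ay=np.zeros(n), T=t[-1], A=A, f_gait=f,
        hs_index=0, to_index=n - 1, height=h, speed=speed, leg_length=0.9,
    )


class TestSpeedOffset:
    def test_exact_recovery_noiseless(self, rng):
        a0, b0, c0 = 0.04, 0.11, -0.05
        g = 9.81
        segs, speeds = [], []
        for _ in range(40):
            A = rng.uniform(2, 8)
            f = rng.uniform(1.4, 2.4)
            h = rng.uniform(1.55, 1.85)
            segs.append(_segment(A=A, f=f, h=h))
            speeds.append((a0 * A + b0 * f + c0) * np.sqrt(h * g))
        model = fit_speed_offset_model(segs, np.array(speeds))
        assert model.a == pytest.approx(a0, abs=1e-10)
        assert model.b == pytest.approx(b0, abs=1e-10)
        assert model.c == pytest.approx(c0, abs=1e-10)

    def test_coefficient_rmse_scales_inverse_sqrt_n(self):
        a0, b0, c0 = 0.04, 0.11, -0.05
        g = 9.81
        rmses = []
        for n in (30, 120, 480):
            errs = []
            for trial_seed in range(24):
                r = np.random.default_rng(1000 + trial_seed)
                A = r.uniform(2, 8, n)
                f = r.uniform(1.4, 2.4, n)
                h = r.uniform(1.55, 1.85, n)
                v = (a0 * A + b0 * f + c0) * np.sqrt(h * g)
                v += r.normal(0, 0.05, n)
                segs = [
                    _segment(A=A[i], f=f[i], h=h[i]) for i in range(n)
                ]
                m = fit_speed_offset_model(segs, v)
                errs.append((m.a - a0) ** 2 + (m.b - b0) ** 2 + (m.c - c0) ** 2)
            rmses.append(np.sqrt(np.mean(errs)))
        # 1/sqrt(n): a 16-fold increase in n should shrink RMSE ~4x
        assert rmses[1] < rmses[0]
        assert rmses[2] < rmses[1]
        assert rmses[2] <= 0.35 * rmses[0]

    def test_degenerate_design_raises(self):
        segs = [_segment(A=5.0, f=1.7) for _ in range(10)]
        with pytest.raises(FitError):
            fit_speed_offset_model(segs, np.ones(10))

    def test_apply_constant_model(self):
        model = OffsetModel(a=0.0, b=0.0, c=0.3)
        seg = _segment(h=1.69)
        v0 = apply_speed_offset(model, seg)
        assert v0 == pytest.approx(0.3 * np.sqrt(1.69 * 9.81))

    def test_height_scaling(self):
        model = OffsetModel(a=0.02, b=0.05, c=0.1)
        v1 = apply_speed_offset(model, _segment(h=1.0))
        v2 = apply_speed_offset(model, _segment(h=2.0))
        assert v2 == pytest.approx(np.sqrt(2) * v1)

    def test_too_few_segments(self):
        with pytest.raises(FitError):
            fit_speed_offset_model([_segment(), _segment()], np.ones(2))


class TestFeatures:
    def _integrated(self, n=87, rng=None):
        rng = rng or np.random.default_rng(0)
        seg = _segment(n=n)
        seg.ax = rng.normal(0, 1, n)
        seg.ay = rng.normal(0, 1, n)
        return integrate_segment(seg)

    def test_87_sample_segment_yields_200_columns(self):
        seg = self._integrated(n=87)
        scaler = fit_feature_scaler([seg])
        fb = assemble_features(seg, scaler)
        assert fb.values.shape == (7, 200)

    def test_first_column_horizontal_position_zero(self):
        seg = self._integrated()
        scaler = ChannelScaler()
        scaler.fit(raw_feature_rows(seg)[1:])
        fb = assemble_features(seg, scaler)
        # row 1 is x; at HS it is the scaled image of raw 0
        raw_x0 = raw_feature_rows(seg)[1][0]
        assert raw_x0 == 0.0

    def test_time_row_is_phase_fraction(self):
        seg = self._integrated()
        scaler = fit_feature_scaler([seg])
        fb = assemble_features(seg, scaler)
        np.testing.assert_allclose(fb.values[0], np.linspace(0, 1, 200), atol=1e-12)

    def test_resample_identity_at_200(self):
        rows = np.random.default_rng(3).normal(size=(7, 200))
        np.testing.assert_allclose(resample_phase(rows, 200), rows, rtol=1e-12)

    def test_scaled_rows_within_unit_interval_on_training_data(self):
        seg = self._integrated()
        scaler = fit_feature_scaler([seg])
        fb = assemble_features(seg, scaler)
        assert fb.values[1:].min() >= -1e-12
        assert fb.values[1:].max() <= 1 + 1e-12

    def test_degenerate_channel_left_at_half(self, caplog):
        seg = self._integrated()
        seg.ax = np.zeros(len(seg))  # degenerate acceleration channel
        seg2 = integrate_segment(seg)
        scaler = fit_feature_scaler([seg2])
        import logging

        with caplog.at_level(logging.WARNING):
            fb = assemble_features(seg2, scaler)
        np.testing.assert_allclose(fb.values[5], 0.5)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_vertical_position_offset_is_leg_length(self):
        seg = self._integrated()
        assert seg.py[0] == pytest.approx(seg.leg_length)

    def test_scaler_round_trip(self, rng):
        data = rng.normal(size=(11, 300))
        scaler = ChannelScaler().fit(data)
        back = scaler.inverse(scaler.transform(data))
        np.testing.assert_allclose(back, data, atol=1e-10)
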