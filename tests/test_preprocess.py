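"""Epoching, band-pass filtering, instantaneous phase and zero-lag
orthogonalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ewcomm as e
from ewcomm.preprocess import bandpass, epoch_recording, instantaneous_phase, leakage_correct

SR = 250.0
ALPHA = e.DEFAULT_BANDS[1]
GAMMA_HI = e.DEFAULT_BANDS[4]


def _recording(data, sr=SR, epoch_s=10.0):
    return e.ParcellatedRecording(
        data=data, sampling_rate=sr,
        region_labels=[f"r{i}" for i in range(data.shape[0])],
        epoch_length_s=epoch_s,
    )


class TestEpoching:
    def test_floor_and_remainder_discarded(self, rng):
        rec = _recording(rng.standard_normal((3, int(25 * SR))))
        epochs = epoch_recording(rec)
        assert epochs.shape == (2, 3, 2500)

    def test_exactly_one_epoch(self, rng):
        rec = _recording(rng.standard_normal((3, 2500)))
        assert epoch_recording(rec).shape[0] == 1

    def test_concatenation_identity(self, rng):
        data = rng.standard_normal((4, 2500 * 2 + 137))
        rec = _recording(data)
        epochs = epoch_recording(rec)
        recon = epochs.transpose(1, 0, 2).reshape(4, -1)
        np.testing.assert_array_equal(recon, data[:, :5000])

    def test_too_short_errors(self, rng):
        with pytest.raises(ValueError):
            _recording(rng.standard_normal((3, 100)))


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        t = np.arange(int(8 * SR)) / SR
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, ALPHA, SR)
        core = slice(500, -500)
        assert np.abs(y[core]).max() >= 0.95

    def test_stopband_attenuation(self):
        t = np.arange(int(8 * SR)) / SR
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, GAMMA_HI, SR)
        core = slice(500, -500)
        rms_in = np.sqrt((x[core] ** 2).mean())
        rms_out = np.sqrt((y[core] ** 2).mean())
        assert rms_out <= 0.01 * rms_in

    def test_zeros_map_to_zeros(self):
        assert not bandpass(np.zeros(1000), ALPHA, SR).any()

    def test_band_above_nyquist_errors(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(1000), GAMMA_HI, 150.0)


class TestInstantaneousPhase:
    def test_phase_advance_matches_frequency(self):
        t = np.arange(int(10 * SR)) / SR
        x = np.cos(2 * np.pi * 10.0 * t)
        ph = instantaneous_phase(x)
        dphi = np.angle(np.exp(1j * np.diff(ph)))
        core = slice(500, -500)
        np.testing.assert_allclose(dphi[core], 2 * np.pi * 10.0 / SR, atol=1e-3)

    def test_quadrature_offset(self):
        t = np.arange(int(10 * SR)) / SR
        pc = instantaneous_phase(np.cos(2 * np.pi * 10 * t))
        ps = instantaneous_phase(np.sin(2 * np.pi * 10 * t))
        diff = np.angle(np.exp(1j * (pc - ps)))
        np.testing.assert_allclose(diff[500:-500], np.pi / 2, atol=1e-3)

    def test_range(self, rng):
        ph = instantaneous_phase(bandpass(rng.standard_normal(5000), ALPHA, SR))
        assert (np.abs(ph) <= np.pi).all()

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_phase_invariant_to_positive_scaling(self, c):
        x = bandpass(np.random.default_rng(7).standard_normal(2000), ALPHA, SR)
        np.testing.assert_allclose(
            instantaneous_phase(c * x), instantaneous_phase(x), atol=1e-8
        )


def _max_abs_zero_lag_corr(x):
    c = np.corrcoef(x)
    return np.abs(c - np.eye(len(c))).max()


class TestLeakageCorrect:
    def test_uncorrelated_input_is_fixed_point(self):
        t = np.arange(2500)
        x = np.stack(
            [np.sin(2 * np.pi * k * t / 2500.0) for k in (3, 7, 11)]
        )  # exactly orthogonal, zero-mean rows
        y = leakage_correct(x)
        for i in range(3):
            r = np.corrcoef(y[i], x[i])[0, 1]
            assert r >= 0.999

    def test_identical_rows_error_names_rows(self, rng):
        x = rng.standard_normal((4, 2500))
        x[2] = x[0]
        with pytest.raises(ValueError, match=r"rows \[0, 2\]"):
            leakage_correct(x)

    def test_random_input_orthogonalized(self, rng):
        x = rng.standard_normal((5, 2500)) @ np.eye(2500)
        mix = rng.standard_normal((5, 5)) * 0.3 + np.eye(5)
        y = leakage_correct(mix @ x)
        assert _max_abs_zero_lag_corr(y) < 1e-6

    def test_idempotent(self, rng):
        x = np.random.default_rng(3).standard_normal((5, 2500))
        y1 = leakage_correct(x)
        y2 = leakage_correct(y1)
        assert np.linalg.norm(y2 - y1) / np.linalg.norm(y1) < 1e-6
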