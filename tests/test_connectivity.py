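"""Connectivity front end: Pearson FC, normalization chain, band-pass,
analytic signals, orthogonalization and power-envelope connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurofuse.connectivity import (
    CANONICAL_BANDS,
    RoiTimeSeries,
    analytic_signal,
    bandpass,
    compute_fmri_fc,
    compute_pec,
    edges_to_matrix,
    normalize_connectivity,
    orthogonalize_pair,
    upper_triangle,
)

ALPHA = CANONICAL_BANDS["alpha"]


def _sinusoid(freq, t=2000, fs=250.0, phase=0.0, amp=1.0):
    tt = np.arange(t) / fs
    return amp * np.cos(2 * np.pi * freq * tt + phase)


class TestFmriFc:
    def test_identical_and_anticorrelated_columns(self, rng):
        a = rng.normal(size=500)
        ts = RoiTimeSeries("s", "fmri", np.column_stack([a, a, -a]))
        fc = compute_fmri_fc(ts)
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(fc.values), 1.0)
        assert fc.normalization_state == ["raw_corr"]

    def test_recovers_generating_correlation(self):
        # Monte-Carlo sampling oracle: known r=0.6 between ROIs 0 and 1
        rng = np.random.default_rng(42)
        cov = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.0], [0.0, 0.0, 1.0]])
        data = rng.multivariate_normal(np.zeros(3), cov, size=500)
        fc = compute_fmri_fc(RoiTimeSeries("s", "fmri", data))
        assert fc.values[0, 1] == pytest.approx(0.6, abs=0.08)

    def test_converges_to_generating_matrix_at_large_t(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 5))
        cov = a @ a.T + 5 * np.eye(5)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        data = rng.multivariate_normal(np.zeros(5), cov, size=5000)
        fc = compute_fmri_fc(RoiTimeSeries("s", "fmri", data))
        assert np.max(np.abs(fc.values - corr)) < 0.05

    def test_zero_variance_column_names_roi(self):
        data = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="index \\[1\\]"):
            compute_fmri_fc(RoiTimeSeries("s", "fmri", data))

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            RoiTimeSeries("s", "fmri", np.ones((2, 4)))


class TestNormalization:
    def test_fisher_values_then_zscore(self, rng):
        # edges r = (0, 0.5, -0.5): atanh -> (0, 0.5493, -0.5493), then
        # standardized over the 3 edges -> (0, +-sqrt(3/2))
        raw = edges_to_matrix(np.array([0.0, 0.5, -0.5]), 3, diagonal=1.0)
        from neurofuse.connectivity import ConnectivityMatrix

        c = ConnectivityMatrix("s", "fmri", raw, ["raw_corr"])
        out = normalize_connectivity(c)
        edges = upper_triangle(out.values)
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert edges[0] == pytest.approx(0.0, abs=1e-12)
        assert edges[1] == pytest.approx(np.sqrt(1.5), abs=1e-9)
        assert edges[2] == pytest.approx(-np.sqrt(1.5), abs=1e-9)
        assert out.normalization_state == ["raw_corr", "fisher_z", "zscore"]
        assert np.all(np.diag(out.values) == 0)

    def test_zscore_moments_and_symmetry(self, rng):
        n = 12
        m = np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-0.8, 0.8, (n, n))), -0.9, 0.9)
        np.fill_diagonal(m, 1.0)
        from neurofuse.connectivity import ConnectivityMatrix

        out = normalize_connectivity(ConnectivityMatrix("s", "fmri", m, ["raw_corr"]))
        e = upper_triangle(out.values)
        assert abs(e.mean()) < 1e-9
        assert abs(e.std() - 1) < 1e-9
        assert np.allclose(out.values, out.values.T, atol=1e-10)

    def test_unit_correlation_clipped_with_warning(self, rng):
        a = rng.normal(size=100)
        fc = compute_fmri_fc(RoiTimeSeries("s", "fmri", np.column_stack([a, a, rng.normal(size=100)])))
        with pytest.warns(UserWarning, match="clipped"):
            out = normalize_connectivity(fc)
        assert np.all(np.isfinite(out.values))

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fisher_z_strictly_monotone_and_sign_preserving(self, r1, r2):
        z1, z2 = np.arctanh(r1), np.arctanh(r2)
        if r1 < r2:
            assert z1 < z2
        assert np.sign(z1) == np.sign(r1)


class TestBandpass:
    def test_alpha_band_passes_10hz_blocks_40hz(self):
        for freq, lo, hi in [(10.0, 0.95, 1.05), (40.0, 0.0, 0.05)]:
            data = _sinusoid(freq)[:, None] * np.ones((1, 2))
            ts = RoiTimeSeries("s", "eeg", data, sampling_rate=250.0)
            out = bandpass(ts, ALPHA)
            mid = slice(500, 1500)
            gain = np.abs(out.data[mid, 0]).max() / np.abs(data[mid, 0]).max()
            assert lo <= gain <= hi
        assert out.band == "alpha"

    def test_zero_signal_stays_zero(self):
        ts = RoiTimeSeries("s", "eeg", np.zeros((400, 2)), sampling_rate=250.0)
        assert np.allclose(bandpass(ts, ALPHA).data, 0.0)

    def test_band_edge_at_nyquist_rejected(self):
        ts = RoiTimeSeries("s", "eeg", np.ones((400, 2)), sampling_rate=60.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts, CANONICAL_BANDS["gamma"])


class TestAnalyticSignal:
    def test_cosine_magnitude_and_hilbert_pair(self):
        data = _sinusoid(10.0)[:, None]
        ts = RoiTimeSeries("s", "eeg", np.repeat(data, 2, axis=1), sampling_rate=250.0)
        z = analytic_signal(ts)
        mid = slice(200, 1800)
        assert np.allclose(np.abs(z[mid, 0]), 1.0, atol=1e-2)
        assert np.allclose(z.real, ts.data, atol=1e-8)
        tt = np.arange(2000) / 250.0
        assert np.allclose(z[mid, 0].imag, np.sin(2 * np.pi * 10 * tt)[mid], atol=1e-2)


class TestOrthogonalization:
    def test_identical_signal_fully_removed(self):
        x = (_sinusoid(10.0) + 1j * _sinusoid(10.0, phase=-np.pi / 2)).astype(complex)
        out = orthogonalize_pair(x, x)
        assert np.abs(out).max() < 1e-10

    def test_quadrature_component_preserved(self):
        # y in exact phase quadrature to x: envelope must survive within 5%
        t, fs = 4000, 250.0
        tt = np.arange(t) / fs
        env = 1.0 + 0.3 * np.sin(2 * np.pi * 0.4 * tt)
        x = np.exp(1j * 2 * np.pi * 10 * tt)
        y = env * np.exp(1j * (2 * np.pi * 10 * tt + np.pi / 2))
        out = orthogonalize_pair(x, y)
        mid = slice(500, 3500)
        assert np.abs(np.abs(out[mid]) / np.abs(y[mid]) - 1).max() < 0.05

    def test_independent_noise_keeps_nonzero_envelope(self, rng):
        from scipy.signal import hilbert

        x = hilbert(rng.normal(size=2000))
        y = hilbert(rng.normal(size=2000))
        assert np.abs(orthogonalize_pair(x, y)).mean() > 0.1

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="identically zero"):
            orthogonalize_pair(np.zeros(100, complex), np.ones(100, complex))


def _am_pair(rho, seed, t=8000, fs=250.0):
    """Independent (or envelope-correlated) amplitude-modulated alpha oscillators."""
    from scipy.signal import butter, sosfiltfilt

    rng = np.random.default_rng(seed)
    sos = butter(2, 1.0, btype="lowpass", fs=fs, output="sos")
    w = rng.normal(size=(t + 200, 2))
    w[:, 1] = rho * w[:, 0] + np.sqrt(1 - rho**2) * w[:, 1]
    slow = sosfiltfilt(sos, w, axis=0)[100:-100]
    slow /= slow.std(axis=0)
    env = np.exp(0.5 * slow)
    tt = np.arange(t) / fs
    f = rng.uniform(9, 11, 2)
    ph = rng.uniform(0, 2 * np.pi, 2)
    data = env * np.cos(2 * np.pi * f * tt[:, None] + ph) + 0.02 * rng.normal(size=(t, 2))
    return RoiTimeSeries("s", "eeg", data, sampling_rate=fs)


class TestPec:
    def test_identical_sinusoids_give_zero(self):
        data = np.repeat(_sinusoid(10.0)[:, None], 2, axis=1)
        ts = RoiTimeSeries("s", "eeg", data, sampling_rate=250.0)
        pec = compute_pec(ts, ALPHA, normalize=False)
        assert pec.values[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_null_mean_near_zero(self):
        vals = [compute_pec(_am_pair(0.0, 1000 + k), ALPHA, normalize=False).values[0, 1]
                for k in range(40)]
        assert abs(np.mean(vals)) < 0.05

    def test_planted_envelope_correlation_detected(self):
        null = [compute_pec(_am_pair(0.0, 2000 + k), ALPHA, normalize=False).values[0, 1]
                for k in range(40)]
        planted = [compute_pec(_am_pair(0.8, 3000 + k), ALPHA, normalize=False).values[0, 1]
                   for k in range(10)]
        assert np.mean(planted) > np.quantile(null, 0.95)

    def test_constant_envelope_rejected(self):
        ts = RoiTimeSeries("s", "eeg", np.zeros((1000, 2)), sampling_rate=250.0)
        with pytest.raises(ValueError, match="constant"):
            compute_pec(ts, ALPHA, normalize=False)
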