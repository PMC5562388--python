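"""Zero-phase filtering, short-channel regression, and block averaging."""

import numpy as np
import pytest
from scipy import signal as sps

import nirstwin as nt
from nirstwin.processing import FilterSpec, design_filter


class TestZeroPhaseFilter:
    def test_dc_passes_the_occlusion_lowpass_unchanged(self):
        x = np.full(2000, 3.7)
        y = nt.zero_phase_filter(x, FilterSpec.occlusion_lowpass(), fs=25.0)
        assert np.allclose(y, x, atol=1e-9)

    def test_stopband_tone_attenuated_to_design_spec(self):
        """A 5-Hz tone through the 1-Hz lowpass drops by at least the design
        stopband attenuation (doubled by the forward-backward pass)."""
        fs = 25.0
        spec = FilterSpec.occlusion_lowpass()
        sos = design_filter(spec, fs)
        w, h = sps.sosfreqz(sos, worN=[5.0 / (fs / 2) * np.pi])
        assert 20 * np.log10(abs(h[0])) <= -spec.stopband_db
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        y = nt.zero_phase_filter(x, spec, fs)
        interior = slice(int(5 * fs), -int(5 * fs))
        assert np.abs(y[interior]).max() < 10 ** (-spec.stopband_db / 20)

    def test_passband_tone_keeps_zero_lag(self):
        fs = 25.0
        t = np.arange(int(400 * fs)) / fs
        x = np.sin(2 * np.pi * 0.1 * t)
        y = nt.zero_phase_filter(x, FilterSpec.motor_bandpass(), fs)
        lags = sps.correlation_lags(len(x), len(x))
        xc = sps.correlate(y, x)
        assert lags[np.argmax(xc)] == 0

    def test_band_edges_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            nt.zero_phase_filter(np.zeros(100), FilterSpec("lowpass", 3, (4.0,)), fs=10.0)

    def test_motor_bandpass_passes_the_block_design_fundamental(self):
        fs = 25.0
        sos = design_filter(FilterSpec.motor_bandpass(), fs)
        w, h = sps.sosfreqz(sos, worN=np.array([0.025, 0.075]) / (fs / 2) * np.pi)
        assert np.all(np.abs(h) ** 2 > 0.9)  # |H|^2 = zero-phase gain


class TestShortChannelRegression:
    fs = 10.0

    def _osc(self, seed, n=4000):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / self.fs
        return (
            np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
            + 0.5 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        )

    def test_pure_scaled_contamination_removed(self):
        ss = self._osc(1)
        ls = 2.0 * ss
        out = nt.short_channel_regression(ls, ss, self.fs)
        interior = slice(200, -200)
        assert np.abs(out[interior]).max() < 1e-8 * np.abs(ls).max()

    def test_zero_short_channel_leaves_long_unchanged(self):
        ls = self._osc(2)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = nt.short_channel_regression(ls, np.zeros_like(ls), self.fs)
        assert np.array_equal(out, ls)

    def test_recovers_uncorrelated_cerebral_signal(self):
        """LS = cerebral + 1.5*SS with an uncorrelated cerebral component:
        the corrected series correlates with the true cerebral at r > 0.95."""
        rng = np.random.default_rng(42)
        n = 4000
        t = np.arange(n) / self.fs
        ss = self._osc(3, n)
        box = ((t % 40) < 20).astype(float)
        kernel = nt.canonical_hrf(np.arange(0, 30, 1 / self.fs))
        cerebral = np.convolve(box, kernel)[:n]
        cerebral /= np.abs(cerebral).max()
        ls = cerebral + 1.5 * ss
        out = nt.short_channel_regression(ls, ss, self.fs)
        r = np.corrcoef(out, cerebral)[0, 1]
        assert r > 0.95

    def test_residual_orthogonal_to_regressor_within_each_window(self):
        ss = self._osc(4)
        ls = self._osc(5) + 0.8 * ss
        window_s = 120.0
        out, alpha = nt.short_channel_regression(
            ls, ss, self.fs, window_s=window_s, return_alpha=True
        )
        w = int(window_s * self.fs)
        for k in (w, len(ss) // 2, len(ss) - w):
            sl = slice(k - w // 2, k - w // 2 + w)
            ss_c = ss[sl] - ss[sl].mean()
            ls_c = ls[sl] - ls[sl].mean()
            resid = ls_c - alpha[k] * ss_c
            rel = abs(ss_c @ resid) / (np.linalg.norm(ss_c) * np.linalg.norm(ls_c))
            assert rel < 1e-8

    def test_separate_scaling_per_chromophore(self):
        ss = np.vstack([self._osc(6), self._osc(7)])
        ls = np.vstack([2.0 * ss[0], -0.5 * ss[1]])
        out = nt.short_channel_regression(ls, ss, self.fs)
        interior = slice(200, -200)
        assert np.abs(out[:, interior]).max() < 1e-8

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValueError):
            nt.short_channel_regression(np.zeros(50), np.zeros(50), self.fs)


class TestBlockAverage:
    fs = 10.0

    def test_identical_epochs_average_to_the_epoch_with_zero_sem(self):
        t = np.arange(0, 400, 1 / self.fs)
        x = np.sin(2 * np.pi * (t % 40) / 40)
        onsets = np.arange(40, 320, 40.0)
        ep = nt.block_average(x, onsets, self.fs, baseline_s=None)
        assert ep.n_trials == len(onsets)
        assert np.allclose(ep.sem, 0.0, atol=1e-12)
        assert np.allclose(ep.epochs - ep.mean, 0.0, atol=1e-12)

    def test_sem_of_iid_noise_scales_as_sigma_over_sqrt_n(self, rng):
        sigma = 0.7
        x = sigma * rng.standard_normal(10 * 500)
        onsets = 50.0 + 42.0 * np.arange(10)
        ep = nt.block_average(x, onsets, self.fs, baseline_s=None)
        assert ep.sem.mean() == pytest.approx(sigma / np.sqrt(10), rel=0.1)

    def test_single_trial_reports_zero_sem_with_warning(self):
        x = np.arange(500.0)
        ep = nt.block_average(x, [10.0], self.fs, baseline_s=None)
        with pytest.warns(UserWarning, match="single trial"):
            assert np.all(ep.sem == 0)

    def test_baseline_shift_zeroes_the_pre_onset_interval(self):
        x = 5.0 + np.arange(600.0) / 100
        ep = nt.block_average(x, [20.0, 30.0], self.fs)
        pre = ep.t_rel < 0
        assert ep.mean[pre].mean() == pytest.approx(0.0, abs=1e-9)

    def test_no_complete_epoch_raises(self):
        with pytest.raises(ValueError):
            nt.block_average(np.zeros(100), [50.0], self.fs)

    def test_filter_then_average_commutes_with_average_then_filter(self):
        """Zero-phase LTI filtering commutes with trial averaging on
        equal-length epochs (numerical check)."""
        rng = np.random.default_rng(8)
        fs = 10.0
        x = rng.standard_normal(int(500 * fs))
        onsets = 60.0 + 44.0 * np.arange(9)
        spec = FilterSpec.occlusion_lowpass()
        filtered_then_avg = nt.block_average(
            nt.zero_phase_filter(x, spec, fs), onsets, fs, baseline_s=None
        ).mean
        epochs = nt.block_average(x, onsets, fs, baseline_s=None).epochs
        avg_then_filtered = nt.zero_phase_filter(epochs.mean(axis=0), spec, fs)
        interior = slice(int(5 * fs), -int(5 * fs))
        assert np.allclose(
            filtered_then_avg[interior], avg_then_filtered[interior], atol=5e-3
        )
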