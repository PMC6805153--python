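"""Pre-whitening, evoked averaging, cropping, FFT power, z-scoring."""

import numpy as np
import pytest

from freqtag.errors import (
    ConfigError,
    DegenerateChannelError,
    DegenerateSpectrumError,
)
from freqtag.simulate import SensorEpochs
from freqtag.spectral import (
    EvokedResponse,
    SpectralPower,
    average_erf,
    crop_steady_state,
    power_spectrum,
    prewhiten,
    zscore_spectrum,
)


def _epochs_from(data, sfreq=32.0, t0=-0.5):
    return SensorEpochs(data=data, sfreq=sfreq, t0=t0, condition="imagery")


class TestPrewhiten:
    def _toy(self, sds=(2.0, 0.5), sfreq=32.0):
        rng = np.random.default_rng(0)
        n_pre = int(0.5 * sfreq)
        n_post = int(2.0 * sfreq)
        base = rng.standard_normal((1, 10, len(sds), n_pre))
        base *= np.asarray(sds)[None, None, :, None]
        post = np.ones((1, 10, len(sds), n_post))
        return _epochs_from(np.concatenate([base, post], axis=-1), sfreq=sfreq)

    def test_unit_sd_channel_unchanged_and_definition(self):
        ep = self._toy(sds=(2.0, 0.5))
        white = prewhiten(ep)
        pre = white.times < 0
        sd = white.data[0, :, :, pre].std(ddof=0)
        # post-stimulus samples divided by each channel's baseline SD
        base = ep.data[0, :, :, ep.times < 0]
        est = base.std(axis=(0, 2) if base.ndim == 3 else 0, ddof=0)
        # baseline variance exactly 1 after whitening
        for c in range(2):
            b = white.data[0, :, c, :][:, white.times < 0]
            assert b.std(ddof=0) == pytest.approx(1.0)
        raw_sd0 = ep.data[0, :, 0, :][:, ep.times < 0].std(ddof=0)
        assert np.allclose(
            white.data[0, :, 0, :][:, white.times >= 0],
            ep.data[0, :, 0, :][:, ep.times >= 0] / raw_sd0,
        )

    def test_scale_invariance(self):
        ep = self._toy()
        scaled = _epochs_from(ep.data * np.array([10.0, 1.0])[None, None, :, None])
        w1 = prewhiten(ep)
        w2 = prewhiten(scaled)
        assert np.allclose(w1.data, w2.data)

    def test_zero_variance_channel_named(self):
        data = np.zeros((1, 3, 2, 64))
        data[:, :, 1, :] = np.random.default_rng(1).standard_normal((1, 3, 64))
        ep = _epochs_from(data)
        with pytest.raises(DegenerateChannelError, match="channel 0"):
            prewhiten(ep)


class TestAverageErf:
    def test_single_trial_identity_and_negation(self):
        rng = np.random.default_rng(2)
        trial = rng.standard_normal((1, 1, 3, 64))
        erf = average_erf(_epochs_from(trial))[0]
        assert np.array_equal(erf.data, trial[0, 0])
        pair = np.concatenate([trial, -trial], axis=1)
        erf2 = average_erf(_epochs_from(pair))[0]
        assert np.allclose(erf2.data, 0)
        assert erf2.n_trials_averaged == 2

    def test_noise_variance_shrinks_as_one_over_trials(self):
        rng = np.random.default_rng(3)
        n_trials = 15
        single_vars, evoked_vars = [], []
        for _ in range(40):
            noise = rng.standard_normal((1, n_trials, 4, 128))
            ep = _epochs_from(noise)
            erf = average_erf(ep)[0]
            single_vars.append(noise.var())
            evoked_vars.append(erf.data.var())
        ratio = np.mean(single_vars) / np.mean(evoked_vars)
        assert ratio == pytest.approx(n_trials, rel=0.1)


class TestCrop:
    def _erf(self, sfreq=32.0, dur=13.0, t0=-0.5):
        n = int(dur * sfreq)
        return EvokedResponse(
            data=np.arange(2 * n, dtype=float).reshape(2, n), sfreq=sfreq, t0=t0
        )

    def test_default_gives_steady_state_window(self):
        out = crop_steady_state(self._erf())
        assert out.data.shape[1] == int(11.25 * 32)
        assert out.cropped_length == pytest.approx(11.25)
        assert out.t0 == 1.25

    def test_skip_zero_starts_at_onset(self):
        erf = self._erf()
        out = crop_steady_state(erf, skip=0.0, length=2.0)
        onset = int(0.5 * 32)
        assert np.array_equal(out.data, erf.data[:, onset : onset + 64])

    def test_non_integer_length_rounded_down(self):
        out = crop_steady_state(self._erf(), skip=0.0, length=1.03)
        assert out.data.shape[1] == int(np.floor(1.03 * 32))
        assert out.cropped_length == pytest.approx(out.data.shape[1] / 32)

    def test_window_exceeding_data_raises(self):
        with pytest.raises(ConfigError):
            crop_steady_state(self._erf(), skip=5.0, length=11.25)


class TestPowerSpectrum:
    def test_bin_spacing_of_steady_state_window(self):
        n = int(11.25 * 32)
        erf = EvokedResponse(data=np.zeros((1, n)), sfreq=32.0, t0=1.25)
        spec = power_spectrum(erf)
        assert spec.bin_spacing == pytest.approx(1 / 11.25)
        assert spec.bin_spacing == pytest.approx(0.0889, abs=5e-5)

    def test_bin_centered_tone_concentrates_in_one_bin(self):
        sfreq, dur = 32.0, 11.25
        t = np.arange(int(dur * sfreq)) / sfreq
        erf = EvokedResponse(
            data=np.sin(2 * np.pi * 0.8 * t)[None, :], sfreq=sfreq, t0=0.0
        )
        spec = power_spectrum(erf)
        i = int(np.argmin(np.abs(spec.freqs - 0.8)))
        assert i == 9  # 0.8 Hz is the 9th bin of a 11.25 s window
        others = np.delete(spec.power[0], i)
        assert others.max() < 1e-20 * spec.power[0, i]

    def test_amplitude_ratio_squares_in_power(self):
        sfreq, dur = 64.0, 10.0
        t = np.arange(int(dur * sfreq)) / sfreq
        sig = 1.0 * np.sin(2 * np.pi * 1.0 * t) + 2.0 * np.sin(2 * np.pi * 3.0 * t)
        spec = power_spectrum(EvokedResponse(data=sig[None], sfreq=sfreq, t0=0.0))
        # oracle: direct DFT sums at the two bins
        n = len(t)
        k1 = np.abs(np.sum(sig * np.exp(-2j * np.pi * 10 * np.arange(n) / n))) ** 2 / n
        k3 = np.abs(np.sum(sig * np.exp(-2j * np.pi * 30 * np.arange(n) / n))) ** 2 / n
        i1 = int(np.argmin(np.abs(spec.freqs - 1.0)))
        i3 = int(np.argmin(np.abs(spec.freqs - 3.0)))
        assert spec.power[0, i1] == pytest.approx(k1, rel=1e-9)
        assert spec.power[0, i3] == pytest.approx(k3, rel=1e-9)
        assert spec.power[0, i3] / spec.power[0, i1] == pytest.approx(4.0, rel=1e-9)

    def test_parseval(self):
        rng = np.random.default_rng(4)
        sig = rng.standard_normal((3, 200))
        spec = power_spectrum(EvokedResponse(data=sig, sfreq=50.0, t0=0.0))
        # two-sided sum: double interior rfft bins (N even: keep DC & Nyquist)
        p = spec.power.copy()
        p[:, 1:-1] *= 2
        total = p.sum(axis=1)
        assert np.allclose(total, (sig**2).sum(axis=1), rtol=1e-10)


class TestPreprocess:
    def test_bandpass_keeps_in_band_removes_out_of_band(self):
        from freqtag.spectral import preprocess_epochs

        sfreq = 256.0
        t = np.arange(int(4 * sfreq)) / sfreq
        keep = np.sin(2 * np.pi * 5.0 * t)
        drift = np.sin(2 * np.pi * 0.05 * t)
        hf = np.sin(2 * np.pi * 110.0 * t)
        data = (keep + drift + hf)[None, None, None, :]
        ep = _epochs_from(data, sfreq=sfreq, t0=0.0)
        out = preprocess_epochs(ep, band=(0.2, 60.0), notch_freq=50.0)
        spec = np.abs(np.fft.rfft(out.data[0, 0, 0])) ** 2
        freqs = np.fft.rfftfreq(out.n_times, 1 / sfreq)

        def p(f):
            return spec[np.argmin(np.abs(freqs - f))]

        assert p(5.0) > 100 * p(0.05)
        assert p(5.0) > 100 * p(110.0)

    def test_notch_suppresses_power_line(self):
        from freqtag.spectral import preprocess_epochs

        sfreq = 256.0
        t = np.arange(int(4 * sfreq)) / sfreq
        data = (np.sin(2 * np.pi * 50.0 * t) + np.sin(2 * np.pi * 10.0 * t))[
            None, None, None, :
        ]
        ep = _epochs_from(data, sfreq=sfreq, t0=0.0)
        out = preprocess_epochs(ep, band=(0.2, 60.0), notch_freq=50.0)
        spec = np.abs(np.fft.rfft(out.data[0, 0, 0])) ** 2
        freqs = np.fft.rfftfreq(out.n_times, 1 / sfreq)
        i50 = np.argmin(np.abs(freqs - 50.0))
        i10 = np.argmin(np.abs(freqs - 10.0))
        assert spec[i50] < 0.01 * spec[i10]


class TestZscore:
    def _spec(self, values):
        freqs = 0.5 + np.arange(len(values)) * 0.5
        return SpectralPower(power=np.asarray(values, float)[None], freqs=freqs)

    def test_arithmetic(self):
        # background (1,2,3,4,5): mean 3, sample SD 1.5811; target 6 -> 1.897
        spec = self._spec([1, 2, 3, 4, 5, 6])
        z = zscore_spectrum(spec, exclude=(3.0,), band=(0.5, 2.5))
        i_target = 5
        assert z[0, i_target] == pytest.approx((6 - 3) / np.std([1, 2, 3, 4, 5], ddof=1))
        assert z[0, i_target] == pytest.approx(1.897, abs=5e-4)

    def test_excluded_bins_do_not_contribute(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        s1 = self._spec(base)
        bumped = list(base)
        bumped[7] = 100.0  # bin at 4.0 Hz
        s2 = self._spec(bumped)
        z1 = zscore_spectrum(s1, exclude=(0.8, 4.0), band=(0.5, 4.5))
        z2 = zscore_spectrum(s2, exclude=(0.8, 4.0), band=(0.5, 4.5))
        keep = np.arange(9) != 7
        assert np.allclose(z1[0, keep], z2[0, keep])

    def test_degenerate_background_raises(self):
        spec = self._spec([2.0] * 8)
        with pytest.raises(DegenerateSpectrumError):
            zscore_spectrum(spec, exclude=(), band=(0.5, 4.5))
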