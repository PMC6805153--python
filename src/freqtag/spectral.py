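"""Sensor-level spectral stage: pre-whitening, evoked averaging, FFT power.

The analysis chain is: pre-whiten each channel by its pre-stimulus
baseline SD (diagonal noise covariance), average trials into the evoked
response, drop the first 1.25 s of stimulation (transient), and Fourier
transform the remaining 11.25 s steady-state window, giving a frequency
resolution of 1/11.25 ~ 0.089 Hz so that the tagged rates 0.8 Hz and
4 Hz fall exactly on bin centres (bins 9 and 45).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignmentError,
    ConfigError,
    DegenerateChannelError,
    DegenerateSpectrumError,
    EmptyInputError,
)
from .simulate import SensorEpochs

__all__ = [
    "EvokedResponse",
    "SpectralPower",
    "preprocess_epochs",
    "prewhiten",
    "average_erf",
    "crop_steady_state",
    "power_spectrum",
    "zscore_spectrum",
    "bin_index",
]


@dataclass(frozen=True)
class EvokedResponse:
    """Trial-averaged response: channels x time."""

    data: np.ndarray
    sfreq: float
    t0: float
    n_trials_averaged: int = 1
    cropped_length: float | None = None  # actual window length in s after cropping

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ConfigError("evoked data must be (channels, time)")
        if self.n_trials_averaged < 1:
            raise EmptyInputError("evoked response requires at least one trial")
        if np.any(np.isnan(d)):
            raise ConfigError("evoked data contains NaN")
        object.__setattr__(self, "data", d)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[1]) / self.sfreq


@dataclass(frozen=True)
class SpectralPower:
    """Per-channel power by frequency bin, uniform bin spacing.

    Power convention: ``|X_k|^2 / N`` with ``X_k`` the unnormalized DFT
    coefficient and ``N`` the window length in samples, one-sided (rfft)
    without doubling.  Under this convention the sum over the full
    (two-sided) spectrum equals ``N`` times the mean squared amplitude
    (Parseval).
    """

    power: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.power, dtype=float))
        f = np.asarray(self.freqs, dtype=float)
        if p.shape[-1] != f.shape[0]:
            raise ConfigError("power and freqs lengths disagree")
        if np.any(p < 0):
            raise ConfigError("power must be nonnegative")
        df = np.diff(f)
        if f.shape[0] >= 2 and (np.any(df <= 0) or not np.allclose(df, df[0], rtol=1e-6)):
            raise ConfigError("freqs must be strictly increasing and uniformly spaced")
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "freqs", f)

    @property
    def bin_spacing(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]

    def channel_average(self) -> "SpectralPower":
        """Average power across channels (the per-subject analysis unit)."""
        return SpectralPower(self.power.mean(axis=0, keepdims=True), self.freqs)


def bin_index(freqs: np.ndarray, f: float) -> int:
    """Index of the bin whose centre matches ``f`` within half a bin."""
    spacing = float(freqs[1] - freqs[0])
    i = int(np.argmin(np.abs(freqs - f)))
    if abs(freqs[i] - f) > spacing / 2 + 1e-12:
        raise AlignmentError(f"{f} Hz does not align with a bin centre (spacing {spacing:.4g})")
    return i


def preprocess_epochs(
    epochs: SensorEpochs,
    band: tuple[float, float] = (0.2, 60.0),
    notch_freq: float | None = 50.0,
) -> SensorEpochs:
    """Zero-phase band-pass (and power-line notch) of raw epochs.

    Filters are linear-phase FIR applied forward-backward; edge effects
    are eliminated by padding each epoch with one epoch length of
    reflected data on either side before filtering.  The upper corner
    is capped below Nyquist for low-rate simulated data.
    """
    from scipy import signal as ssig

    lo, hi = band
    hi = min(hi, 0.45 * epochs.sfreq)
    if not 0 < lo < hi:
        raise ConfigError(f"invalid band ({lo}, {hi}) Hz at sfreq {epochs.sfreq}")
    n = epochs.n_times
    padded = np.pad(epochs.data, [(0, 0)] * 3 + [(n - 1, n - 1)], mode="reflect")
    # band-pass: high-pass corner is very low, so use a long FIR
    numtaps = min(2 * n - 1, int(3.3 * epochs.sfreq / lo) | 1)
    taps = ssig.firwin(numtaps, [lo, hi], pass_zero=False, fs=epochs.sfreq)
    out = ssig.filtfilt(taps, 1.0, padded, axis=-1, padlen=0)
    if notch_freq is not None and notch_freq < epochs.sfreq / 2:
        b, a = ssig.iirnotch(notch_freq, 30.0, fs=epochs.sfreq)
        out = ssig.filtfilt(b, a, out, axis=-1, padlen=0)
    return epochs.replace_data(out[..., n - 1 : 2 * n - 1])


def prewhiten(
    epochs: SensorEpochs, baseline_window: tuple[float, float] | None = None
) -> SensorEpochs:
    """Divide each channel by its pre-stimulus baseline SD, per subject.

    The diagonal noise covariance is estimated from the baseline segment
    (default: the full pre-stimulus window), pooling samples across
    trials; the SD uses ddof=0 so the whitened baseline has variance
    exactly 1 per channel.
    """
    if baseline_window is None:
        baseline_window = (epochs.t0, 0.0)
    lo, hi = baseline_window
    if lo < epochs.t0 - 1e-9 or hi > 1e-9:
        raise ConfigError("baseline window must lie within the pre-stimulus segment")
    times = epochs.times
    mask = (times >= lo - 1e-9) & (times < hi - 1e-9)
    if not mask.any():
        raise ConfigError("baseline window contains no samples")
    base = epochs.data[..., mask]  # (subj, trials, chan, t_base)
    sd = base.std(axis=(1, 3), ddof=0)  # (subj, chan)
    bad = np.argwhere(sd == 0)
    if bad.size:
        s, c = bad[0]
        raise DegenerateChannelError(
            f"channel {c} of subject {s} has zero baseline variance"
        )
    data = epochs.data / sd[:, None, :, None]
    return epochs.replace_data(data)


def average_erf(epochs: SensorEpochs) -> list[EvokedResponse]:
    """Trial-average each subject's epochs into an evoked response."""
    if epochs.n_trials < 1:
        raise EmptyInputError("cannot average zero trials")
    return [
        EvokedResponse(
            data=epochs.data[s].mean(axis=0),
            sfreq=epochs.sfreq,
            t0=epochs.t0,
            n_trials_averaged=epochs.n_trials,
        )
        for s in range(epochs.n_subjects)
    ]


def crop_steady_state(
    erf: EvokedResponse, skip: float = 1.25, length: float = 11.25
) -> EvokedResponse:
    """Keep the steady-state window [skip, skip+length) after onset.

    The default drops the first 1.25 s of stimulation (transient
    response) and keeps 11.25 s.  Non-integer sample counts are rounded
    down; the realized window length is recorded in ``cropped_length``.
    """
    start = int(round((skip - erf.t0) * erf.sfreq))
    n_keep = int(np.floor(length * erf.sfreq + 1e-9))
    if start < 0 or start + n_keep > erf.data.shape[1] or n_keep <= 0:
        raise ConfigError(
            f"window [{skip}, {skip + length}) s exceeds the available epoch"
        )
    return EvokedResponse(
        data=erf.data[:, start : start + n_keep],
        sfreq=erf.sfreq,
        t0=skip,
        n_trials_averaged=erf.n_trials_averaged,
        cropped_length=n_keep / erf.sfreq,
    )


def power_spectrum(erf: EvokedResponse) -> SpectralPower:
    """FFT power of the evoked window: no taper, no zero-padding.

    Bin spacing is the reciprocal of the window duration (11.25 s ->
    0.089 Hz).  See :class:`SpectralPower` for the power convention.
    """
    n = erf.data.shape[1]
    if n == 0:
        raise EmptyInputError("empty window")
    coefs = np.fft.rfft(erf.data, axis=-1)
    power = np.abs(coefs) ** 2 / n
    freqs = np.fft.rfftfreq(n, 1.0 / erf.sfreq)
    return SpectralPower(power=power, freqs=freqs)


def zscore_spectrum(
    spectrum: SpectralPower,
    exclude: tuple[float, ...] = (0.8, 4.0),
    band: tuple[float, float] = (0.5, 4.5),
) -> np.ndarray:
    """Z-score each bin against the band background, per channel.

    The background is every bin with centre in ``band`` except those
    matching an excluded (tagged) frequency; z = (power - mean_bg) /
    SD_bg with the sample SD (ddof=1).  Returns an array shaped like
    ``spectrum.power``.
    """
    f = spectrum.freqs
    half = spectrum.bin_spacing / 2
    in_band = (f >= band[0] - 1e-9) & (f <= band[1] + 1e-9)
    bg = in_band.copy()
    for fx in exclude:
        bg &= np.abs(f - fx) > half
    if bg.sum() < 3:
        raise DegenerateSpectrumError("fewer than 3 background bins in band")
    mean_bg = spectrum.power[:, bg].mean(axis=1, keepdims=True)
    sd_bg = spectrum.power[:, bg].std(axis=1, ddof=1, keepdims=True)
    if np.any(sd_bg == 0):
        raise DegenerateSpectrumError("background bins have zero SD")
    return (spectrum.power - mean_bg) / sd_bg
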