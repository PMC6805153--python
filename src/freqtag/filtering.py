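"""Zero-phase FIR filtering and coloured-noise generation helpers."""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import SamplingError

__all__ = ["fir_bandpass", "fir_bandpass_design", "notch", "pink_noise"]


def fir_bandpass_design(sfreq: float, band: tuple[float, float], transition: float = 10.0) -> np.ndarray:
    """Design a linear-phase band-pass FIR (Hamming window).

    The number of taps is set from the transition width (default 10 Hz)
    using the Hamming-window rule 3.3 / (transition / sfreq), which gives
    >= 40 dB stop-band attenuation one transition width away from the
    band edges.
    """
    lo, hi = band
    nyq = sfreq / 2.0
    if not (0 < lo < hi < nyq):
        raise SamplingError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    transition = min(transition, lo, nyq - hi)
    numtaps = int(np.ceil(3.3 * sfreq / transition))
    numtaps += 1 - numtaps % 2  # odd length, type-I
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=sfreq, window="hamming")


def fir_bandpass(
    data: np.ndarray, sfreq: float, band: tuple[float, float], transition: float = 10.0
) -> tuple[np.ndarray, int]:
    """Zero-phase band-pass along the last axis.

    Returns the filtered data and the one-sided edge length (in samples,
    equal to the filter length) within which samples are contaminated by
    boundary effects and should be excluded from spectra.
    """
    taps = fir_bandpass_design(sfreq, band, transition)
    if data.shape[-1] <= 3 * len(taps):
        raise SamplingError(
            f"trace of {data.shape[-1]} samples is shorter than 3 filter lengths ({3 * len(taps)})"
        )
    out = signal.filtfilt(taps, 1.0, data, axis=-1)
    return out, len(taps)


def notch(data: np.ndarray, sfreq: float, freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch (power-line removal) along the last axis."""
    if freq >= sfreq / 2:
        raise SamplingError(f"notch frequency {freq} Hz above Nyquist")
    b, a = signal.iirnotch(freq, q, fs=sfreq)
    return signal.filtfilt(b, a, data, axis=-1)


def pink_noise(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit standard deviation.

    White Gaussian noise is shaped in the frequency domain with a
    1/sqrt(f) amplitude profile (DC dropped), then rescaled to unit SD
    per trace.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd
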