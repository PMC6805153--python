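"""Intracranial high-gamma tagging branch.

Per contact: band-pass the trace to 60-100 Hz, take the Hilbert
envelope, Fourier transform the envelope per trial over the
steady-state window, and run the neighbour-bin peak test with the trial
as the paired unit.  Tagging strength is summarized by the normalized
peak

    (P_target - P_neighbouring) / (P_target + P_neighbouring)

which is bounded in [-1, 1] and invariant to the overall power scale,
so trials can be pooled across contacts and regions: a one-sample
one-tailed t tests whether a region's normalized peak exceeds zero,
and a pooled-variance two-sample t contrasts the imagery and baseline
conditions (pooled rather than Welch, so df = n1 + n2 - 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import hilbert

from .errors import EmptyInputError, PairingError, UndefinedPeakError
from .filtering import fir_bandpass
from .simulate import ContactRecord
from .spectral import SpectralPower, bin_index
from .stats import PeakStat, neighbor_bin_test

__all__ = [
    "EnvelopeResult",
    "EnvelopeSpectrum",
    "NormalizedPeak",
    "highgamma_envelope",
    "envelope_spectrum",
    "contact_peak_test",
    "normalized_peak",
    "normalized_peaks_per_trial",
    "region_pool_test",
]


@dataclass(frozen=True)
class EnvelopeResult:
    """Instantaneous high-gamma amplitude per trial.

    ``n_edge`` samples at each end are contaminated by filter edge
    effects and are excluded by :func:`envelope_spectrum`.
    """

    envelope: np.ndarray  # (trials, time)
    sfreq: float
    t0: float
    n_edge: int


@dataclass(frozen=True)
class EnvelopeSpectrum:
    """Per-trial envelope power by frequency bin."""

    power: np.ndarray  # (trials, n_bins)
    freqs: np.ndarray
    contact: ContactRecord | None = None

    @property
    def bin_spacing(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class NormalizedPeak:
    """Bounded tagging-strength index for one trial at one frequency."""

    value: float
    target_freq: float
    trial: int = -1
    region: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not -1 <= self.value <= 1:
            raise UndefinedPeakError(f"normalized peak {self.value} outside [-1, 1]")


def highgamma_envelope(
    record: ContactRecord, band: tuple[float, float] = (60.0, 100.0)
) -> EnvelopeResult:
    """Zero-phase band-pass then Hilbert envelope, per trial.

    Only trials flagged correct in ``record.trial_mask`` are kept.
    """
    trace = record.trace[record.trial_mask]
    if trace.shape[0] == 0:
        raise EmptyInputError("no correct trials")
    filtered, n_edge = fir_bandpass(trace, record.sfreq, band)
    env = np.abs(hilbert(filtered, axis=-1))
    return EnvelopeResult(envelope=env, sfreq=record.sfreq, t0=record.t0, n_edge=n_edge)


def envelope_spectrum(
    env: EnvelopeResult, skip: float = 1.25, length: float | None = 11.25
) -> EnvelopeSpectrum:
    """Per-trial FFT power of the envelope over the steady-state window.

    The window starts ``skip`` seconds after stimulus onset (default
    1.25 s, mirroring the sensor-level transient exclusion) and spans
    ``length`` seconds (None = to the end, excluding the filter edge).
    The envelope mean (DC) is removed before the FFT; power convention
    matches :class:`freqtag.spectral.SpectralPower`.
    """
    start = int(round((skip - env.t0) * env.sfreq))
    start = max(start, env.n_edge)
    if length is None:
        stop = env.envelope.shape[1] - env.n_edge
    else:
        stop = start + int(np.floor(length * env.sfreq + 1e-9))
    if stop <= start or stop > env.envelope.shape[1]:
        raise EmptyInputError("steady-state window exceeds the envelope")
    seg = env.envelope[:, start:stop]
    seg = seg - seg.mean(axis=-1, keepdims=True)
    n = seg.shape[1]
    power = np.abs(np.fft.rfft(seg, axis=-1)) ** 2 / n
    freqs = np.fft.rfftfreq(n, 1.0 / env.sfreq)
    return EnvelopeSpectrum(power=power, freqs=freqs)


def contact_peak_test(
    spec: EnvelopeSpectrum, band: tuple[float, float] = (0.5, 4.5)
) -> list[PeakStat]:
    """Neighbour-bin test across trials with BH-FDR over the band.

    Identical statistic machinery to the sensor-level test; the paired
    unit is the trial, so df = n_trials - 1.
    """
    return neighbor_bin_test(spec.power, spec.freqs, band=band, tails="one")


def normalized_peak(p_target: float, p_neighbouring: float) -> float:
    """(P_t - P_n) / (P_t + P_n), bounded in [-1, 1]."""
    if p_target < 0 or p_neighbouring < 0:
        raise UndefinedPeakError("powers must be nonnegative")
    total = p_target + p_neighbouring
    if total == 0:
        raise UndefinedPeakError("target and neighbouring power are both zero")
    return float((p_target - p_neighbouring) / total)


def normalized_peaks_per_trial(
    spec: EnvelopeSpectrum,
    target_freq: float,
    region: str = "",
    condition: str = "",
) -> list[NormalizedPeak]:
    """Per-trial normalized peaks at ``target_freq``."""
    i = bin_index(spec.freqs, target_freq)
    if i == 0 or i == len(spec.freqs) - 1:
        raise UndefinedPeakError("target frequency maps to an edge bin")
    out = []
    for r in range(spec.power.shape[0]):
        p_t = float(spec.power[r, i])
        p_n = float(0.5 * (spec.power[r, i - 1] + spec.power[r, i + 1]))
        out.append(
            NormalizedPeak(
                value=normalized_peak(p_t, p_n),
                target_freq=float(spec.freqs[i]),
                trial=r,
                region=region,
                condition=condition,
            )
        )
    return out


def region_pool_test(peaks: list[NormalizedPeak] | pd.DataFrame) -> pd.DataFrame:
    """Region-level statistics on pooled normalized peaks.

    Per region x condition: one-sample one-tailed t against zero over
    all pooled trials (df = n - 1).  Per region: two-tailed independent
    t between conditions with pooled variance (df = n1 + n2 - 2).
    Returns a tidy table with one row per test.
    """
    if isinstance(peaks, pd.DataFrame):
        df = peaks
    else:
        df = pd.DataFrame(
            {
                "value": [p.value for p in peaks],
                "region": [p.region for p in peaks],
                "condition": [p.condition for p in peaks],
                "target_freq": [p.target_freq for p in peaks],
            }
        )
    rows = []
    for (region, condition), grp in df.groupby(["region", "condition"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise EmptyInputError(
                f"region {region!r} condition {condition!r} has a singleton group"
            )
        n = len(vals)
        sd = vals.std(ddof=1)
        if sd == 0:
            t = 0.0 if vals.mean() == 0 else np.sign(vals.mean()) * np.inf
            p = 0.5 if vals.mean() == 0 else (0.0 if vals.mean() > 0 else 1.0)
            d = 0.0 if vals.mean() == 0 else np.sign(vals.mean()) * np.inf
        else:
            t = vals.mean() / (sd / np.sqrt(n))
            p = float(sps.t.sf(t, n - 1))
            d = vals.mean() / sd
        rows.append(
            {
                "region": region,
                "condition": condition,
                "test": "one_sample_gt_zero",
                "n": n,
                "df": n - 1,
                "t": float(t),
                "p": float(p),
                "cohens_d": float(d),
            }
        )
    for region, grp in df.groupby("region", sort=True):
        conds = sorted(grp["condition"].unique())
        if len(conds) != 2:
            continue
        a = grp.loc[grp["condition"] == conds[0], "value"].to_numpy(dtype=float)
        b = grp.loc[grp["condition"] == conds[1], "value"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise EmptyInputError(f"region {region!r} has a singleton condition group")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        n1, n2 = len(a), len(b)
        sp = np.sqrt(
            ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        )
        d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
        rows.append(
            {
                "region": region,
                "condition": f"{conds[0]}-{conds[1]}",
                "test": "independent_two_sample",
                "n": n1 + n2,
                "df": n1 + n2 - 2,
                "t": float(t),
                "p": float(p),
                "cohens_d": float(d),
            }
        )
    return pd.DataFrame(rows)
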