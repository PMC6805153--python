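"""Peak statistics: neighbour-bin tests, FDR, contrasts, RM-ANOVA.

The central statistic of the frequency-tagging design is the
neighbour-bin test: at every bin in the band of interest, the power at
the bin is compared against the mean of its two flanking bins with a
one-tailed paired t test across analysis units (subjects for sensor
spectra, trials for intracranial envelope spectra), and the p values
are Benjamini-Hochberg FDR corrected across the tested bins.  Because
the flanker average cancels any locally linear trend, the test is
insensitive to the 1/f background.

Cohen's d for paired tests is d_z = mean(diff) / SD(diff), consistent
with d = t / sqrt(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, EmptyInputError, GeometryError, PairingError
from .spectral import SpectralPower, bin_index

__all__ = [
    "PeakStat",
    "paired_t",
    "neighbor_bin_test",
    "peak_power",
    "condition_contrast",
    "lateralization_test",
    "bh_fdr",
    "rm_anova_gg",
    "peakstats_to_frame",
]


@dataclass(frozen=True)
class PeakStat:
    """One peak test: t, df, raw and FDR-corrected p, Cohen's d."""

    freq: float
    t_value: float
    df: int
    p_raw: float
    p_fdr: float
    cohens_d: float
    degenerate: bool = False  # zero-variance differences (t reported as +/-inf)


def paired_t(diff: np.ndarray, tails: str = "one") -> tuple[float, int, float, float, bool]:
    """Paired t test on precomputed differences.

    Returns ``(t, df, p, cohens_d, degenerate)``.  ``tails='one'`` tests
    mean(diff) > 0.  Zero-variance differences give t = +/-inf with
    p = 0 (or 1) and the degenerate flag set; an all-zero difference
    vector gives t = 0.
    """
    diff = np.asarray(diff, dtype=float)
    n = diff.shape[0]
    if n < 2:
        raise EmptyInputError("paired t test needs at least 2 units")
    df = n - 1
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, df, 0.5 if tails == "one" else 1.0, 0.0, False
        t = np.inf if mean > 0 else -np.inf
        if tails == "one":
            p = 0.0 if mean > 0 else 1.0
        else:
            p = 0.0
        return t, df, p, np.sign(mean) * np.inf, True
    t = mean / (sd / np.sqrt(n))
    if tails == "one":
        p = float(sps.t.sf(t, df))
    else:
        p = float(2 * sps.t.sf(abs(t), df))
    d = mean / sd
    return float(t), df, p, float(d), False


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def neighbor_bin_test(
    powers: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float] = (0.5, 4.5),
    tails: str = "one",
) -> list[PeakStat]:
    """Neighbour-bin peak test with BH-FDR over the tested band.

    Parameters
    ----------
    powers : (units, n_bins) array
        One channel-average (or envelope) spectrum per analysis unit.
    freqs : (n_bins,) array
        Bin centres, uniformly spaced.
    band : (low, high)
        Bins with centres in this closed interval are tested; bins
        lacking a flanker inside the spectrum are skipped with a
        warning.
    """
    powers = np.atleast_2d(np.asarray(powers, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    if powers.shape[0] < 3:
        raise EmptyInputError("neighbour-bin test needs at least 3 paired units")
    if powers.shape[1] != freqs.shape[0]:
        raise PairingError("powers and freqs disagree")

    candidates = np.flatnonzero((freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9))
    tested: list[int] = []
    for i in candidates:
        if i == 0 or i == freqs.shape[0] - 1:
            warnings.warn(
                f"bin at {freqs[i]:.4g} Hz skipped: flanker outside spectrum",
                stacklevel=2,
            )
            continue
        tested.append(int(i))
    results = []
    for i in tested:
        diff = powers[:, i] - 0.5 * (powers[:, i - 1] + powers[:, i + 1])
        t, df, p, d, degen = paired_t(diff, tails=tails)
        results.append((freqs[i], t, df, p, d, degen))
    p_adj = bh_fdr(np.array([r[3] for r in results]))
    return [
        PeakStat(
            freq=float(f),
            t_value=t,
            df=df,
            p_raw=p,
            p_fdr=float(pa),
            cohens_d=d,
            degenerate=degen,
        )
        for (f, t, df, p, d, degen), pa in zip(results, p_adj)
    ]


def peak_power(spectrum: SpectralPower | np.ndarray, f: float, freqs: np.ndarray | None = None) -> float:
    """Peak power: bin power minus the mean of its two flanking bins."""
    if isinstance(spectrum, SpectralPower):
        p = spectrum.channel_average().power[0]
        fr = spectrum.freqs
    else:
        p = np.asarray(spectrum, dtype=float)
        if freqs is None:
            raise ValueError("freqs required when passing a raw power array")
        fr = np.asarray(freqs, dtype=float)
    i = bin_index(fr, f)
    if i == 0 or i == len(fr) - 1:
        raise GeometryError(f"{f} Hz maps to an edge bin; flankers unavailable")
    return float(p[i] - 0.5 * (p[i - 1] + p[i + 1]))


def condition_contrast(
    peaks_a: np.ndarray, peaks_b: np.ndarray, tails: str = "two", freq: float = np.nan
) -> PeakStat:
    """Paired condition contrast of per-unit peak powers (A - B)."""
    a = np.asarray(peaks_a, dtype=float)
    b = np.asarray(peaks_b, dtype=float)
    if a.shape != b.shape:
        raise PairingError(f"unpaired inputs: {a.shape} vs {b.shape}")
    t, df, p, d, degen = paired_t(a - b, tails=tails)
    return PeakStat(
        freq=freq, t_value=t, df=df, p_raw=p, p_fdr=p, cohens_d=d, degenerate=degen
    )


def lateralization_test(
    powers_at_bin: np.ndarray, sides: np.ndarray, f: float = np.nan
) -> PeakStat:
    """Right-vs-left hemisphere contrast of sensor power at one bin.

    ``powers_at_bin`` is (units, channels); ``sides`` labels each
    channel 'left' | 'right' | 'midline' (midline excluded).  Two-tailed
    paired t across units on (right mean - left mean).
    """
    powers = np.atleast_2d(np.asarray(powers_at_bin, dtype=float))
    sides = np.asarray(sides, dtype=object)
    left = sides == "left"
    right = sides == "right"
    if not left.any() or not right.any():
        raise GeometryError("need at least one sensor on each side")
    if powers.shape[0] < 2:
        raise EmptyInputError("lateralization test needs >= 2 units (df >= 1)")
    diff = powers[:, right].mean(axis=1) - powers[:, left].mean(axis=1)
    t, df, p, d, degen = paired_t(diff, tails="two")
    return PeakStat(
        freq=f, t_value=t, df=df, p_raw=p, p_fdr=p, cohens_d=d, degenerate=degen
    )


def rm_anova_gg(values: np.ndarray, factor_names: tuple[str, str] = ("condition", "region")):
    """Two-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    Parameters
    ----------
    values : (subjects, levels_A, levels_B) array
        Complete balanced within-subject design.  A one-factor design is
        expressed with ``levels_B == 1``.

    Returns
    -------
    table : pandas.DataFrame
        One row per effect with F, uncorrected df, GG epsilon,
        GG-corrected df and p (columns ``F, df1, df2, eps, df1_gg,
        df2_gg, p_gg``).
    posthoc : pandas.DataFrame
        Bonferroni-adjusted pairwise paired t tests between levels of
        the first factor within each level of the second.
    """
    import pingouin as pg

    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise DesignError("values must be (subjects, levels_A, levels_B)")
    n_subj, n_a, n_b = values.shape
    if n_subj < 3:
        raise DesignError("need at least 3 subjects")
    if np.any(np.isnan(values)):
        raise DesignError("design has missing cells")

    subj, a_lv, b_lv = np.meshgrid(
        np.arange(n_subj), np.arange(n_a), np.arange(n_b), indexing="ij"
    )
    df_long = pd.DataFrame(
        {
            "subject": subj.ravel(),
            factor_names[0]: a_lv.ravel(),
            factor_names[1]: b_lv.ravel(),
            "value": values.ravel(),
        }
    )

    if n_b == 1:
        aov = pg.rm_anova(
            data=df_long, dv="value", within=factor_names[0], subject="subject",
            correction=True, detailed=True,
        )
        err = aov.loc[aov["Source"] == "Error"].iloc[0]
        aov = aov.loc[aov["Source"] != "Error"].copy()
        aov["ddof1"] = aov["DF"]
        aov["ddof2"] = float(err["DF"])
    else:
        aov = pg.rm_anova(
            data=df_long, dv="value", within=list(factor_names), subject="subject",
            correction=True, detailed=False,
        )

    def col(row, *names, default=np.nan):
        for name in names:
            if name in row.index:
                return row[name]
        return default

    rows = []
    for _, r in aov.iterrows():
        eps = float(col(r, "eps", default=1.0))
        if not np.isfinite(eps):
            eps = 1.0
        df1, df2 = float(r["ddof1"]), float(r["ddof2"])
        f_val = float(r["F"]) if np.isfinite(r["F"]) else 0.0
        p_unc = float(col(r, "p_unc", "p-unc", default=1.0))
        if not np.isfinite(p_unc):
            p_unc = 1.0
        p_gg = col(r, "p_GG_corr", "p-GG-corr")
        if not np.isfinite(p_gg):
            # recompute from epsilon-shrunk dfs (pingouin omits it when
            # the correction is not triggered)
            p_gg = float(sps.f.sf(f_val, eps * df1, eps * df2)) if f_val > 0 else 1.0
        rows.append(
            {
                "effect": r["Source"],
                "F": f_val,
                "df1": df1,
                "df2": df2,
                "p_uncorrected": p_unc,
                "eps": eps,
                "df1_gg": eps * df1,
                "df2_gg": eps * df2,
                "p_gg": float(p_gg),
            }
        )
    table = pd.DataFrame(rows)

    # Bonferroni post hoc: pairwise levels of factor A within each level of B
    pairs = [(i, j) for i in range(n_a) for j in range(i + 1, n_a)]
    n_comp = len(pairs) * n_b if pairs else 1
    ph_rows = []
    for b in range(n_b):
        for i, j in pairs:
            t, dfree, p, d, _ = paired_t(values[:, i, b] - values[:, j, b], tails="two")
            ph_rows.append(
                {
                    factor_names[1]: b,
                    "level_a": i,
                    "level_b": j,
                    "t": t,
                    "df": dfree,
                    "p_uncorrected": p,
                    "p_bonf": min(1.0, p * n_comp),
                    "cohens_d": d,
                }
            )
    posthoc = pd.DataFrame(ph_rows)
    return table, posthoc


def peakstats_to_frame(stats: list[PeakStat], **extra) -> pd.DataFrame:
    """Tidy PeakStat rows (one per frequency) for CSV output."""
    df = pd.DataFrame(
        {
            "freq_hz": [s.freq for s in stats],
            "t": [s.t_value for s in stats],
            "df": [s.df for s in stats],
            "p_raw": [s.p_raw for s in stats],
            "p_fdr": [s.p_fdr for s in stats],
            "cohens_d": [s.cohens_d for s in stats],
            "degenerate": [s.degenerate for s in stats],
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df
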