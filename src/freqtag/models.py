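"""Model/Results facades over the analysis stages.

Each branch of the analysis is exposed as a model object constructed
from data whose ``fit()`` returns a results object carrying estimates,
test statistics and a ``summary()`` table — the conventional shape of
statistical modelling packages.  The underlying module-level functions
remain the primitive API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seeg as sg
from . import source as src
from . import spectral as sp
from . import stats as st
from .grids import Leadfield
from .simulate import ContactRecord, SensorEpochs

__all__ = [
    "SensorTaggingModel",
    "SensorTaggingResults",
    "SourceLocalizationModel",
    "SourceLocalizationResults",
    "ContactTaggingModel",
    "ContactTaggingResults",
]


def _subject_spectra(
    epochs: SensorEpochs, skip: float, length: float
) -> tuple[np.ndarray, np.ndarray, list[sp.EvokedResponse]]:
    """Pre-whiten, average, crop, transform: per-subject channel-average
    power spectra plus the cropped evoked responses."""
    white = sp.prewhiten(epochs)
    erfs = [sp.crop_steady_state(e, skip, length) for e in sp.average_erf(white)]
    spectra = [sp.power_spectrum(e) for e in erfs]
    freqs = spectra[0].freqs
    chan_avg = np.vstack([s.channel_average().power[0] for s in spectra])
    return chan_avg, freqs, erfs


class SensorTaggingModel:
    """Sensor-level frequency-tagging analysis of one or two conditions.

    Parameters
    ----------
    imagery, baseline : SensorEpochs
        Trial-structured epochs per condition (baseline optional).
    sensor_sides : array of str, optional
        'left' | 'right' | 'midline' per channel, enabling the
        lateralization contrast.
    f_img, f_stim : float
        Tagged frequencies (defaults 0.8 and 4 Hz).
    band : (low, high)
        Frequency range of the neighbour-bin peak scan.
    skip, length : float
        Steady-state window (seconds after onset; defaults 1.25/11.25).
    """

    def __init__(
        self,
        imagery: SensorEpochs,
        baseline: SensorEpochs | None = None,
        sensor_sides: np.ndarray | None = None,
        f_img: float = 0.8,
        f_stim: float = 4.0,
        band: tuple[float, float] = (0.5, 4.5),
        skip: float = 1.25,
        length: float = 11.25,
    ) -> None:
        self.conditions: dict[str, SensorEpochs] = {imagery.condition: imagery}
        if baseline is not None:
            self.conditions[baseline.condition] = baseline
        self.sensor_sides = sensor_sides
        self.f_img, self.f_stim = f_img, f_stim
        self.band, self.skip, self.length = band, skip, length

    def fit(self) -> "SensorTaggingResults":
        spectra: dict[str, np.ndarray] = {}
        peak_tables: dict[str, list[st.PeakStat]] = {}
        peak_powers: dict[str, dict[float, np.ndarray]] = {}
        lateralization: dict[tuple[str, float], st.PeakStat] = {}
        freqs = None
        for cond, ep in self.conditions.items():
            chan_avg, freqs, _ = _subject_spectra(ep, self.skip, self.length)
            spectra[cond] = chan_avg
            peak_tables[cond] = st.neighbor_bin_test(chan_avg, freqs, band=self.band)
            peak_powers[cond] = {
                f: np.array(
                    [st.peak_power(chan_avg[s], f, freqs) for s in range(len(chan_avg))]
                )
                for f in (self.f_img, self.f_stim)
            }
            if self.sensor_sides is not None:
                white = sp.prewhiten(ep)
                erfs = [
                    sp.crop_steady_state(e, self.skip, self.length)
                    for e in sp.average_erf(white)
                ]
                specs = [sp.power_spectrum(e) for e in erfs]
                for f in (self.f_img, self.f_stim):
                    i = sp.bin_index(freqs, f)
                    per_chan = np.vstack([s.power[:, i] for s in specs])
                    lateralization[(cond, f)] = st.lateralization_test(
                        per_chan, self.sensor_sides, f=f
                    )
        contrasts: dict[float, st.PeakStat] = {}
        if len(self.conditions) == 2:
            a, b = list(self.conditions)
            for f in (self.f_img, self.f_stim):
                contrasts[f] = st.condition_contrast(
                    peak_powers[a][f], peak_powers[b][f], tails="two", freq=f
                )
        return SensorTaggingResults(
            freqs=freqs,
            spectra=spectra,
            peak_tables=peak_tables,
            peak_powers=peak_powers,
            contrasts=contrasts,
            lateralization=lateralization,
            model=self,
        )


@dataclass
class SensorTaggingResults:
    """Per-subject spectra, peak tests, contrasts and lateralization."""

    freqs: np.ndarray
    spectra: dict[str, np.ndarray]
    peak_tables: dict[str, list[st.PeakStat]]
    peak_powers: dict[str, dict[float, np.ndarray]]
    contrasts: dict[float, st.PeakStat]
    lateralization: dict[tuple[str, float], st.PeakStat]
    model: SensorTaggingModel = field(repr=False, default=None)

    def significant_peaks(self, condition: str, q: float = 0.05) -> list[st.PeakStat]:
        return [s for s in self.peak_tables[condition] if s.p_fdr < q]

    def peak_table_frame(self) -> pd.DataFrame:
        frames = [
            st.peakstats_to_frame(tbl, condition=cond)
            for cond, tbl in self.peak_tables.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = ["Sensor-level frequency tagging", "=" * 34]
        for cond, tbl in self.peak_tables.items():
            sig = [s for s in tbl if s.p_fdr < 0.05]
            lines.append(f"condition {cond!r}: {len(sig)} FDR-significant bins")
            for s in sig:
                lines.append(
                    f"  {s.freq:6.3f} Hz  t({s.df}) = {s.t_value:6.2f}  "
                    f"p_fdr = {s.p_fdr:.2e}  d = {s.cohens_d:.2f}"
                )
        for f, c in self.contrasts.items():
            lines.append(
                f"peak-power contrast at {f:.1f} Hz: t({c.df}) = {c.t_value:.2f}, "
                f"p = {c.p_raw:.3g}, d = {c.cohens_d:.2f}"
            )
        for (cond, f), s in self.lateralization.items():
            lines.append(
                f"lateralization ({cond}, {f:.1f} Hz): t({s.df}) = {s.t_value:.2f}, "
                f"p = {s.p_raw:.3g}"
            )
        return "\n".join(lines)


class SourceLocalizationModel:
    """Minimum L1-norm source localization at one tagged frequency.

    Built from sensor epochs and a leadfield; ``fit`` pre-whitens,
    computes each subject's evoked Fourier coefficients at the target
    bin and its two neighbours, solves the cone program per bin,
    contrasts smoothed log activation against the neighbour control,
    and cluster-corrects the voxelwise paired t map.
    """

    def __init__(
        self,
        epochs: SensorEpochs,
        leadfield: Leadfield,
        freq: float,
        gamma: float = 1.0,
        fwhm: float = 5.0,
        skip: float = 1.25,
        length: float = 11.25,
        voxel_alpha: float = 0.001,
        cluster_alpha: float = 0.01,
        n_permutations: int = 1024,
        noise_tol: float | None = None,
        solver_tol: float = 1e-7,
    ) -> None:
        self.epochs = epochs
        self.leadfield = leadfield
        self.freq = freq
        self.gamma = gamma
        self.fwhm = fwhm
        self.skip, self.length = skip, length
        self.voxel_alpha, self.cluster_alpha = voxel_alpha, cluster_alpha
        self.n_permutations = n_permutations
        self.noise_tol = noise_tol
        self.solver_tol = solver_tol

    def fit(self, seed: int = 0) -> "SourceLocalizationResults":
        rlf = src.reduce_orientations(self.leadfield)
        rlf = rlf.with_weights(src.depth_weights(self.leadfield, self.gamma))
        _, freqs, erfs = _subject_spectra(self.epochs, self.skip, self.length)
        spacing = float(freqs[1] - freqs[0])
        grid = self.leadfield.grid

        target_logs, control_logs, raw_maps = [], [], []
        for erf in erfs:
            maps = {}
            for f in (self.freq - spacing, self.freq, self.freq + spacing):
                kf = src.erf_frequency_bin(erf, f)
                sol = src.solve_l1_bin(
                    kf, rlf, noise_tol=self.noise_tol, tol=self.solver_tol
                )
                maps[f] = src.rms_activation(sol, grid, condition=self.epochs.condition)
            control = src.neighbor_control_map(
                maps[self.freq - spacing], maps[self.freq + spacing]
            )
            raw_maps.append(maps[self.freq])
            target_logs.append(src.smooth_and_log(maps[self.freq], self.fwhm).values)
            control_logs.append(src.smooth_and_log(control, self.fwhm).values)

        target_arr = np.vstack(target_logs)
        control_arr = np.vstack(control_logs)
        clusters = src.voxelwise_cluster_test(
            target_arr,
            control_arr,
            grid,
            voxel_alpha=self.voxel_alpha,
            cluster_alpha=self.cluster_alpha,
            n_permutations=self.n_permutations,
            seed=seed,
        )
        return SourceLocalizationResults(
            freq=self.freq,
            grid=grid,
            activation_maps=raw_maps,
            target_log=target_arr,
            control_log=control_arr,
            clusters=clusters,
            model=self,
        )


@dataclass
class SourceLocalizationResults:
    """Activation maps and cluster-corrected localization at one bin."""

    freq: float
    grid: "src.SourceGrid"
    activation_maps: list[src.ActivationMap]
    target_log: np.ndarray
    control_log: np.ndarray
    clusters: src.ClusterResult
    model: SourceLocalizationModel = field(repr=False, default=None)

    @property
    def mean_activation(self) -> np.ndarray:
        return np.mean([m.values for m in self.activation_maps], axis=0)

    def peak_voxel(self) -> int | None:
        sig = self.clusters.significant
        if not sig:
            return None
        best = max(sig, key=lambda c: c["peak_t"])
        return best["peak"]

    def cluster_frame(self) -> pd.DataFrame:
        rows = [
            {
                "freq_hz": self.freq,
                "n_voxels": len(c["voxels"]),
                "peak_voxel": c["peak"],
                "peak_t": c["peak_t"],
                "mass": c["mass"],
                "p_fwe": c["p"],
                "significant": c["significant"],
            }
            for c in self.clusters.clusters
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Minimum L1-norm localization at {self.freq:.3f} Hz",
            "=" * 44,
            f"voxel threshold t({self.clusters.df}) > {self.clusters.t_threshold:.2f}",
            f"{len(self.clusters.clusters)} cluster(s), "
            f"{len(self.clusters.significant)} FWE-significant",
        ]
        for c in self.clusters.significant:
            pos = self.grid.positions[c["peak"]]
            lines.append(
                f"  cluster of {len(c['voxels'])} voxels, peak t = {c['peak_t']:.2f} "
                f"at ({pos[0]:.0f}, {pos[1]:.0f}, {pos[2]:.0f}) mm, p_FWE = {c['p']:.4f}"
            )
        return "\n".join(lines)


class ContactTaggingModel:
    """High-gamma envelope tagging analysis of intracranial contacts."""

    def __init__(
        self,
        records: list[ContactRecord],
        band: tuple[float, float] = (60.0, 100.0),
        f_targets: tuple[float, ...] = (0.8, 4.0),
        scan_band: tuple[float, float] = (0.5, 4.5),
        skip: float = 1.25,
        length: float | None = 11.25,
    ) -> None:
        self.records = list(records)
        self.band = band
        self.f_targets = f_targets
        self.scan_band = scan_band
        self.skip, self.length = skip, length

    def fit(self) -> "ContactTaggingResults":
        peak_rows = []
        np_rows = []
        for k, rec in enumerate(self.records):
            env = sg.highgamma_envelope(rec, self.band)
            spec = sg.envelope_spectrum(env, skip=self.skip, length=self.length)
            stats = sg.contact_peak_test(spec, band=self.scan_band)
            frame = st.peakstats_to_frame(
                stats,
                contact=k,
                region=rec.region,
                condition=rec.condition,
                subject=rec.subject_id,
            )
            peak_rows.append(frame)
            for f in self.f_targets:
                for pk in sg.normalized_peaks_per_trial(
                    spec, f, region=rec.region, condition=rec.condition
                ):
                    np_rows.append(
                        {
                            "contact": k,
                            "region": pk.region,
                            "condition": pk.condition,
                            "target_freq": pk.target_freq,
                            "trial": pk.trial,
                            "value": pk.value,
                        }
                    )
        peak_table = pd.concat(peak_rows, ignore_index=True)
        norm_peaks = pd.DataFrame(np_rows)
        region_tables = {
            f: sg.region_pool_test(
                norm_peaks.loc[np.isclose(norm_peaks["target_freq"], f)]
            )
            for f in sorted(norm_peaks["target_freq"].unique())
        }
        return ContactTaggingResults(
            peak_table=peak_table,
            normalized_peaks=norm_peaks,
            region_tables=region_tables,
            model=self,
        )


@dataclass
class ContactTaggingResults:
    """Per-contact peak tests and pooled region statistics."""

    peak_table: pd.DataFrame
    normalized_peaks: pd.DataFrame
    region_tables: dict[float, pd.DataFrame]
    model: ContactTaggingModel = field(repr=False, default=None)

    def significant_contacts(self, freq: float, q: float = 0.05) -> list[int]:
        t = self.peak_table
        sel = t.loc[(np.isclose(t["freq_hz"], freq, atol=1e-6)) & (t["p_fdr"] < q)]
        return sorted(sel["contact"].unique())

    def summary(self) -> str:
        lines = ["High-gamma envelope tagging", "=" * 28]
        t = self.peak_table
        for (contact, cond), grp in t.groupby(["contact", "condition"]):
            sig = grp.loc[grp["p_fdr"] < 0.05]
            if len(sig):
                freqs = ", ".join(f"{f:.2f}" for f in sig["freq_hz"])
                lines.append(
                    f"contact {contact} ({grp['region'].iat[0]}, {cond}): "
                    f"significant at {freqs} Hz"
                )
        for f, tbl in self.region_tables.items():
            lines.append(f"-- normalized peak at {f:.2f} Hz --")
            for _, r in tbl.iterrows():
                lines.append(
                    f"  {r['region']} [{r['condition']}] {r['test']}: "
                    f"t({r['df']}) = {r['t']:.2f}, p = {r['p']:.3g}, d = {r['cohens_d']:.2f}"
                )
        return "\n".join(lines)
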