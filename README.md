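# freqtag

Frequency-tagging analysis of rhythmic neural activity: sensor-level
spectral peak statistics, a frequency-domain minimum L1-norm (SOCP)
source estimator, and an intracranial high-gamma envelope tagging
branch — exercised end-to-end on synthetic forward-model data with
known ground truth.

## The problem

When a subject listens to a 4 Hz tone train and mentally groups the
tones into fives, two rhythms coexist in the recording: a fast
stimulus-driven response at 4 Hz and a slow internally generated
rhythm at 4/5 = 0.8 Hz.  Because both rates are known a priori, each
occupies a single predictable bin of the evoked-response spectrum, so
the top-down and bottom-up processes can be separated *in frequency*
and localized independently.  `freqtag` is for electrophysiologists
who want this analysis as a tested, reusable pipeline: spectral peak
detection with proper multiple-comparison control, source imaging of a
single frequency bin, and the matching intracranial envelope analysis.

## The statistics and the model

**Neighbour-bin peak test.**  At every bin with centre in
0.5–4.5 Hz, the power P(f) is compared with the mean of its two
flanking bins by a one-tailed paired t test across units (subjects for
sensor spectra, trials for intracranial envelope spectra), with
Benjamini–Hochberg FDR correction across bins.  Peak power is
P(f) − (P(f−Δ) + P(f+Δ))/2, which cancels any locally linear
background.  The analysis window is 11.25 s (transient first 1.25 s of
stimulation excluded), giving bin spacing 1/11.25 ≈ 0.089 Hz, so
0.8 Hz and 4 Hz are exactly bins 9 and 45.

**Minimum L1-norm source estimate.**  At one frequency bin with
complex sensor coefficients K_f and gain matrix G (reduced by SVD to
the two dominant orientations θ, φ per source), the estimator solves
the second-order cone program

    min  Σᵢ wᵢ √( ω²ᵢ,re,θ + ω²ᵢ,im,θ + ω²ᵢ,re,φ + ω²ᵢ,im,φ )
    s.t. K_f = G Ω_f

with depth weights wᵢ = ‖Gᵢ‖_F^γ (mean-normalized, default γ = 1).
The solver is an in-package ADMM basis pursuit with group
soft-thresholding and a least-squares support polish; every solve
carries a Lagrange dual certificate bounding its suboptimality.
Source activation is the RMS of the four real coefficients, contrasted
against the mean of the two neighbouring bins, smoothed (5 mm FWHM) and
log-transformed, and tested voxelwise with sign-flip max-cluster-mass
permutation FWE correction.

**Normalized peak (intracranial).**  Contacts are band-passed to
60–100 Hz; the Hilbert envelope's per-trial spectrum is tested as
above, and tagging strength is (P_target − P_neighbouring) /
(P_target + P_neighbouring) ∈ [−1, 1], pooled across same-region
contacts for one-sample and between-condition t tests.

## Worked example

Run the end-to-end demo — simulate a 20-subject tagged dataset
(one 0.8 Hz imagery source, bilateral 4 Hz stimulus sources, pink
channel noise, 64-source grid), then run all three analysis branches:

```python
from freqtag import RunConfig, run_demo

report = run_demo(RunConfig(seed=1, out_dir="demo_out"))
print(report.summary())
```

prints (abridged):

```
Sensor-level frequency tagging
==================================
condition 'imagery': 2 FDR-significant bins
   0.800 Hz  t(19) =   3.83  p_fdr = 1.28e-02  d = 0.86
   4.000 Hz  t(19) =   7.41  p_fdr = 1.14e-05  d = 1.66
condition 'baseline': 1 FDR-significant bins
   4.000 Hz  t(19) =   7.38  p_fdr = 1.22e-05  d = 1.65
peak-power contrast at 0.8 Hz: t(19) = 4.32, p = 0.000371, d = 0.97
peak-power contrast at 4.0 Hz: t(19) = -0.96, p = 0.351, d = -0.21

Minimum L1-norm localization at 0.800 Hz
============================================
voxel threshold t(19) > 3.58
1 cluster(s), 1 FWE-significant
  cluster of 1 voxels, peak t = 8.03 at (-2, 8, -2) mm, p_FWE = 0.0039

High-gamma envelope tagging
============================
contact 0 (operIFG, imagery): significant at 0.80 Hz
contact 2 (STG, imagery): significant at 4.00 Hz
-- normalized peak at 0.80 Hz --
  operIFG [imagery] one_sample_gt_zero: t(19) = 7.66, p = 1.58e-07, d = 1.71
  ...
```

Reading the output: the 0.8 Hz peak is significant only under the
imagery condition (the mental grouping rhythm), while 4 Hz is
significant under both (the tone train drives it regardless of task);
the peak-power contrast confirms the 0.8 Hz difference between
conditions and the absence of one at 4 Hz.  The source stage localizes
the 0.8 Hz bin to a single significant cluster whose peak voxel is the
injected imagery source (at (−2, 8, −2) mm on the synthetic grid), and
the synthetic inferior-frontal contact shows the 0.8 Hz envelope
modulation only during imagery.  `demo_out/` then contains the HDF5
data container, one CSV per statistics table (each row stamped with
the seed and config hash, including the z-scored display spectra), and
two figures: the channel-average spectra with the tagged bins marked
(`spectra.png`) and the two activation maps (`activation_maps.png`).

The same stages are scriptable individually — statsmodels-style model
objects (`SensorTaggingModel`, `SourceLocalizationModel`,
`ContactTaggingModel`; each `.fit()` returns a results object with
`.summary()`), or the CLI:

```bash
freqtag simulate data.h5 --seed 1
freqtag sensor --epochs data.h5 --out sensor_out
freqtag source --epochs data.h5 --freq 0.8 --gamma 1.0 --seed 1
freqtag seeg   --contacts data.h5 --band 60 100
```

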