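# Methods

`freqtag` implements a frequency-tagging analysis for experiments in
which a fast, stimulus-driven rhythm and a slow, internally generated
rhythm coexist in the same recording.  The reference paradigm is
rhythmic inner counting: a train of 50 tones at 4 Hz (one tone per
250 ms, 12.5 s of stimulation preceded by a 0.5 s baseline) that the
subject mentally organizes into groups of five, so the grouping
rhythm appears at 4/5 = 0.8 Hz.  Because both rates are known a
priori, their neural signatures occupy single, predictable bins of the
response spectrum and can be separated and localized without any
overlap in frequency.

## Sensor-level model

The per-subject analysis unit is the evoked (trial-averaged) response.
The chain is:

1. **Pre-whitening.**  Each channel is divided by its pre-stimulus
   baseline standard deviation (a diagonal noise covariance estimated
   from the 0.5 s baseline, pooled over trials, ddof 0).  This makes
   heterogeneous channel types commensurable and gives every channel
   unit baseline variance.
2. **Evoked averaging and steady-state cropping.**  Trials are
   averaged; the first 1.25 s after onset (one full grouping cycle)
   are discarded to remove the transient onset response, leaving an
   11.25 s steady-state window.  The window length is an exact
   multiple of both tagged periods, so 0.8 Hz and 4 Hz fall exactly on
   bin centres (bins 9 and 45 of a 1/11.25 ~ 0.089 Hz axis) and the
   rectangular-window FFT incurs no leakage at the tagged bins.
3. **Power spectra.**  Per channel, power is `|X_k|^2 / N` with `X_k`
   the raw DFT coefficient (no taper, no padding); the channel-average
   spectrum is the subject-level statistic.
4. **Neighbour-bin peak test.**  At every bin with centre in
   0.5–4.5 Hz, the bin's power is compared to the mean of its two
   flanking bins by a one-tailed paired t test across subjects;
   p values are Benjamini–Hochberg FDR corrected across the tested
   bins.  The flanker average cancels any locally linear background
   (including the 1/f trend to first order), which is what makes the
   test calibrated on coloured-noise spectra.
5. **Peak power, contrasts, lateralization.**  Peak power is the bin
   power minus the flanker mean; condition contrasts are two-tailed
   paired t tests on per-subject peak powers; the lateralization test
   contrasts mean power over right- vs left-hemisphere sensors.
   Cohen's d for paired designs is d_z = mean(diff)/SD(diff) = t/sqrt(n).

## Minimum L1-norm source model

At a single frequency bin, the complex sensor coefficients K_f relate
to per-source complex amplitudes through the gain (leadfield) matrix.
Each source's three Cartesian gain columns are first reduced to the
two dominant orientations (theta, phi) by SVD of the m x 3 block — the
best rank-2 approximation, discarding the weakest direction (the
discarded energy fraction is recorded per source).  The estimator
solves

    min  sum_i w_i sqrt( w_re_theta^2 + w_im_theta^2
                        + w_re_phi^2  + w_im_phi^2 )      s.t. K_f = G Omega_f

a second-order cone program: the objective is a weighted sum of
per-source Euclidean norms over the four real coefficients, which is
rotation-invariant within each source (no bias toward coordinate
axes) and yields sparse source configurations.  The depth weights
w_i = ||G_i||_F^gamma (mean-normalized, default gamma = 1) penalize
superficial high-gain sources; gamma is exposed because no canonical
value exists, and gamma = 0 disables the correction.

### Solver

No third-party conic solver is used; the program is solved by ADMM
basis pursuit with group soft-thresholding:

* x-update: exact Euclidean projection onto {A x = b} via one cached
  Cholesky factor of A A^T (2m x 2m);
* z-update: blockwise shrinkage (exact zeros off the support);
* over-relaxation (alpha = 1.6) and adaptive penalty;
* weights are absorbed into the columns (x_i = x~_i / w_i with columns
  A_i / w_i), so shrinkage thresholds are uniform regardless of the
  depth-weight spread — this preconditioning is an exact
  reformulation and is what keeps convergence fast for strongly
  depth-weighted problems;
* support polish: the detected support is refit by least squares and
  accepted when feasible and no worse — exact at vertex solutions;
* a relaxed mode replaces the equality by ||A x − b|| <= eps for
  inputs outside the gain column space (the solver raises a specific
  error advising it).

Every equality-mode solve returns a feasible point of the Lagrange
dual (max b^T y s.t. ||A_i^T y|| <= w_i), built from the ADMM dual
iterate and scaled into the feasible region; the resulting duality gap
certifies the objective's suboptimality (typically <= 1e-7 relative).
Tests additionally check the solver against an independent oracle that
minimizes a smoothed objective over the nullspace parametrization with
BFGS and mu-continuation.

A note on sparsity: solutions are vertices of the feasible set, so the
number of active sources is bounded by the number of real constraint
rows, 2m (real and imaginary parts of m sensors) — not by m.  With
8 sensors, certified-optimal solutions with up to ~13 active groups
are routinely observed on dense right-hand sides.  Exact recovery of
a planted single source is likewise not universal: at 8 sensors and
20 candidate sources a few percent of random incoherent instances
admit a multi-source combination with a strictly lower weighted
objective, and the estimator correctly returns that optimum (the dual
certificate and the independent oracle agree); recovery claims in the
tests are therefore stated as rates, with every non-recovery required
to be a certified better optimum.

### Source-level statistics

Per source, activation is the RMS of the four real coefficients
(group norm / 2; the denominator convention is arbitrary and cancels
in every contrast).  A control map is the voxelwise mean of the
activation maps at the two neighbouring bins.  Maps are smoothed on
the native grid with a Gaussian kernel (sigma = fwhm/2.3548, default
fwhm 5 mm) normalized per *source* voxel so total map mass is
conserved; a uniform map is unchanged up to boundary normalization.
Maps are then log-transformed (floor 1e-12 x map maximum) to reduce
the skewness of minimum-L1 amplitudes, and target vs control is tested
voxelwise with a one-tailed paired t (voxel p < 0.001).  Clusters are
formed under 26-neighbourhood adjacency on the cubic grid and
cluster-level family-wise error is controlled by sign-flip permutation
of the paired differences with a max-cluster-mass null (1024
permutations, or exhaustive enumeration when 2^subjects is smaller);
clusters are retained at cluster p < 0.01.  ROI values are means over
a 5 mm cube at the peak voxel, and condition x region ROI designs are
analysed by two-way repeated-measures ANOVA with Greenhouse–Geisser
correction and Bonferroni post hocs (via pingouin; validated against
longhand sums of squares in the tests).

For *detection* of an effect the cluster statistics above are the
authority; for *where a multi-source rhythm lives* the group-mean RMS
activation map is the better readout, because the t statistic rewards
low across-subject variance and can rank a stable secondary voxel
above a true source.  The end-to-end checks therefore score imagery
localization by the significant cluster's peak voxel and
stimulus-source localization by the argmax of the group-mean 4 Hz
activation map.

## Intracranial high-gamma branch

Per contact: zero-phase FIR band-pass to 60–100 Hz (Hamming design,
transition 10 Hz, >= 40 dB stop-band; one filter length at each edge
flagged and excluded), Hilbert envelope per trial, then per-trial FFT
power of the envelope over the same steady-state window convention as
the sensor branch (skip 1.25 s).  The neighbour-bin test runs with
the trial as the paired unit (df = trials − 1).  Tagging strength is
the normalized peak (P_t − P_n)/(P_t + P_n), bounded in [−1, 1] and
scale-invariant, so trials pool across same-region contacts: a
one-sample one-tailed t tests each region x condition against zero,
and a pooled-variance two-sample t (df = n1 + n2 − 2) contrasts
conditions.

## Synthetic data generator

The generator provides every input with known ground truth:

* **Leadfields** — `random-incoherent` (unit-Frobenius random gain
  blocks on a 5 mm cubic grid; the favourable regime for L1 support
  recovery, used for solver checks) and `spherical-shell` (1/d^2
  distance fall-off from a sensor shell, giving the depth bias that
  depth weighting addresses).  Sensors carry hemisphere labels from
  the sign of x.
* **Sensor epochs** — leadfield x source currents plus channel noise.
  The imagery source current ramps up within each 1.25 s cycle
  (squared cycle phase), placing energy at 0.8 Hz and its harmonics,
  mirroring the within-group build-up seen in intracranial envelopes;
  stimulus sources emit one Hann-shaped evoked pulse per tone.
  Successive stimulus sources respond with a 20 ms latency stagger
  (hemispheric response-latency asymmetry); this also decoheres the
  4 Hz phase across sources, without which two perfectly coherent
  sources form a single rank-one pattern that a sparse inverse can
  attribute to phantom locations.  Channel noise is pink by default
  (white optional) because flat noise makes low-frequency detection
  unrealistically easy.  Per-subject log-normal gain variability
  (SD 0.3) yields sensor-level effect sizes of the magnitude reported
  for this paradigm (d ~ 1 at the imagery rate, d ~ 2–4 at the
  stimulus rate).  An optional per-trial phase-jitter parameter exists
  for the imagery rhythm; no empirical value is known, so it defaults
  to zero.
* **Contacts** — a frequency-modulated carrier confined to 60–100 Hz
  with *exact* unit instantaneous amplitude, multiplied by
  1 + sum(depth cos(2 pi f t)) from stimulus onset, plus pink noise.
  The default noise level is calibrated so a depth-0.5 modulation over
  20 trials gives per-contact effect sizes d ~ 1–1.5, the scale seen
  at responsive intracranial contacts.

What the generator does **not** emulate: realistic head geometry and
correlated sensor noise, non-stationary or jittered imagery timing,
artifacts (ocular, cardiac, epileptic), volume-conduction mixing of
intracranial contacts, and between-region amplitude covariance.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the statistics under the stated model, not robustness
to real-data pathologies.

## Numerical choices and simulation sizes

* Solver tolerances: ADMM relative primal/dual 1e-9 for solver
  checks, 1e-7 inside the source pipeline; backend-free dual
  certificates accompany every equality solve.
* Frequencies must align to bin centres within 1e-3 bins
  (`validate_config` rejects e.g. 0.77 Hz against an 11.25 s window).
* Degenerate paths are explicit errors: zero-variance channels,
  zero-norm gain blocks, infeasible equality constraints, undefined
  normalized peaks, zero-SD backgrounds.
* Zero-variance paired differences report t = +/-inf with a
  degeneracy flag rather than NaN.
* Monte-Carlo checks run at a 64 Hz sensor rate with 24 sensors and a
  4 x 4 x 4 grid of 64 sources (5 mm spacing), 20 subjects x 15
  trials, and 512 Hz / 20-trial contacts — sizes chosen so the full
  suite completes in minutes while keeping every rate and window of
  the paradigm exact.  The demo pipeline uses the same sizes.

## Calibration properties worth knowing

* The sensor-variant neighbour-bin test is calibrated (empirical
  type-I ~ 0.044 at alpha = 0.05 under channel-averaged pink-noise
  nulls) and the FDR scan's family-wise false-alarm rate stays below
  0.06 at q = 0.05.
* The sEEG-variant test is slightly *conservative* (~ 0.034 at 20
  trials): single-contact envelope powers are exponential-like, and
  the right-skew of the paired differences lowers the one-tailed
  upper-tail rejection rate.  This is intrinsic to the statistic at
  these trial counts and errs on the safe side.
* The normalized-peak one-sample test is conservative by construction:
  under the null the neighbour average has half the variance of the
  target bin, making the expected normalized peak negative (~ −0.09
  for exponential powers), so rejections against zero are rarer than
  nominal.

## Known limitations

* The equality-constrained solve fits sensor noise exactly; with low
  SNR the support spreads (up to the 2m vertex bound) and the
  neighbour-bin control map is what restores specificity.  The
  relaxed (eps-ball) mode exists but has no principled default eps.
* Coherent same-phase sources at one bin are not separately
  identifiable by any single-bin sparse inverse (rank-one mixture);
  latency or phase diversity is required.
* Orientation reduction discards the weakest gain direction; sources
  oriented along it are invisible to the estimator (discarded energy
  is reported so such cases can be audited).
* Greenhouse–Geisser epsilon estimates in two-way designs with more
  than two levels per factor carry the usual small-sample inaccuracy
  (pingouin warns accordingly).
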