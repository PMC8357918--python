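# Methods

## Generative model of the synthetic cohort

Each subject `s` owns a fingerprint drawn once per cohort seed:

* alpha peak frequency `f_α ~ U(8, 12)` Hz,
* 1/f background exponent `χ ~ U(0.8, 1.4)`,
* relative band amplitudes (delta 0.5, theta 0.5, alpha 1.2, beta 0.7,
  gamma 0.2, each jittered lognormally with σ = 0.25),
* one 90×90 envelope-coupling target per band of interest (alpha, beta):
  a random modular structure (6 modules, within-module coupling 0.3–0.7,
  background 0.05, Gaussian perturbation) projected to the nearest
  positive-semidefinite correlation-like matrix with off-diagonals in
  [0, 0.8] by alternating projections (8 iterations leave box violations at
  the 1e-13 level, so the final clip keeps the smallest eigenvalue above
  −1e-8),
* per-ROI amplitudes, lognormal with σ = 0.2.

A session realizes, per ROI and band, `amplitude × carrier × envelope` plus a
1/f background.  Carriers are unit-variance Gaussian noise drawn directly on
the in-band DFT bins; the alpha carrier is additionally shaped by a Gaussian
amplitude profile (σ = 0.4 Hz) around `f_α` so the subject has a genuine
spectral peak.  Envelopes are low-pass (1 Hz) Gaussian processes mixed through
the matrix square root of the coupling target and rectified as
`max(1 + 0.5·g, 0.05)` — mostly linear in the Gaussian driver, so realized
envelope correlations increase monotonically with the target (the pipeline
asserts monotonicity, never equality, because orthogonalization and
beamformer mixing shrink the realized values).  Coupling lives on the
envelopes, never the carriers, so leakage-corrected AEC can detect it in
principle.

Sessions at 625 and 1250 Hz are synthesized on the 312.5 Hz grid and
Fourier-upsampled; all signal content sits below 49 Hz, far under the base
Nyquist, so the upsampled series is the exact band-limited interpolant and
the native-rate decimation paths still have real work to do.

Sensor noise is white Gaussian per channel, with a per-kind std equal to 0.3×
the median signal RMS of that channel kind.  Amplitude units are arbitrary
throughout: no tesla/nAm calibration exists for the scenario, and every
downstream statistic (area-normalized spectra, correlations, ranks) is
scale-free; tests assert this invariance explicitly.

What the generator does **not** emulate: cortical anatomy and realistic
volume conduction (BEM/FEM), ocular/cardiac/muscle artifacts, head movement,
drowsiness drift, cross-frequency structure, or session-to-session real
plasticity.  Passing tests therefore show that the pipeline recovers
subject-stable structure through two different sensor systems and processing
paths — not that it would survive every artifact class of real recordings.

## Geometry

Head: single sphere, radius 0.09 m (multi-sphere = per-channel centers is
supported but off by default).  Helmets: 151 axial gradiometers
(radius 0.105 m, baseline 0.05 m, radial normals) or 102 sites × (radial
magnetometer + two orthogonal planar gradiometers, baseline 0.0168 m), both
quasi-uniform Fibonacci layouts over a 110° cap.  Sources: 78 "cortical"
centroids at radius 0.06–0.075 m plus 12 "subcortical" at 0.02–0.045 m,
fixed tangential orientations (the radial direction is silent in a sphere); a
user-supplied 90-row coordinate table overrides the layout.  None of these
numbers are data-derived; they are chosen to be physically plausible and are
all configurable.

## Processing-path choices

* **Per-timepoint order of operations.**  BL: beamform at 312.5 Hz, epoch.
  FU1: decimate sensors 625→312.5 Hz, beamform, epoch.  FU2: beamform at
  1250 Hz, decimate the *source* series 4×, epoch.  This mirrors the two
  hardware pipelines the scenario describes and exercises decimation at both
  the sensor and the source level.
* **Decimation** is an order-8 Butterworth low-pass at 0.8× the new Nyquist
  applied forward-backward (zero phase — phase distortion would bias envelope
  correlations), then every k-th sample.
* **Rejection rules.**  The original workflow rejected channels and epochs
  visually; here both are deterministic.  Channels: |robust z| of
  log-variance > 4 within a channel kind.  Epochs: any channel's peak
  amplitude > 6 robust-z units of its per-channel epoch-peak distribution,
  with the MAD-based scale floored at 20% of the median peak — with ≤ 22
  epochs the raw MAD collapses toward zero and would flag ordinary envelope
  fluctuations; the floor keeps the rule sensitive to genuine spikes (tests
  inject 50× spikes) and nothing else.
* **Covariance regularization**: 5% of the mean eigenvalue on the diagonal
  (the vendor implementations' settings are unknown); configurable, logged.
* **Orientation sign** is arbitrary; fixed by making the first nonzero
  component positive.  Degenerate eigenvalue pairs (e.g. C = I) tie-break to
  the lexicographically smallest sign-fixed vector, with a warning.
* **Spectral estimator**: raw per-epoch periodogram averaged over epochs and
  ROIs (Bartlett), no taper by default (a Hann option exists); the epoching is
  fixed at 4096 samples and 15–22 epochs control variance.  Normalization to
  unit area happens per subject/timepoint *before* any group averaging, which
  is the form the per-subject KS tests need.  Peak frequency is the argmax
  bin in 4–13 Hz, no interpolation, ties toward the lower frequency.
* **AEC-c conventions**: orthogonalization is per-epoch time-domain
  regression on the band-limited signals; the two directional correlations
  are averaged *before* the (r+1)/2 rescale (affine-equivalent to the other
  order); envelopes keep their full sampling rate; the first and last 5% of
  samples are discarded before correlating (Hilbert edge guard on 13.11 s
  epochs).  Exactly collinear pairs are flagged undefined and excluded from
  the epoch average.
* **Fast path**: the all-pairs epoch kernel uses linearity of the analytic
  signal, `analytic(y − c·x) = analytic(y) − c·analytic(x)`, fused in a
  numba kernel when numba is importable; tests pin it to the direct per-pair
  implementation at 1e-9.

## Statistics

KS-D is computed on binned spectral *mass* (the spectra are densities, not
samples): D = max |ΔCDF| over bins; the optional p-value (asymptotic KS with
effective n = number of bins) is labelled approximate and never used in the
consistency pipeline.  Spearman uses the upper-triangle vectorization (4005
values) with average ranks.  The RM-ANOVA is the textbook one-way
repeated-measures decomposition, F = MS_cond / MS_cond×subj with
df = (k−1, (k−1)(n−1)) and partial η² = SS_cond/(SS_cond+SS_err) — for n = 8,
k = 3 that is F(2, 14); sums of squares at accumulated-rounding level are
treated as zero, and SS_err = 0 yields F = ∞, p = 0.  No sphericity
correction is applied.  The within-vs-between comparison is a pooled-variance
two-tailed t-test on the 24 within vs 24 between values (df = 46); reading
"average within-subject correlations" as 8 per-subject means would give
df = 14 instead, and the 24-vs-24 reading is the one consistent with df = 46.

A caveat the calibration experiment makes explicit: RM-ANOVA on the
*between*-subject values is anticonservative by construction, because all
subjects' between values at one timepoint share the same cross-subject
distances and shift together.  The null-calibration claim is therefore made,
and verified, for the within-subject values, where the three pair
distributions are exchangeable; the calibration runs on a reduced path
(source-level spectra at the common rate, no forward/inverse model) since it
exercises the statistics layer, not the physics.

## Problem sizes

Default cohort: 8 subjects × 3 sessions of 300 s (22 epochs after epoching).
The replication experiment runs 10 cohorts at 60 s sessions (4 epochs per
session) and the calibration 100 cohorts at 30 s (2 epochs) — the package's
standard experiment sizes, small enough to run on a single CPU in minutes
while leaving every statistic well inside its asymptotic regime of interest.

## Known limitations

* One scalar beamformer implementation stands in for both vendors'; "different
  systems" means different arrays, rates and noise, not different inverse
  code.
* The sphere head model makes radial sources invisible; ROI orientations are
  therefore constrained tangential in the generator.
* Realized AEC-c values are far below the imposed coupling targets (leakage
  correction plus beamformer mixing); only orderings are meaningful.
* The approximate KS p-value treats bins as independent samples, which they
  are not; D itself is the reported statistic.
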