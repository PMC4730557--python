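# Methods

This note documents the models, numerical choices and limitations of the
`rsfa` package: what each stage computes, what the synthetic-cohort
generator does and does not emulate, and therefore what a passing test
suite does and does not demonstrate about real data.

## RSFA estimation

RSFA at a voxel is the SD (n−1 denominator) of the resting BOLD series
after (1) OLS removal of a 17-column nuisance design — intercept, linear
and quadratic trends, mean white-matter signal, mean CSF signal, the six
rigid-body motion parameters and their first differences (zero-padded at
the first sample) — and (2) a zero-phase band-pass to 0.01–0.08 Hz.

Numerical choices:

- **Filter**: 4th-order Butterworth in second-order sections, applied
  forward–backward (`sosfiltfilt`), so the effective magnitude response is
  the squared single-pass response and the phase is zero. The band is the
  conventional physiological window for resting fluctuations.
- **Order of operations**: regression first, then filtering (the residual
  is exactly orthogonal to every design column before the filter touches
  it). `clean_and_filter(filter_first=True)` swaps the order; the
  literature is divided and the default is stated, not claimed optimal.
- **Design pruning**: zero-variance non-intercept columns and
  near-collinear pairs (|r| > 0.999, the later column dropped) are pruned
  with a warning. This handles degenerate synthetic inputs (constant
  motion) without failing the fit.
- **Validity**: voxels outside the union of the GM/WM/CSF masks are marked
  invalid; runs shorter than 50 volumes are rejected.

## Haemodynamic scaling of task responses

First-level model per voxel: intercept, polynomial drift (order 2 — a
desk-scale stand-in for a slow-drift high-pass basis), the six motion
parameters as regressors of no interest, and a canonical double-gamma HRF
regressor (response peak ≈ 6 s, undershoot ≈ 16 s; built by nilearn's
`compute_regressor`). HRF temporal/dispersion derivatives are omitted:
the synthetic data are generated with the canonical shape, so derivatives
would fit nothing.

Scaling divides each participant's beta by their RSFA at the same voxel.
Voxels whose RSFA falls at or below the 1st percentile of in-mask RSFA
(or is zero) are removed from the mask instead of divided — the ratio is
numerically unstable there.

Group stage: mass-univariate OLS of participant maps on age plus
covariates; t and two-sided p for the age slope. For the
scaled-minus-unscaled contrast the two map sets live on different units
(a ratio vs a raw beta), so each set is z-scored across participants per
voxel before differencing. Family-wise error is controlled by Bonferroni
or by a permutation max-t procedure (age labels permuted, default 1000
permutations, seeded); random-field theory is deliberately not used — the
synthetic grids are small and unsmoothed, so its lattice assumptions do
not apply.

## Cardiac indices

- **Beat detection**: `scipy.signal.find_peaks` with an adaptive height
  threshold (median + 0.5 × (99th percentile − median)), a prominence
  requirement at 0.3 of the same spread, and a 300-ms refractory period.
  The 99th-percentile reference tracks pulse tops even when pulses occupy
  a small fraction of samples, which keeps detection stable under 10%
  additive noise.
- **IBI cleaning**: iterated mean ± k·SD removal (k = 3). The first pass
  computes its cut-off with the single most extreme interval temporarily
  excluded, so one wild ectopic beat cannot inflate the threshold that is
  supposed to catch it; later passes use the full remaining sample;
  iteration stops at the first pass that removes nothing. The most
  extreme value is excluded in pass 1 only. Removal provenance
  (interval index → pass number) is kept on the result. The procedure is
  idempotent by construction.
- **Mean HR**: beats counted per 60-s window, averaged over windows; a
  trailing partial window contributes at its scaled rate if it covers at
  least half a window and is discarded otherwise (our rule; any
  convention only perturbs the estimate at the margin).
- **HRV power**: the cleaned IBI series, timestamped at each interval's
  ending beat, is cubic-spline resampled to 4 Hz, linearly detrended, and
  Welch-transformed (64-s segments, 50% overlap); band power is the
  integral of the PSD over 0.05–0.15 Hz (LF) or 0.15–0.4 Hz (HF), in
  ms². Records shorter than 120 s are rejected.
- **Vascular index**: PCA of the z-scored (mean HR, LF, HF) table
  (correlation-matrix PCA — the three features have incomparable units).
  PC1 is sign-oriented so its HF loading is positive: higher score =
  slower heart rate and larger HRV. Log-transforming the powers before
  PCA is a defensible alternative; standardization alone already yields
  PC1–V correlations ≈ 0.99 on synthetic cohorts.

## Band-limited sensor variability

Per-channel SD of the band-passed signal for six bands: subdelta
0.01–0.08, delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–80 Hz.
The 0.08–1 Hz gap between subdelta and delta is intentional — variability
is defined on this exact band list, not on a partition of the spectrum.
Raw-signal SD is the primary statistic; a Hilbert-envelope SD option
exists (`band_sd(..., envelope=True)`) but carries no claims. Subdelta
content requires records of at least 100 s; the generator enforces this.

The artifact flagger marks a component when its |temporal correlation|
with a reference channel reaches 3 × the SD of all component correlations
with that channel; for eye-movement references a spatial-template
correlation at 2 × the SD of all map–template correlations is additionally
required. At least 5 components are needed for the SD to mean anything,
and the rule's false-flag rate is non-trivial below ~20 components (the
tests assert the average over replicates, not single draws).

## Component reduction

A participants × features matrix is decomposed as mixing @ sources.
FastICA (scikit-learn: logcosh contrast, symmetric decorrelation,
tol 1e-6, max 1000 iterations) runs on the feature-indexed observations —
features are the samples, participants the dimensions, the group-spatial-
ICA convention. Each dimension is centred over samples, which removes any
participant-constant profile (a multiplicative global amplitude mode
vanishes at this step). Non-convergence triggers up to 5 reseeded
restarts, then an error with diagnostics.

Determinism: components are ordered by explained variance, each source is
sign-flipped to positive skewness, and mixing columns are z-scored —
repeated runs with one seed are bitwise identical.

**MDL order**: the classic eigenvalue-spectrum form — for candidate order
k, the cost is the negative log-likelihood of "k structured components +
isotropic Gaussian residual" plus ½ × (free parameters) × log(samples).
The cost depends only on eigenvalue ratios, and the two covariance
orientations share their non-zero spectrum, so the implementation uses
the smaller matrix side as the model dimension and the larger as the
sample count (centering costs one rank along the feature axis). An
i.i.d.-correction factor of the sample count is a known refinement; the
classic form is the default because the correction's subsampling scheme
is underdetermined.

## Mediation

All variables (and covariates) are z-scored, so coefficients are
standardized betas. The same covariates enter all three regressions,
which makes ab = c − c′ an algebraic identity (asserted to 1e-10 in the
tests). Bootstrap: whole participant rows resampled with replacement;
each draw refits all paths (batched normal-equation solves, so B = 10,000
at n = 335 takes seconds); draws in which IV, M or DV is constant are
discarded and more than 1% discarded is an error. The bias-corrected CI
uses z0 = Φ⁻¹(fraction of bootstrap estimates below the point estimate)
with quantile positions Φ(2z0 ± z_{1−α/2}); when the bootstrap
distribution is median-unbiased (z0 = 0) this reduces to the plain
percentile interval. The reported z is point estimate / bootstrap SE; the
reported p is the smallest alpha on the grid {0.05, 0.01, 0.001} at which
the BC interval excludes zero — inference here is CI-based, and the
Wald-style z is descriptive only.

Classification: *mediation* if the ab CI excludes zero, |c′| < |c| and
sign(ab) = sign(c); *suppression* if the CI excludes zero and |c′| > |c|;
otherwise *none*. Effect size: proportion mediated 100·|ab/c| %,
displayed to the nearest integer, undefined at c = 0.

Measured calibration at the study scale (n = 335, B = 1000, 99% CI):
coverage of a planted indirect effect ≈ 98–100/100 replicates, type-I
rate under b = 0 ≈ 1.6–2% — both recomputed by the test suite and
`scripts/acceptance.py` at run time.

## The synthetic cohort: what it emulates, what it does not

Ages are uniform on 18–88 (the emulated lifespan sample is approximately
uniform across deciles). Latents: V = 1.5 − 0.005·age + N(0, 0.175²),
N = 0.85 + 0.003·age + N(0, 0.12²), both truncated at 0.05 (downstream
stages divide by RSFA ∝ V). These defaults put corr(age, V) ≈ −0.5 —
matching the observed scale of the age–HRV path — and corr(age, N) ≈
+0.45; no published effect size pins the N slope, so it is an exposed
parameter, not a claim.

**Resting BOLD** (default 16×16×8 grid, 250 volumes, TR 1.97 s — a
desk-scale stand-in for the acquisition): five slabs along x — vascular
GM (fluctuation SD ∝ V), neural GM (SD ∝ V·(1 + 0.3(N−1)); vascular-
dominated with weak neural coupling, consistent with the vascular reading
of RSFA), null GM (constant SD), WM and CSF (two independent shared
nuisance signals). Planted fluctuations are built by filtering white
noise with the analysis band-pass, orthogonalizing against the run's own
nuisance design, and rescaling so the SD *after* the analysis filter
equals the target — amplitude targets therefore survive the full
analysis path exactly, rather than losing ~5–10% to re-filtering and to
chance absorption by 17 regressors. Drift (linear + quadratic),
motion-coupled components (in the span of the motion regressors) and
white noise are added on top.

**Task BOLD**: brief events at SOA 3.94 s with 1-s duration and response
amplitude 3 (arbitrary signal units) — an efficiency-driven desk-scale
design. True amplitude is V in the vascular region (age-flat neural
drive) and N·V in the neural region, so the unscaled beta tracks the
product and the scaled beta tracks the neural drive.

**Physiology**: beat times integrate an instantaneous IBI = base interval
(set by V through a target heart rate, 75 − 15(V − 1.25) bpm) modulated
by one LF (0.10 Hz) and one HF (0.25 Hz) sinusoid with fractional depths
∝ V; a configured 2% of beats are displaced by ±40% of the local
interval (ectopic beats — large enough to exercise the 3-SD rejection,
small enough not to destroy the series). The waveform is a 50-Hz train
of Gaussian pulses.

**Sensors** (default 32 channels at 200 Hz for 120 s — desk-scale
analogues of a 102-magnetometer 1-kHz array): each channel sums six
band-limited noise components with exactly planted SDs. Per band, the
per-channel SD is base(N, age) × (1 + 0.6(l1·p1(c) + l2·p2(c))) with two
narrow focal channel patterns p1, p2 (deliberately sharply peaked:
focal topographies are strongly super-Gaussian across channels, which is
what makes them identifiable by ICA) and loadings l1 (∝ standardized N)
and l2 (free). Band-specific age slopes multiply the base SD.

Not emulated: realistic vascular physiology, respiration/CO₂ dynamics,
anatomical structure, scanner artifacts, spatial autocorrelation,
head-movement field distortions, ECG morphology. Passing tests show the
*estimators and inference machinery* recover planted structure under this
generative model; they are silent on acquisition-specific confounds of
real recordings.

## Problem sizes in the shipped checks

The test suite and acceptance script run at sizes chosen to make each
check statistically decisive while keeping the whole battery at minutes
on one CPU: the scaling experiment uses n = 100 participants on the
16×16×8 grid; bootstrap coverage uses 100 replicate cohorts at n = 335
with B = 1000; the type-I simulation uses 500 replicates; the multimodal
study in the acceptance script uses n = 120 with 24 channels and 100-s
sensor records. B = 10,000 (the full-analysis default) appears in the
worked example; calibration loops use B = 1000, which changes CI
endpoints by less than the Monte-Carlo tolerance of the checks.

## Known limitations

- The generator's task and rest noise are white in time; real BOLD noise
  is autocorrelated, which would widen first-level standard errors.
- The mediation z and p conventions are CI-based, not the Wald
  statistics some toolboxes print; numerical agreement with published
  z columns is not expected and not claimed.
- The MDL criterion assumes an isotropic residual; strongly structured
  noise (e.g. spatially correlated sensor noise) can inflate the selected
  order.
- `flag_artifact_components` is a generic correlation-threshold flagger;
  it does not build blink/cardiac template topographies from data.
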