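# rsfa

**Dissociating vascular from neural contributions to ageing effects in BOLD
fMRI**, with resting-state fluctuation amplitude (RSFA) as the scaling
quantity, plus the cardiac, electrophysiological and statistical machinery
that the question requires.

## The problem

The BOLD signal is a composite: a task response is neural drive multiplied
by vascular gain, and vasculature changes with age. An apparent age-related
"decline in activation" can therefore be purely vascular. RSFA — the SD of
the nuisance-cleaned, 0.01–0.08 Hz band-passed resting BOLD series at a
voxel — is a practical proxy for that vascular gain. This package
implements the full analysis around that idea:

- **RSFA mapping** (`rsfa.fluctuation`): regress out 17 nuisance terms
  (intercept, linear/quadratic trends, WM and CSF mean signals, 6 motion
  parameters and their first differences), zero-phase band-pass
  0.01–0.08 Hz, take the voxelwise SD.
- **Haemodynamic scaling** (`rsfa.task`): canonical double-gamma HRF GLM
  per voxel; scaled beta = β/RSFA at the same voxel; mass-univariate group
  regressions of unscaled, scaled and scaled-minus-unscaled maps on age,
  with Bonferroni or permutation max-t family-wise error control.
- **Cardiac vascular index** (`rsfa.cardiac`): beat detection, the
  iterated mean ± 3 SD interbeat-interval cleaning rule (first pass
  computed with the single most extreme interval temporarily excluded),
  mean heart rate per 60-s window, LF (0.05–0.15 Hz) and HF (0.15–0.4 Hz)
  HRV power from a 4-Hz cubic-spline tachogram via Welch, and a PCA of
  (HR, LF, HF) whose first component is the vascular-health score.
- **Band-limited sensor variability** (`rsfa.bands`): per-channel SD of
  band-passed MEG-style signals for subdelta 0.01–0.08, delta 1–4, theta
  4–8, alpha 8–13, beta 13–30 and gamma 30–80 Hz; grand means across
  channels; a 3-SD/2-SD correlation-threshold artifact-component flagger.
- **Component reduction** (`rsfa.decompose`): participants × features
  variability matrices factorized by MDL-ordered FastICA (tanh contrast,
  symmetric decorrelation) into z-scored participant loadings and source
  maps, with loading–age statistics.
- **Mediation analysis** (`rsfa.mediation`): three-variable OLS path
  models with covariates; indirect effect ab = a·b (= c − c′ exactly);
  bias-corrected bootstrap CIs (default B = 10,000, 99% CI);
  mediation-vs-suppression classification; proportion mediated
  100·|ab/c| %.
- **Synthetic cohort** (`rsfa.simulate`): a full study generator —
  ~335 adults aged 18–88 with a latent vascular gain V declining with age
  (driving RSFA and HRV), an independent neural amplitude N (driving
  sensor variability and task responses), resting/task BOLD on a labelled
  voxel grid, pulse waveforms with LF/HF modulation and planted ectopic
  beats, and multichannel sensor runs with planted spatial patterns — all
  with known ground truth so every stage is testable.

## The statistics at the core

For participant i with independent variable IV (age), mediator M and
dependent variable DV, all z-scored, the three regressions (covariates in
every model):

```
M  = i1 + a·IV            + e1
DV = i2 + c·IV            + e2
DV = i3 + b·M  + c′·IV    + e3
```

The indirect effect is ab = a·b and equals c − c′ identically under OLS.
Inference uses the bias-corrected bootstrap: resample participants B
times, and with z0 = Φ⁻¹(fraction of bootstrap estimates below the point
estimate), read the CI at bootstrap quantiles Φ(2z0 ± z_{1−α/2}).
Mediation: the ab CI excludes 0, |c′| < |c|, sign(ab) = sign(c).
Suppression: the ab CI excludes 0 but |c′| > |c| — removing the mediator's
share *strengthens* the direct effect.

## Worked example

`examples/07_mediation.py` generates an n = 335 chain with standardized
paths (a, b, c′) = (−0.5, 0.3, −0.15) and runs the full
bias-corrected bootstrap:

```
n = 335, B = 10000, CI level = 99%

path      beta     SE      z      99% CI
a       -0.503  0.047  -10.77  [-0.618, -0.378]
b       +0.259  0.055  +4.70  [+0.119, +0.406]
c       -0.402  0.048  -8.32  [-0.523, -0.273]
c_prime -0.271  0.055  -4.90  [-0.412, -0.122]
ab      -0.130  0.030  -4.39  [-0.218, -0.061]

classification: mediation
proportion mediated: 32% (population value 50%; one n=335 draw carries sampling error)
```

The ab interval excludes zero and the direct effect shrank, so the
mediator accounts for a reliable share of the age effect. Each script in
`examples/` demonstrates one capability the same way: build or load a
small input, run the method, print what it means
(`01_simulate_study` … `07_mediation`).

`examples/03_task_scaling.py` shows the central scaling result on
synthetic data — a planted vascular-only age decline is 100% "significant"
before scaling, abolished in ~95% of voxels after scaling, while a planted
neural age increase survives scaling in 100% of its voxels.

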