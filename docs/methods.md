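# Methods

This note documents the models implemented in `infotms`, their assumptions,
the default parameter choices and why they were made, and what the synthetic
generator does and does not emulate.

## Task design generator

A session is 6 runs of 80 trials. Each run presents the four AGNG miniblocks
("Go Happy/No-Go Fear", "Go Fear/No-Go Happy", "Go Happy/No-Go Neutral",
"Go Fear/No-Go Neutral") of 20 trials each (15 Go, 5 No-Go, shuffled), in one
of two fixed Latin-square-style orders selected by `run_order_id`. A trial is
a 500 ms fixation, a 500 ms face, and an inter-trial interval drawn from an
exponential distribution with rate 0.8 s⁻¹ above a 2.75 s floor, rejected
above 7.0 s. The rate is a package choice: the interval bounds are fixed by
the task, the rate is not, and a mean of ~1.1 s above the floor gives an
expected run length of ≈ 390 s, comfortably inside the 444 s acquisition
window (222 volumes at TR = 2 s) while keeping the design efficient. Runs
begin with an 8 s lead-in so that the four volumes discarded before analysis
contain no events. A schedule that exceeds the window is resampled a bounded
number of times before `DesignGenerationError` is raised. Neutral faces occur
only as No-Go cues (the miniblock names admit no Go-Neutral cell); Go trials
are always emotional.

## Behavior model

Trial correctness is Bernoulli with cell probabilities

* Go: `p_go_correct` (default 0.96);
* No-Go: `p_nogo_correct_base − α·tms_nogo_decrement + (1−α)·δ·1[Negative]`,
  defaults 0.78, 0.025 and δ = 0.08.

α is the attenuation factor (0 = no stimulation, 1 = full disruption). The
decrement term is a package addition: disrupting goal representations should
impair inhibitory performance overall, not only remove the negative-cue
advantage, and 2.5 points combined with the loss of the 8-point boost in one
of three No-Go valence cells reproduces an overall No-Go impairment of ≈ 5
points. Defaults put overall error near 8%, a typical AGNG error rate.
RTs for presses are lognormal (μ = −0.8 log-s, σ = 0.25; median ≈ 0.45 s).
RT is present exactly when the response is a press.

## BOLD forward model

Voxels live on a regular grid (default 14 × 14 × 10 at 2.5 mm isotropic). A
`RegionLayout` assigns disjoint voxel sets to roles: `goal_pattern` (inside
the `anatomical_mask` used to constrain the searchlight), `valence_pattern`,
`seed`, `remote`, and `brain_mask`. Every trial contributes an HRF-convolved
500 ms boxcar times a per-voxel amplitude:

* **Goal region** — amplitude `m₀ + ½·s_g·u_g·(±1 Go/No-Go) + ½·s_v·w·(±1
  Neg/Pos)`, where `u_g` and `w` are fixed zero-sum, unit-norm, mutually
  orthogonal direction vectors drawn once per subject (`PatternBasis`), and
  `s_g = (1−α)·d_sep·σ_noise`, `s_v = valence_separation·σ_noise` (σ_noise
  is replaced by 1 in the noiseless limit so that debugging runs still carry
  signal). Zero-sum directions make the region-mean response independent of
  α — attenuation removes multivoxel information without changing univariate
  activation, which is exactly the specificity property the pipeline must
  detect. Valence information is planted in the goal region (never
  attenuated) in addition to the dedicated valence region; without it, the
  "valence decoding unchanged under attenuation" control would hold only
  vacuously at chance level.
* **Attenuation mask** — α can be restricted to a voxel subset. The
  orchestrator passes the selected 5 mm target ROI, the in-silico analogue of
  stimulating the individualized site rather than the entire pattern-coding
  region; goal voxels outside the ROI keep their information, which is why a
  non-individualized anatomical-mask ROI loses less decoding than the target
  ROI.
* **Seed/remote coupling** — the seed region carries the task response plus a
  slow AR fluctuation (SD 1.0, needed to identify the interaction separately
  from the psychological main effect); the remote region receives
  `(β_c + (1−α)·γ_c·x_neg(t))·seed(t)`, with `x_neg` the HRF-convolved
  negative-cue regressor. γ_c is the PPI ground truth: the fitted
  negative-minus-positive interaction contrast recovers it.
* **Noise** — AR(1) in time (default φ = 0.4 would be typical of TR = 2 s
  data; 0.3 is used to keep runs mildly autocorrelated), spatially smoothed
  with a Gaussian kernel (default FWHM 2.5 mm = one voxel) and rescaled to
  unit marginal SD before multiplying by `noise_sd`. An optional lognormal
  per-voxel SD jitter produces heterogeneous variances to exercise noise
  normalization, and optional spike volumes (probability per volume, default
  0) exercise the motion-scrubbing path.

Default planted effect sizes are `pattern_separation = valence_separation =
0.6`. Because the pattern directions are high-spatial-frequency (zero-sum)
while the noise is spatially smooth, whitening recovers them efficiently;
0.6 puts baseline target-ROI decoding around AUC 0.8 at desk scale — clearly
above chance with headroom below ceiling, so run-level AUC variance is
non-degenerate and the mixed models behave. Larger separations saturate the
decoder at AUC 1.0, which no real fMRI study attains.

## Single-trial GLM (Least-Squares-All)

Per run, after discarding the first 4 volumes: one design column per trial
(boxcar convolved with the HRF on a 0.1 s grid, then decimated to volume
times; onsets are not rounded), a discrete-cosine high-pass basis with
K = ⌊2·N·TR/cutoff⌋ columns (cutoff 90 s) — the in-model equivalent of a
high-pass filter that keeps residual degrees of freedom explicit — one
indicator column per spike volume, and an intercept. The model is fit by OLS
per voxel; trial betas and residuals are returned. Rank deficiency (e.g.,
duplicate onsets) is reported with the offending columns via pivoted QR.
Temporal autocorrelation is not prewhitened at the GLM stage; the decoding
pipeline consumes betas and residuals only, and voxel-space noise structure
is handled by multivariate noise normalization downstream.

The HRF is a difference of gamma densities parameterized by peak *times*:
shape = 1 + delay/dispersion, scale = dispersion, so the default kernel's
argmax is exactly 6 s (and the undershoot's at 16 s), with undershoot ratio
1/6 and 32 s support, peak-normalized to 1.

## Multivariate noise normalization

Residuals are pooled across a session's runs (demeaned per run) and their
covariance is shrunk toward its diagonal with the closed-form optimal
intensity λ* = Σ_{i≠j} Var(ŝ_ij) / Σ_{i≠j} ŝ_ij², clipped to [0, 1]
(Schäfer–Strimmer estimator; the variance term is computed from moment
matrices, never materializing the T × V × V array). Eigenvalues are floored
at 1e−10, guaranteeing SPD. Whitening multiplies each trial vector by
Σ^(−1/2) (default; the standard multivariate noise normalization) or Σ^(−1)
(`mode="inv"`, the literal "inverted and multiplied" reading); both are
implemented and tested, and whitening is exactly invertible by Σ^(+1/2).

## Decoding

L2-penalized logistic regression (C = 1, balanced class weights, lbfgs,
tol 1e−6, max 1000 iterations — deterministic given data). Features are
z-scored per voxel with training-fold statistics only (leakage-free; the
fold-wise choice is the conservative reading of "z-scored data").
Leave-one-run-out cross-validation scores each held-out run by the AUC of the
decision values (Mann–Whitney; ties count ½). Permutation nulls shuffle
labels within run — preserving per-run class counts and respecting run
exchangeability — and report p = (1 + #{null ≥ observed}) / (1 + n_perm).

## Searchlight targeting

Sphere membership is computed in voxel-index space: integer offsets with
‖o‖ ≤ radius (radius 3 voxels ≡ 7.5 mm at 2.5 mm voxels; 123 offsets), in
fixed lexicographic order. Spheres are clipped at grid and brain-mask
borders with no minimum-voxel threshold. Every voxel of the constraint mask
receives the mean cross-validated AUC of its sphere; the map is kept
unthresholded and its maximum (ties broken to the smallest linear index,
deterministically) becomes the target. The target ROI comprises voxels whose
centers lie strictly within 5 mm of the peak — 27 voxels away from edges; the
strict inequality is the reading under which the 5 mm/2.5 mm ROI is the
27-voxel ball. Target selection uses baseline-session betas only.

## PPI

Per run: HRF-convolved regressors for negative and positive faces, the
demeaned seed time series, interactions formed as seed × *mean-centered*
psychological regressor (the FEAT convention; centering is what makes the
interaction separable from the seed main effect), drift columns and an
intercept; OLS on the remote time series. The coupling contrast is
β_ppi(negative) − β_ppi(positive). Interactions are formed on the BOLD-level
seed series (no deconvolution), matching FEAT-style PPI. Run-wise contrasts
beyond ±4 SD of the across-subject mean are flagged and excluded; counts and
percentages are reported. In the orchestrator the PPI seed is the layout's
dedicated seed region — the stand-in for the individualized site — because
layout regions are disjoint by construction.

## Group statistics

Run-level records are analyzed with linear mixed models (statsmodels
MixedLM). Crossed subject and run random factors use the single-group
variance-component formulation; models with random slopes group by subject
and drop slopes in the fixed order TMS-site, valence, action-goal before
falling back to a random intercept, then to OLS (flagged on the estimate).
Wald p-values use the normal approximation; `t = B/SE` exactly. Accuracy is
modeled at the cell-proportion level per run in percent (the reporting scale
of the behavioral results); Neutral cells are excluded from the factorial
model because the design has no Go-Neutral cell. Besides the omnibus
goal × valence × session Wald test, the model reports the focused 1-df
interaction contrast (baseline negative-cue boost minus each TMS session's
boost) — with 5 No-Go trials per miniblock the omnibus has ≈ 75% power at
δ = 8 points and n = 31, whereas the focused contrast, which is also the
pairwise comparison a study would report, has ≈ 90%. Cohen's d is the mean
difference over the pooled SD (unpaired) or over the SD of differences
(paired).

## Orchestration and problem sizes

`run_experiment` derives all randomness from one `SeedSequence`; reports are
byte-identical across repeated calls with the same config and seed. Session
order effects and carryover are not modeled. Default `n_subjects = 12` keeps
a full replication at a few minutes on one core (31 subjects, the study-scale
n, is a config change); the test suite uses 2–3 subjects, a 10 × 10 × 8 grid
with a 19-voxel goal blob and a 64-voxel constraint mask, 3-run sessions for
searchlight recovery, and 50–200 permutations — sizes chosen so the whole
suite completes in minutes while leaving every statistical check
well-identified.

## What the generator does and does not emulate

It emulates: the AGNG trial structure and timing, planted multivoxel
class information with controllable separation, valence-modulated functional
coupling, AR(1)-plus-smooth noise, heterogeneous voxel variances, motion
spikes, and attenuation of information and coupling restricted to a
stimulated site. It does not emulate: image acquisition and preprocessing
(motion, slice timing, distortion, registration), hemodynamic variability
across voxels or subjects, non-Gaussian physiological noise, anatomical
variability of region geometry, carryover between sessions, or any
neurophysiology of stimulation beyond a multiplicative attenuation. Passing
tests therefore demonstrate that the analysis chain is correct and calibrated
under its stated generative assumptions — not that those assumptions capture
real fMRI data.

## Numerical choices

Convolution at 0.1 s resolution (TR/20), decimated to volume onsets; DCT
columns unit-normalized; eigenvalue floor 1e−10 in whitening; logistic
solver tolerance 1e−6; searchlight ties resolved by C-order linear index;
empty-region, rank-deficiency, non-finite-data and degenerate-SD conditions
raise informative errors rather than propagating NaNs. Degenerate
zero-variance inputs to the mixed models return B = 0 with p = 1 rather than
failing.
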