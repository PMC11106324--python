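# infotms

**In-silico information-based TMS targeting on synthetic affective Go/No-Go fMRI.**

Information-based TMS targets a stimulation site at the peak of a subject's
multivariate decoding map: a searchlight classifier locates where a task
variable (here, the action goal *Go* vs *No-Go* during emotional-face
processing) is most decodable within an anatomical mask, and an inhibitory
stimulation protocol (cTBS) is aimed at that individualized site. Evaluating
such a pipeline on real data is expensive — three scanning sessions per
subject — and none of its stages can be unit-tested against ground truth,
because the truth is unknown.

`infotms` provides the complete analysis chain together with a synthetic
generator in which the ground truth is *planted* and parameterized, so every
stage is testable end to end:

* **Task/behavior generator** — affective Go/No-Go (AGNG) sessions: 6 runs ×
  4 miniblocks × 20 trials (15 Go / 5 No-Go), 500 ms faces, truncated
  exponential ITIs in 2.75–7 s, 222 volumes/run at TR = 2 s; Bernoulli
  accuracy with a negative-cue No-Go boost δ and lognormal RTs.
* **BOLD forward model** — double-gamma HRF responses with a planted
  multivoxel Go/No-Go pattern (class-mean separation *d*·σ_noise), a valence
  pattern, valence-modulated seed→remote coupling (the PPI ground truth), and
  AR(1) + spatially smoothed Gaussian noise. A cTBS-like attenuation factor
  α ∈ [0, 1] scales the planted pattern and coupling modulation.
* **Single-trial GLM** — Least-Squares-All: one HRF-convolved regressor per
  trial plus DCT high-pass (90 s), spike regressors and intercept; OLS betas
  and residuals.
* **Multivariate noise normalization** — residual covariance Σ with
  Schäfer–Strimmer diagonal-target shrinkage; patterns whitened by Σ^(−1/2)
  (or Σ^(−1)).
* **Decoding** — leave-one-run-out cross-validated l2 logistic regression
  (C = 1, balanced class weights, train-fold z-scoring) scored by AUC, with
  within-run label-permutation nulls.
* **Searchlight targeting** — 3-voxel (7.5 mm) spheres constrained to an
  anatomical mask; the unthresholded map's peak defines the target and a 5 mm
  ROI around it.
* **PPI connectivity** — demeaned seed time course × mean-centered valence
  regressors; negative-minus-positive interaction beta per run, ±4 SD
  outlier screening.
* **Group statistics** — mixed-effects models with subject and run as random
  factors: AUC − 0.5 intercepts, TMS-session contrasts, the accuracy model
  over goal × valence × session with random slopes, Cohen's d, and the
  coupling–decoding slope.

The orchestrator (`run_experiment`) replays the full three-session design —
baseline (target discovery), control TMS (α = 0), target TMS (α = 1 at the
selected site) — and checks that the qualitative result pattern is
recoverable: target-site decoding collapses to its permutation null while
valence decoding and mean activation are untouched, the negative-cue No-Go
advantage disappears, and seed–remote coupling drops and tracks run-wise
decoding.

## Worked example

```bash
infotms run-experiment --config cfg.json --seed 4 --out out/
```

with `cfg.json` = `{"n_subjects": 2, "n_permutations": 10}` prints

```
baseline: mean AUC = 0.787 (perm p = 0.091)
control_tms: mean AUC = 0.797 (perm p = 0.091)
target_tms: mean AUC = 0.506 (perm p = 0.455)
report written to out/report.json
```

Baseline and control-TMS sessions decode the action goal from the selected
target ROI well above chance (mean AUC ≈ 0.79; the permutation p is at its
floor of 1/11 given 10 permutations), while in the target-TMS session
decoding falls to chance (AUC ≈ 0.51) and is indistinguishable from its
permutation null — the planted attenuation is recovered. `report.json`
additionally carries the mixed-model session contrasts, the behavioral
goal × valence × session contrasts, PPI coupling by session, the
coupling–decoding slope, and per-subject target coordinates with their
distance from the planted pattern region.

The same from Python:

```python
from infotms import ExperimentConfig, run_experiment
report = run_experiment(ExperimentConfig(n_subjects=12, master_seed=0))
print(report.session_summary)
```

`infotms simulate --seed N --out dir/` writes one synthetic session to disk
(BIDS-style `events.tsv`, NIfTI BOLD volumes and region masks, and a
ground-truth JSON sidecar) for use with external tools.

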