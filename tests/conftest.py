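"""Shared fixtures: compact layouts, synthesized sessions, and record simulators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from infotms import (
    BehaviorParams,
    ExperimentConfig,
    GroundTruthSpec,
    RegionLayout,
    generate_session_design,
    make_pattern_basis,
    run_experiment,
    simulate_behavior,
    synthesize_run,
)
from infotms.bold import _ball, _box
from infotms.glm import concat_betasets, fit_run


def compact_layout(grid=(10, 10, 8)) -> RegionLayout:
    """Small grid for fast tests: 19-voxel goal blob inside a 64-voxel mask."""
    return RegionLayout(
        grid_shape=grid,
        regions={
            "goal_pattern": _ball((4, 4, 4), 1.5),
            "valence_pattern": _ball((8, 8, 2), 1.0),
            "seed": _ball((8, 1, 5), 1.0),
            "remote": _ball((1, 8, 5), 1.0),
            "anatomical_mask": _box((2, 2, 2), (6, 6, 6)),
            "brain_mask": _box((0, 0, 0), grid),
        },
    )


@pytest.fixture(scope="session")
def layout():
    return compact_layout()


def synthesize_session(
    layout: RegionLayout,
    truth: GroundTruthSpec,
    seed: int,
    n_runs: int = 6,
    behavior: BehaviorParams | None = None,
):
    """Generate, simulate and GLM-fit ``n_runs`` runs of one session.

    Returns (betaset over all grid voxels, list of residual sets, design).
    """
    rng = np.random.default_rng(seed)
    design = generate_session_design(1 + seed % 2, seed)
    if behavior is not None:
        design = simulate_behavior(design, behavior, rng)
    basis = make_pattern_basis(layout, np.random.default_rng(seed + 10_000))
    fits = []
    for r in range(1, n_runs + 1):
        run = synthesize_run(design.run_trials(r), layout, truth, rng=rng, basis=basis)
        fits.append(fit_run(run))
    betas = concat_betasets([b for b, _ in fits])
    return betas, [res for _, res in fits], design


def gaussian_patterns(
    rng: np.random.Generator,
    d_sep: float,
    n_runs: int = 6,
    per_run: int = 40,
    n_voxels: int = 12,
    p_positive: float = 0.5,
):
    """Two-class Gaussian trial patterns with mean-vector distance ``d_sep``."""
    direction = rng.standard_normal(n_voxels)
    direction /= np.linalg.norm(direction)
    X, y, runs = [], [], []
    for r in range(1, n_runs + 1):
        labels = (rng.random(per_run) < p_positive).astype(int)
        # guarantee both classes per run
        labels[0], labels[1] = 0, 1
        signs = 2.0 * labels - 1.0
        X.append(
            rng.standard_normal((per_run, n_voxels))
            + 0.5 * d_sep * np.outer(signs, direction)
        )
        y.append(labels)
        runs.append(np.full(per_run, r))
    return np.vstack(X), np.concatenate(y), np.concatenate(runs)


def simulate_behavior_cells(
    rng: np.random.Generator,
    n_subjects: int = 31,
    delta: float = 0.08,
    p_go: float = 0.96,
    p_nogo: float = 0.78,
    decrement: float = 0.025,
    subject_sd: float = 0.03,
    alphas: dict | None = None,
) -> pd.DataFrame:
    """Run-level accuracy cells from the Bernoulli behavior model (fast path)."""
    if alphas is None:
        alphas = {"baseline": 0.0, "control_tms": 0.0, "target_tms": 1.0}
    counts = {
        ("Go", "Positive"): 30,
        ("Go", "Negative"): 30,
        ("No-Go", "Negative"): 5,
        ("No-Go", "Positive"): 5,
    }
    rows = []
    for s in range(n_subjects):
        subj_eff = subject_sd * rng.standard_normal()
        for session, a in alphas.items():
            for r in range(1, 7):
                for (goal, valence), n in counts.items():
                    if goal == "Go":
                        p = p_go
                    else:
                        p = p_nogo - a * decrement + (1 - a) * delta * (valence == "Negative")
                    p = float(np.clip(p + subj_eff, 0.0, 1.0))
                    rows.append(
                        {
                            "subject": s,
                            "session": session,
                            "run": r,
                            "action_goal": goal,
                            "valence": valence,
                            "accuracy": 100.0 * rng.binomial(n, p) / n,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def experiment_report():
    """One small but complete three-session experiment, shared across tests."""
    config = ExperimentConfig(n_subjects=3, n_permutations=50, master_seed=11)
    return run_experiment(config)


@pytest.fixture(scope="session")
def searchlight_recovery():
    """Peak-recovery experiment: searchlight maps over 25 seeded sessions at
    d_sep = 2 plus one no-signal null map; shared between the searchlight and
    acceptance suites."""
    from infotms import GroundTruthSpec, SphereSpec, run_searchlight, select_target

    lay = compact_layout()
    centroid = lay.regions["goal_pattern"].mean(axis=0)
    brain = lay.mask_volume("brain_mask")
    anat = lay.mask_volume("anatomical_mask")
    spec = SphereSpec(3.0)
    n_seeds = 25
    distances = []
    for seed in range(n_seeds):
        betas, _, _ = synthesize_session(
            lay, GroundTruthSpec(pattern_separation=2.0), seed=seed, n_runs=3
        )
        vol = betas.betas.reshape(-1, *lay.grid_shape)
        sl = run_searchlight(
            vol, (betas.action_goal == "Go").astype(int), betas.run_index, brain, anat, spec
        )
        sel = select_target(sl, brain)
        distances.append(float(np.linalg.norm(np.array(sel.center) - centroid)))
    betas, _, _ = synthesize_session(
        lay, GroundTruthSpec(pattern_separation=0.0), seed=1234, n_runs=6
    )
    vol = betas.betas.reshape(-1, *lay.grid_shape)
    sl = run_searchlight(
        vol, (betas.action_goal == "Go").astype(int), betas.run_index, brain, anat, spec
    )
    null_scores = sl.score_volume[np.isfinite(sl.score_volume)]
    return {
        "distances_voxels": distances,
        "radius_voxels": spec.radius_voxels,
        "n_seeds": n_seeds,
        "null_scores": null_scores,
    }
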