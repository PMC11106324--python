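"""Single-trial (Least-Squares All) GLM estimation.

Every trial receives its own HRF-convolved regressor in one simultaneous
per-run model, alongside discrete-cosine drift columns (high-pass equivalent,
90 s cutoff), optional motion-spike indicator columns, and an intercept.
Ordinary least squares yields one beta pattern per trial plus residuals, which
feed the downstream multivariate noise normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hrf as _hrf
from .bold import BOLDRun
from .design import TrialEvent

__all__ = [
    "DesignMatrix",
    "TrialBetaSet",
    "ResidualSet",
    "RankDeficiencyError",
    "drop_initial_volumes",
    "build_dct_highpass",
    "build_lsa_design",
    "fit_lsa",
    "fit_run",
    "concat_betasets",
]

DCT_CUTOFF = 90.0


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; offending columns are reported."""


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_timepoints, n_columns)
    column_roles: list[str]
    tr: float

    @property
    def trial_columns(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.column_roles) if r.startswith("trial_")])


@dataclass
class TrialBetaSet:
    """Trials x voxels beta matrix with per-trial labels."""

    betas: np.ndarray  # (n_trials, n_voxels)
    action_goal: np.ndarray
    valence: np.ndarray
    run_index: np.ndarray
    correct: np.ndarray
    whitened: bool = False

    def __post_init__(self) -> None:
        n = self.betas.shape[0]
        for name in ("action_goal", "valence", "run_index", "correct"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n} trials")
            setattr(self, name, arr)

    def filter_correct(self) -> "TrialBetaSet":
        keep = self.correct.astype(bool)
        return TrialBetaSet(
            betas=self.betas[keep],
            action_goal=self.action_goal[keep],
            valence=self.valence[keep],
            run_index=self.run_index[keep],
            correct=self.correct[keep],
            whitened=self.whitened,
        )

    def select_voxels(self, idx: np.ndarray) -> "TrialBetaSet":
        return replace(self, betas=self.betas[:, idx])


@dataclass
class ResidualSet:
    residuals: np.ndarray  # (n_timepoints, n_voxels)
    run_index: int = 0


def drop_initial_volumes(run: BOLDRun, k: int = 4) -> BOLDRun:
    """Discard the first ``k`` volumes and shift event onsets by ``k * tr``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return run
    if k >= run.n_timepoints:
        raise ValueError(f"cannot drop {k} of {run.n_timepoints} volumes")
    shift = k * run.tr
    if any(t.onset < shift for t in run.design):
        raise ValueError("trial onsets fall inside the dropped volumes")
    new_design = [replace(t, onset=t.onset - shift) for t in run.design]
    return BOLDRun(
        data=run.data[:, k:],
        layout=run.layout,
        tr=run.tr,
        design=new_design,
        truth=run.truth,
        seed_used=run.seed_used,
        spike_volumes=[v - k for v in run.spike_volumes if v >= k],
    )


def build_dct_highpass(n_timepoints: int, tr: float, cutoff: float = DCT_CUTOFF) -> np.ndarray:
    """Unit-norm discrete-cosine drift columns spanning periods > ``cutoff`` s.

    Column count K = floor(2 * n * tr / cutoff), the standard DCT high-pass
    basis size.
    """
    if n_timepoints < 2 or tr <= 0:
        raise ValueError("degenerate run length")
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed 2 * tr")
    k_max = int(np.floor(2.0 * n_timepoints * tr / cutoff))
    n = np.arange(n_timepoints)
    cols = [
        np.cos(np.pi * k * (2 * n + 1) / (2 * n_timepoints)) for k in range(1, k_max + 1)
    ]
    if not cols:
        return np.empty((n_timepoints, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


def build_lsa_design(
    run_design: list[TrialEvent],
    n_timepoints: int,
    tr: float,
    hrf_params: _hrf.HRFParams = _hrf.HRFParams(),
    drift: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
    oversampling: int = 20,
) -> DesignMatrix:
    """One HRF-convolved boxcar column per trial + drift + nuisance + intercept."""
    span = n_timepoints * tr
    if any(not 0 <= t.onset < span for t in run_design):
        raise ValueError("trial onset outside run span")
    cols = [
        _hrf.event_regressor(
            np.array([t.onset]), t.duration, n_timepoints, tr, hrf_params, oversampling
        )
        for t in run_design
    ]
    roles = [f"trial_{i}" for i in range(len(run_design))]
    if drift is not None and drift.size:
        cols.extend(drift.T)
        roles.extend(f"dct_{k}" for k in range(drift.shape[1]))
    if nuisance is not None and nuisance.size:
        cols.extend(np.atleast_2d(nuisance.T))
        roles.extend(f"nuisance_{j}" for j in range(np.atleast_2d(nuisance.T).shape[0]))
    cols.append(np.ones(n_timepoints))
    roles.append("intercept")
    X = np.column_stack(cols)
    _check_rank(X, roles)
    return DesignMatrix(matrix=X, column_roles=roles, tr=tr)


def _check_rank(X: np.ndarray, roles: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = sorted(roles[p] for p in piv[rank:])
        raise RankDeficiencyError(
            f"design rank {rank} < {X.shape[1]} columns; offending columns: {bad}"
        )


def spike_regressors(spike_volumes: list[int], n_timepoints: int) -> np.ndarray:
    """One indicator column per flagged (high framewise-displacement) volume."""
    cols = np.zeros((n_timepoints, len(spike_volumes)))
    for j, v in enumerate(spike_volumes):
        cols[v, j] = 1.0
    return cols


def fit_lsa(
    data: np.ndarray, design: DesignMatrix, run_design: list[TrialEvent] | None = None
) -> tuple[TrialBetaSet, ResidualSet]:
    """OLS per voxel; trial betas extracted in trial order, residuals retained.

    ``data`` is (n_timepoints, n_voxels).  When ``run_design`` is given, trial
    labels are attached to the beta set; otherwise placeholder labels are used.
    """
    X = design.matrix
    if data.shape[0] != X.shape[0]:
        raise ValueError(f"data has {data.shape[0]} timepoints, design {X.shape[0]}")
    if not np.isfinite(data).all():
        raise ValueError("non-finite data")
    _check_rank(X, design.column_roles)
    coef, _, _, _ = np.linalg.lstsq(X, data, rcond=None)
    residuals = data - X @ coef
    tcols = design.trial_columns
    betas = coef[tcols]
    n_trials = len(tcols)
    if run_design is not None:
        if len(run_design) != n_trials:
            raise ValueError("run_design length does not match trial columns")
        goal = np.array([t.action_goal for t in run_design])
        valence = np.array([t.valence for t in run_design])
        run_idx = np.array([t.run_index for t in run_design])
        correct = np.array(
            [True if t.correct is None else bool(t.correct) for t in run_design]
        )
    else:
        goal = np.array(["?"] * n_trials)
        valence = np.array(["?"] * n_trials)
        run_idx = np.zeros(n_trials, dtype=int)
        correct = np.ones(n_trials, dtype=bool)
    return (
        TrialBetaSet(betas=betas, action_goal=goal, valence=valence, run_index=run_idx, correct=correct),
        ResidualSet(residuals=residuals, run_index=int(run_idx[0]) if n_trials else 0),
    )


def fit_run(
    run: BOLDRun,
    k_drop: int = 4,
    cutoff: float = DCT_CUTOFF,
    hrf_params: _hrf.HRFParams = _hrf.HRFParams(),
) -> tuple[TrialBetaSet, ResidualSet]:
    """Convenience pipeline: drop volumes, build the LS-A design, fit OLS."""
    run = drop_initial_volumes(run, k_drop)
    n = run.n_timepoints
    drift = build_dct_highpass(n, run.tr, cutoff)
    nuis = spike_regressors(run.spike_volumes, n) if run.spike_volumes else None
    design = build_lsa_design(run.design, n, run.tr, hrf_params, drift=drift, nuisance=nuis)
    return fit_lsa(run.data.T, design, run.design)


def concat_betasets(sets: list[TrialBetaSet]) -> TrialBetaSet:
    if not sets:
        raise ValueError("no beta sets to concatenate")
    if len({s.whitened for s in sets}) != 1:
        raise ValueError("cannot mix whitened and unwhitened beta sets")
    return TrialBetaSet(
        betas=np.vstack([s.betas for s in sets]),
        action_goal=np.concatenate([s.action_goal for s in sets]),
        valence=np.concatenate([s.valence for s in sets]),
        run_index=np.concatenate([s.run_index for s in sets]),
        correct=np.concatenate([s.correct for s in sets]),
        whitened=sets[0].whitened,
    )
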