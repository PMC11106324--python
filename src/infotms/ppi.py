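"""Psychophysiological interaction (PPI) modeling of seed-remote coupling.

Per run, the demeaned seed-region time series, HRF-convolved regressors for
negative and positive emotional cues, and the products of the seed with the
*mean-centered* psychological regressors form the PPI design.  The negative
minus positive interaction beta is the run-wise coupling contrast; run betas
beyond +/-4 SD of the across-subject mean are excluded before the mixed model
linking coupling to run-wise decoding performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hrf as _hrf
from .bold import BOLDRun
from .design import NEGATIVE, POSITIVE, TrialEvent
from .glm import RankDeficiencyError, _check_rank
from .group_stats import FixedEffectEstimate, _fit_mixed, _term_estimate

__all__ = [
    "PPIDesign",
    "PPIBetas",
    "extract_seed_timecourse",
    "build_ppi_design",
    "fit_ppi",
    "exclude_outliers",
    "coupling_decoding_model",
]


@dataclass
class PPIDesign:
    matrix: np.ndarray  # (n_timepoints, n_columns)
    column_roles: list[str]
    tr: float


@dataclass
class PPIBetas:
    beta_ppi_negative: float
    beta_ppi_positive: float
    contrast: float  # negative - positive
    excluded: bool = False


def extract_seed_timecourse(run: "BOLDRun | np.ndarray", roi_mask=None) -> np.ndarray:
    """Spatial mean over ROI voxels per timepoint, temporally demeaned.

    Accepts a BOLDRun plus a boolean ROI volume (or a region role name), or a
    raw (n_voxels, n_timepoints) array whose rows are the ROI voxels.
    """
    if isinstance(run, BOLDRun):
        if isinstance(roi_mask, str):
            series = run.region_data(roi_mask)
        else:
            mask = np.asarray(roi_mask, dtype=bool)
            if mask.sum() == 0:
                raise ValueError("empty ROI")
            series = run.volume4d()[mask]
    else:
        series = np.atleast_2d(np.asarray(run, dtype=float))
        if series.shape[0] == 0:
            raise ValueError("empty ROI")
    ts = series.mean(axis=0)
    return ts - ts.mean()


def build_ppi_design(
    seed_ts: np.ndarray,
    run_design: list[TrialEvent],
    hrf_params: _hrf.HRFParams = _hrf.HRFParams(),
    drift: np.ndarray | None = None,
    tr: float = 2.0,
    oversampling: int = 20,
) -> PPIDesign:
    """Valence regressors, demeaned seed, and seed x centered-psych interactions."""
    seed_ts = np.asarray(seed_ts, dtype=float)
    n = seed_ts.size
    seed_ts = seed_ts - seed_ts.mean()
    cols, roles = [], []
    psych = {}
    for role, valence in (("negative", NEGATIVE), ("positive", POSITIVE)):
        onsets = np.array([t.onset for t in run_design if t.valence == valence])
        if onsets.size == 0:
            raise ValueError(f"run has no {valence} trials")
        duration = run_design[0].duration
        psych[role] = _hrf.event_regressor(onsets, duration, n, tr, hrf_params, oversampling)
    cols += [psych["negative"], psych["positive"], seed_ts]
    roles += ["psych_negative", "psych_positive", "seed_timecourse"]
    for role in ("negative", "positive"):
        centered = psych[role] - psych[role].mean()
        cols.append(seed_ts * centered)
        roles.append(f"ppi_{role}")
    if drift is not None and drift.size:
        cols.extend(drift.T)
        roles.extend(f"drift_{k}" for k in range(drift.shape[1]))
    cols.append(np.ones(n))
    roles.append("intercept")
    return PPIDesign(matrix=np.column_stack(cols), column_roles=roles, tr=tr)


def fit_ppi(remote_ts: np.ndarray, design: PPIDesign) -> PPIBetas:
    """OLS fit of the remote time series; negative-minus-positive PPI contrast."""
    y = np.asarray(remote_ts, dtype=float)
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError("remote series length does not match design")
    _check_rank(X, design.column_roles)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    i_neg = design.column_roles.index("ppi_negative")
    i_pos = design.column_roles.index("ppi_positive")
    return PPIBetas(
        beta_ppi_negative=float(beta[i_neg]),
        beta_ppi_positive=float(beta[i_pos]),
        contrast=float(beta[i_neg] - beta[i_pos]),
    )


def exclude_outliers(run_betas: np.ndarray, threshold_sd: float = 4.0) -> np.ndarray:
    """Flag run-wise values beyond mean +/- threshold_sd * SD (across all values)."""
    x = np.asarray(run_betas, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - x.mean()) > threshold_sd * sd


def coupling_decoding_model(records: pd.DataFrame) -> FixedEffectEstimate:
    """Mixed model: run-wise decoding AUC ~ PPI coupling contrast.

    ``records`` holds matched (subject, run) rows with columns ``contrast`` and
    ``auc``; subject and run enter as random factors.  Returns the fixed slope.
    """
    df = records.copy()
    if df["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    if np.isclose(df["contrast"].std(ddof=0), 0.0):
        raise ValueError("coupling contrast has no variance; slope undefined")
    fit = _fit_mixed("auc ~ contrast", df)
    return _term_estimate(fit, "contrast", label="coupling_decoding_slope")
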