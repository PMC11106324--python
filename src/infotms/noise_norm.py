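"""Multivariate noise normalization of trial patterns.

The noise covariance across voxels is estimated from GLM residuals, shrunk
toward its diagonal with the analytically optimal (Schaefer-Strimmer)
shrinkage intensity, and its inverse (or inverse square root, the default)
is applied to every trial's beta vector.  Whitening removes nuisance
correlations between voxels induced by physiological and instrument noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import eigh

from .glm import ResidualSet, TrialBetaSet

__all__ = [
    "NoiseCovariance",
    "estimate_residual_cov",
    "whiten_patterns",
    "matrix_power_spd",
]

EIG_FLOOR = 1e-10


@dataclass
class NoiseCovariance:
    sigma: np.ndarray  # (n_voxels, n_voxels), symmetric positive definite
    shrinkage_lambda: float
    source_runs: list[int] = field(default_factory=list)


def estimate_residual_cov(
    residual_sets: "list[ResidualSet] | list[np.ndarray] | np.ndarray",
) -> NoiseCovariance:
    """Diagonal-target shrinkage covariance of pooled, per-run-demeaned residuals.

    The shrinkage intensity is the closed-form optimum
    ``lambda* = sum_{i!=j} Var(s_ij) / sum_{i!=j} s_ij^2`` clipped to [0, 1];
    the result is ``(1 - lambda) S + lambda diag(S)`` with an eigenvalue floor
    guaranteeing positive definiteness.
    """
    if isinstance(residual_sets, np.ndarray):
        residual_sets = [residual_sets]
    arrays, runs = [], []
    for rs in residual_sets:
        if isinstance(rs, ResidualSet):
            arrays.append(np.asarray(rs.residuals, dtype=float))
            runs.append(rs.run_index)
        else:
            arrays.append(np.asarray(rs, dtype=float))
    centered = [a - a.mean(axis=0, keepdims=True) for a in arrays]
    X = np.vstack(centered)
    t, v = X.shape
    if t < 2:
        raise ValueError("need at least 2 timepoints to estimate a covariance")
    if not np.isfinite(X).all():
        raise ValueError("non-finite residuals")
    S = (X.T @ X) / (t - 1)
    # Var(s_ij) without materializing the t x v x v outer-product array:
    # sum_t w_tij^2 = ((X*X)^T (X*X))_ij and mean_t w_tij = s_ij (t-1)/t.
    X2 = X**2
    sum_w2 = X2.T @ X2
    wbar = S * (t - 1) / t
    var_s = t / (t - 1) ** 3 * (sum_w2 - t * wbar**2)
    off = ~np.eye(v, dtype=bool)
    denom = float((S[off] ** 2).sum())
    lam = 1.0 if denom == 0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))
    sigma = (1.0 - lam) * S + lam * np.diag(np.diag(S))
    # floor eigenvalues to guarantee SPD
    w, q = eigh(sigma)
    if w.min() < EIG_FLOOR:
        sigma = (q * np.maximum(w, EIG_FLOOR)) @ q.T
        sigma = 0.5 * (sigma + sigma.T)
    return NoiseCovariance(sigma=sigma, shrinkage_lambda=lam, source_runs=runs)


def matrix_power_spd(sigma: np.ndarray, power: float) -> np.ndarray:
    """Symmetric matrix power via eigendecomposition with an eigenvalue floor."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("sigma must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise ValueError("sigma must be symmetric")
    w, q = eigh(sigma)
    if w.min() <= 0:
        raise ValueError("sigma is not positive definite")
    return (q * np.maximum(w, EIG_FLOOR) ** power) @ q.T


def whiten_patterns(
    betas: "TrialBetaSet | np.ndarray",
    cov: "NoiseCovariance | np.ndarray",
    mode: str = "inv_sqrt",
) -> "TrialBetaSet | np.ndarray":
    """Multiply each trial vector by sigma^(-1/2) (default) or sigma^(-1).

    Labels are unchanged; the returned beta set is flagged ``whitened``.
    """
    if mode not in ("inv_sqrt", "inv"):
        raise ValueError(f"unknown whitening mode {mode!r}")
    sigma = cov.sigma if isinstance(cov, NoiseCovariance) else np.asarray(cov)
    mat = np.asarray(betas.betas if isinstance(betas, TrialBetaSet) else betas, dtype=float)
    if mat.shape[1] != sigma.shape[0]:
        raise ValueError(
            f"pattern has {mat.shape[1]} voxels but covariance is {sigma.shape[0]}-dim"
        )
    W = matrix_power_spd(sigma, -0.5 if mode == "inv_sqrt" else -1.0)
    out = mat @ W
    if isinstance(betas, TrialBetaSet):
        return replace(betas, betas=out, whitened=True)
    return out
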