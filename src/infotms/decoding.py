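"""Leave-one-run-out cross-validated linear decoding with AUC scoring.

The classifier is an l2-penalized logistic regression (C = 1) with balanced
class weights.  Features are z-scored per voxel using training-fold statistics
only.  Performance is the area under the ROC curve of the decision values on
the held-out run (0.5 = chance); significance comes from an empirical null
built by shuffling labels within run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .glm import TrialBetaSet

__all__ = [
    "ClassifierSpec",
    "DecodingResult",
    "PermutationNull",
    "auc_score",
    "crossval_auc",
    "permutation_null",
    "decode_betaset",
    "binary_labels",
]


@dataclass(frozen=True)
class ClassifierSpec:
    penalty: str = "l2"
    C: float = 1.0
    class_weight: str | None = "balanced"
    z_score: bool = True
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")

    def make(self) -> LogisticRegression:
        kwargs = dict(
            C=self.C,
            class_weight=self.class_weight,
            tol=self.tol,
            max_iter=self.max_iter,
            solver="lbfgs",
        )
        if self.penalty != "l2":  # l2 is sklearn's default; passing it is deprecated
            kwargs["penalty"] = self.penalty
        return LogisticRegression(**kwargs)


@dataclass
class DecodingResult:
    run_auc: dict
    mean_auc: float
    fold_assignments: np.ndarray
    spec: ClassifierSpec


@dataclass
class PermutationNull:
    null_aucs: np.ndarray
    observed: float
    p_value: float
    rng_seed: int | None = None


def auc_score(decision_scores: np.ndarray, binary_labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties count 1/2)."""
    y = np.asarray(binary_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(decision_scores, dtype=float)))


def _zscore_train_test(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def crossval_auc(
    X: np.ndarray,
    y: np.ndarray,
    runs: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
) -> DecodingResult:
    """Leave-one-run-out CV: z-score on training runs, fit, AUC on held-out run."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    runs = np.asarray(runs)
    unique_runs = np.unique(runs)
    if unique_runs.size < 2:
        raise ValueError("leave-one-run-out CV needs at least 2 runs")
    run_auc: dict = {}
    for r in unique_runs:
        test = runs == r
        train = ~test
        y_tr, y_te = y[train], y[test]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"training fold for run {r} lacks a class")
        if len(np.unique(y_te)) < 2:
            raise ValueError(f"held-out run {r} lacks a class")
        X_tr, X_te = X[train], X[test]
        if spec.z_score:
            X_tr, X_te = _zscore_train_test(X_tr, X_te)
        clf = spec.make()
        clf.fit(X_tr, y_tr)
        run_auc[r.item() if hasattr(r, "item") else r] = auc_score(
            clf.decision_function(X_te), y_te
        )
    return DecodingResult(
        run_auc=run_auc,
        mean_auc=float(np.mean(list(run_auc.values()))),
        fold_assignments=runs.copy(),
        spec=spec,
    )


def permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    runs: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    n_permutations: int = 500,
    rng: np.random.Generator | None = None,
    observed: float | None = None,
) -> PermutationNull:
    """Empirical null by shuffling labels *within run* (run class counts kept).

    ``p = (1 + #{null >= observed}) / (1 + n_permutations)``.  Pass a
    precomputed ``observed`` mean AUC to skip refitting the true labels.
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(y).astype(int)
    runs = np.asarray(runs)
    if observed is None:
        observed = crossval_auc(X, y, runs, spec).mean_auc
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = y.copy()
        for r in np.unique(runs):
            sel = np.flatnonzero(runs == r)
            y_perm[sel] = y[sel][rng.permutation(sel.size)]
        null[i] = crossval_auc(X, y_perm, runs, spec).mean_auc
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_permutations)
    return PermutationNull(null_aucs=null, observed=float(observed), p_value=p)


def binary_labels(betaset: TrialBetaSet, labels: str = "goal") -> tuple[np.ndarray, np.ndarray]:
    """Map a beta set to (keep mask, 0/1 labels).

    ``goal``: Go = 1 vs No-Go = 0 (all trials kept);
    ``valence``: Negative = 1 vs Positive = 0 (neutral trials dropped).
    """
    if labels == "goal":
        keep = np.ones(len(betaset.action_goal), dtype=bool)
        y = (betaset.action_goal == "Go").astype(int)
    elif labels == "valence":
        keep = np.isin(betaset.valence, ("Negative", "Positive"))
        y = (betaset.valence == "Negative").astype(int)
    else:
        raise ValueError(f"unknown label scheme {labels!r}")
    return keep, y


def decode_betaset(
    betaset: TrialBetaSet,
    labels: str = "goal",
    spec: ClassifierSpec = ClassifierSpec(),
) -> DecodingResult:
    """Leave-one-run-out decoding of a labeled trial beta set."""
    keep, y = binary_labels(betaset, labels)
    return crossval_auc(betaset.betas[keep], y[keep], betaset.run_index[keep], spec)
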