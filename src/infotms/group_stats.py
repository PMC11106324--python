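"""Run-level mixed-effects inference for decoding and behavior.

Run-wise statistics (classifier AUC, PPI coupling betas, behavioral cell
accuracies) are aggregated across subjects with linear mixed-effects models:
subject is the grouping factor and run a variance component, mirroring the
"subject and run as random factors" convention of repeated-measures fMRI
analyses.  Wald p-values use the normal approximation (``df_method =
"normal"``).  Boundary fits (a variance component estimated at zero) can leave
the Hessian-based covariance undefined; in that case the model is refit with
the offending component dropped, and as a last resort ordinary least squares
is used with the fallback recorded on the returned estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "FixedEffectEstimate",
    "EffectSize",
    "SessionEffectResult",
    "BehaviorModelResult",
    "cohens_d",
    "auc_vs_chance",
    "session_effect_on_auc",
    "behavior_model",
]

SESSIONS = ("baseline", "control_tms", "target_tms")


@dataclass
class FixedEffectEstimate:
    term: str
    B: float
    SE: float
    t: float
    p: float
    df_method: str = "normal"
    converged: bool = True
    random_structure: str = "subject + run"

    def __post_init__(self) -> None:
        if self.SE < 0:
            raise ValueError("SE must be non-negative")


@dataclass
class EffectSize:
    cohens_d: float


def cohens_d(x, y, paired: bool = False) -> EffectSize:
    """Standardized mean difference: pooled-SD (unpaired) or SD-of-differences (paired)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if d.size < 2:
            raise ValueError("need n >= 2")
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero SD of differences")
        return EffectSize(float(d.mean() / sd))
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    n1, n2 = x.size, y.size
    pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD")
    return EffectSize(float((x.mean() - y.mean()) / pooled))


def _normal_p(t: float) -> float:
    return float(2.0 * sps.norm.sf(abs(t)))


@dataclass
class _FitInfo:
    """Fixed-effects view of a (possibly refit) mixed model."""

    names: list
    fe: np.ndarray
    cov: np.ndarray
    converged: bool
    random_structure: str
    design_info: object = None


def _fit_mixed(
    formula: str,
    data: pd.DataFrame,
    re_formulas: tuple = (None,),
) -> _FitInfo:
    """Fit with a fallback ladder over random structures.

    Random-slope structures (``re_formulas``) are tried in the given order with
    subject as the grouping factor; the intercept-only structure uses crossed
    subject and run variance components (single-group formulation).  A fit is
    accepted only if it converged with a finite fixed-effects covariance;
    the terminal fallback is OLS, flagged ``converged = False``.
    """
    data = data.copy()
    has_run = "run" in data.columns

    def _candidates():
        for re_formula in re_formulas:
            if re_formula is not None:
                yield (
                    dict(groups=data["subject"], re_formula=re_formula),
                    f"subject slopes({re_formula})",
                )
            else:
                if has_run:
                    data["_one"] = 1
                    yield (
                        dict(
                            groups=data["_one"],
                            vc_formula={"subject": "0 + C(subject)", "run": "0 + C(run)"},
                        ),
                        "crossed(subject, run)",
                    )
                yield (dict(groups=data["subject"]), "subject")

    for kwargs, structure in _candidates():
        try:
            model = smf.mixedlm(formula, data, **kwargs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(reml=True, maxiter=200)
        except Exception:
            continue
        k = result.k_fe
        cov = np.asarray(result.cov_params())[:k, :k]
        if result.converged and np.isfinite(cov).all() and (np.diag(cov) >= 0).all():
            return _FitInfo(
                names=list(result.model.exog_names),
                fe=np.asarray(result.fe_params, dtype=float),
                cov=cov,
                converged=True,
                random_structure=structure,
                design_info=result.model.data.design_info,
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols = smf.ols(formula, data).fit()
    return _FitInfo(
        names=list(ols.model.exog_names),
        fe=np.asarray(ols.params, dtype=float),
        cov=np.asarray(ols.cov_params()),
        converged=False,
        random_structure="ols-fallback",
        design_info=ols.model.data.design_info,
    )


def _estimate(fit: _FitInfo, L: np.ndarray, label: str) -> FixedEffectEstimate:
    B = float(L @ fit.fe)
    var = float(L @ fit.cov @ L)
    SE = float(np.sqrt(max(var, 0.0)))
    if SE > 0:
        t = B / SE
        p = _normal_p(t)
    else:  # degenerate (zero-variance) data
        t = 0.0 if B == 0 else float(np.sign(B) * np.inf)
        p = 1.0 if B == 0 else 0.0
    return FixedEffectEstimate(
        term=label,
        B=B,
        SE=SE,
        t=t,
        p=p,
        converged=fit.converged,
        random_structure=fit.random_structure,
    )


def _term_estimate(fit: _FitInfo, term: str, label: str | None = None) -> FixedEffectEstimate:
    L = np.zeros(len(fit.names))
    L[fit.names.index(term)] = 1.0
    return _estimate(fit, L, label or term)


def auc_vs_chance(records: pd.DataFrame, session: str | None = None) -> FixedEffectEstimate:
    """Mixed-model intercept on (AUC - 0.5): is decoding above chance?

    ``records`` needs columns subject, run, auc (and session if filtering).
    """
    df = records.copy()
    if session is not None:
        df = df[df["session"] == session]
    if df["subject"].nunique() < 2 or df["run"].nunique() < 2:
        raise ValueError("need >= 2 subjects and >= 2 runs")
    df["auc_c"] = df["auc"] - 0.5
    fit = _fit_mixed("auc_c ~ 1", df)
    return _term_estimate(fit, "Intercept", label="auc_minus_chance")


@dataclass
class SessionEffectResult:
    contrasts: dict[str, FixedEffectEstimate]
    effect_sizes: dict[str, float]
    session_means: dict[str, float]


def session_effect_on_auc(records: pd.DataFrame) -> SessionEffectResult:
    """TMS condition as a fixed factor on run-wise AUC; all pairwise contrasts.

    Paired Cohen's d is computed on subject-level session means.
    """
    missing = set(SESSIONS) - set(records["session"].unique())
    if missing:
        raise ValueError(f"missing sessions: {sorted(missing)}")
    df = records.copy()
    fit = _fit_mixed("auc ~ C(session, Treatment('baseline'))", df)

    def unit(fragment: str) -> np.ndarray:
        v = np.zeros(len(fit.names))
        v[[i for i, n in enumerate(fit.names) if fragment in n][0]] = 1.0
        return v

    l_ctrl, l_tgt = unit("control_tms"), unit("target_tms")
    contrasts = {
        "control_vs_baseline": _estimate(fit, l_ctrl, "control_vs_baseline"),
        "target_vs_baseline": _estimate(fit, l_tgt, "target_vs_baseline"),
        "target_vs_control": _estimate(fit, l_tgt - l_ctrl, "target_vs_control"),
    }
    subj_means = df.groupby(["subject", "session"])["auc"].mean().unstack()

    def _d(a: str, b: str) -> float:
        diff = subj_means[a] - subj_means[b]
        sd = diff.std(ddof=1)
        return float(diff.mean() / sd) if sd > 0 else 0.0

    effect_sizes = {
        "control_vs_baseline": _d("control_tms", "baseline"),
        "target_vs_baseline": _d("target_tms", "baseline"),
        "target_vs_control": _d("target_tms", "control_tms"),
    }
    session_means = df.groupby("session")["auc"].mean().to_dict()
    return SessionEffectResult(contrasts, effect_sizes, session_means)


@dataclass
class BehaviorModelResult:
    nogo_negative_vs_positive: dict[str, FixedEffectEstimate]
    boost_reduction: dict[str, FixedEffectEstimate]
    interaction_stat: float
    interaction_p: float
    random_structure: str
    estimates: dict[str, FixedEffectEstimate] = field(default_factory=dict)


# random-slope ladder: slopes dropped in the order session (TMS site),
# valence, action goal, then intercept-only
_RE_LADDER = (
    "~C(session) + C(valence) + C(action_goal)",
    "~C(valence) + C(action_goal)",
    "~C(action_goal)",
    None,
)


def behavior_model(cell_records: pd.DataFrame) -> BehaviorModelResult:
    """Accuracy (%) over action goal x valence x session with subject random effects.

    ``cell_records`` holds one row per subject x session x run x cell with an
    ``accuracy`` column in percent.  Neutral-valence cells are excluded: the
    task has no Go-Neutral cell, so the full factorial exists only for the
    Negative/Positive pair.  Reports the No-Go Negative-vs-Positive marginal
    contrast per session and the goal x valence x session interaction test
    (Wald chi-square on the three-way terms, reported as stat/df).
    """
    required = {"subject", "session", "run", "action_goal", "valence", "accuracy"}
    if not required <= set(cell_records.columns):
        raise ValueError(f"missing columns: {sorted(required - set(cell_records.columns))}")
    df = cell_records[cell_records["valence"].isin(["Negative", "Positive"])].copy()
    counts = df.groupby(["action_goal", "valence", "session"]).size()
    if len(counts) < 4 or counts.min() == 0:
        raise ValueError("empty design cell")
    formula = "accuracy ~ C(action_goal) * C(valence) * C(session, Treatment('baseline'))"
    fit = _fit_mixed(formula, df, re_formulas=_RE_LADDER)

    from patsy import build_design_matrices

    def row(goal: str, valence: str, session: str) -> np.ndarray:
        frame = pd.DataFrame(
            {"action_goal": [goal], "valence": [valence], "session": [session]}
        )
        return np.asarray(build_design_matrices([fit.design_info], frame)[0])[0]

    sessions = sorted(df["session"].unique())

    def boost_row(session: str) -> np.ndarray:
        return row("No-Go", "Negative", session) - row("No-Go", "Positive", session)

    contrasts = {
        session: _estimate(fit, boost_row(session), f"nogo_neg_vs_pos[{session}]")
        for session in sessions
    }
    # focused 1-df three-way interaction contrasts: how much of the baseline
    # negative-cue boost is lost in each TMS session
    boost_reduction = {
        session: _estimate(
            fit, boost_row("baseline") - boost_row(session), f"boost_reduction[{session}]"
        )
        for session in sessions
        if session != "baseline" and "baseline" in sessions
    }

    three_way = [
        i
        for i, n in enumerate(fit.names)
        if "C(action_goal)" in n and "C(valence)" in n and "C(session" in n
    ]
    R = np.zeros((len(three_way), len(fit.names)))
    for j, i in enumerate(three_way):
        R[j, i] = 1.0
    b = R @ fit.fe
    rvr = R @ fit.cov @ R.T
    q = len(three_way)
    try:
        chi2 = float(b @ np.linalg.solve(rvr, b))
        p = float(sps.chi2.sf(chi2, q))
    except np.linalg.LinAlgError:
        chi2, p = float("nan"), float("nan")
    estimates = {n: _term_estimate(fit, n) for n in fit.names}
    return BehaviorModelResult(
        nogo_negative_vs_positive=contrasts,
        boost_reduction=boost_reduction,
        interaction_stat=chi2 / q if q else float("nan"),
        interaction_p=p,
        random_structure=fit.random_structure,
        estimates=estimates,
    )
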