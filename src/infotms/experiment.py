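"""End-to-end in-silico replication of the information-based TMS experiment.

Per subject: a baseline session is simulated and analyzed (single-trial GLM,
searchlight within the anatomical mask, peak-target selection); control-TMS
(attenuation alpha = 0) and target-TMS (alpha = 1) sessions follow.  The
selected target ROI is decoded in every session (with multivariate noise
normalization), PPI coupling is estimated per run, and group-level mixed
models test decoding vs chance, session effects, the behavioral valence x
goal x session structure, and the coupling-decoding association.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import BehaviorParams, simulate_behavior
from .bold import (
    BOLDRun,
    GroundTruthSpec,
    RegionLayout,
    default_layout,
    make_pattern_basis,
    synthesize_run,
)
from .decoding import ClassifierSpec, binary_labels, crossval_auc, permutation_null
from .design import generate_session_design
from .glm import concat_betasets, drop_initial_volumes, fit_run
from .group_stats import (
    SESSIONS,
    auc_vs_chance,
    behavior_model,
    session_effect_on_auc,
)
from .noise_norm import estimate_residual_cov, whiten_patterns
from .ppi import (
    build_ppi_design,
    coupling_decoding_model,
    exclude_outliers,
    extract_seed_timecourse,
    fit_ppi,
)
from .searchlight import SphereSpec, run_searchlight, select_target
from . import glm as _glm

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    n_subjects: int = 12
    layout: RegionLayout = field(default_factory=default_layout)
    truth: GroundTruthSpec = field(default_factory=GroundTruthSpec)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    session_attenuation: tuple[tuple[str, float], ...] = (
        ("baseline", 0.0),
        ("control_tms", 0.0),
        ("target_tms", 1.0),
    )
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    sphere: SphereSpec = field(default_factory=SphereSpec)
    roi_radius_mm: float = 5.0
    n_permutations: int = 100
    run_alpha_sd: float = 0.0
    master_seed: int = 0

    def alphas(self) -> dict[str, float]:
        d = dict(self.session_attenuation)
        missing = set(SESSIONS) - set(d)
        if missing:
            raise ValueError(f"session_attenuation missing {sorted(missing)}")
        return d


@dataclass
class ExperimentReport:
    config_echo: dict
    session_summary: dict
    auc_vs_chance: dict
    session_contrasts: dict
    behavior: dict
    coupling: dict
    target_recovery: dict
    subjects: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _estimate_dict(est) -> dict:
    return {
        "B": est.B,
        "SE": est.SE,
        "t": est.t,
        "p": est.p,
        "converged": est.converged,
        "random_structure": est.random_structure,
    }


def _accuracy_cells(trials, subject: int, session: str) -> pd.DataFrame:
    rows = []
    df = pd.DataFrame(
        {
            "run": [t.run_index for t in trials],
            "action_goal": [t.action_goal for t in trials],
            "valence": [t.valence for t in trials],
            "correct": [bool(t.correct) for t in trials],
        }
    )
    for (run, goal, valence), cell in df.groupby(["run", "action_goal", "valence"]):
        rows.append(
            {
                "subject": subject,
                "session": session,
                "run": run,
                "action_goal": goal,
                "valence": valence,
                "accuracy": 100.0 * cell["correct"].mean(),
            }
        )
    return pd.DataFrame(rows)


def _session_rois_decode(
    runsets: list[tuple],
    roi_flat: np.ndarray,
    classifier: ClassifierSpec,
    n_permutations: int,
    rng: np.random.Generator,
) -> dict:
    """Decode the target ROI (whitened) for one session's fitted runs."""
    betas = concat_betasets([b for b, _ in runsets]).filter_correct()
    roi_set = betas.select_voxels(roi_flat)
    cov = estimate_residual_cov([_sub_resid(r, roi_flat) for _, r in runsets])
    white = whiten_patterns(roi_set, cov)
    keep, y = binary_labels(white, "goal")
    res = crossval_auc(white.betas[keep], y[keep], white.run_index[keep], classifier)
    null = permutation_null(
        white.betas[keep],
        y[keep],
        white.run_index[keep],
        classifier,
        n_permutations=n_permutations,
        rng=rng,
        observed=res.mean_auc,
    )
    keep_v, y_v = binary_labels(white, "valence")
    res_val = crossval_auc(white.betas[keep_v], y_v[keep_v], white.run_index[keep_v], classifier)
    univariate = float(roi_set.betas.mean())
    return {
        "run_auc": res.run_auc,
        "mean_auc": res.mean_auc,
        "perm_p": null.p_value,
        "valence_auc": res_val.mean_auc,
        "univariate_mean": univariate,
        "shrinkage_lambda": cov.shrinkage_lambda,
    }


def _sub_resid(residset, roi_flat: np.ndarray):
    return residset.residuals[:, roi_flat]


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full three-session simulation and analysis; deterministic in
    ``(config, master_seed)``."""
    layout = config.layout
    alphas = config.alphas()
    ss = np.random.SeedSequence(config.master_seed)
    subj_seqs = ss.spawn(config.n_subjects)
    goal_centroid = layout.regions["goal_pattern"].mean(axis=0)
    brain_mask = layout.mask_volume("brain_mask")
    anat_mask = layout.mask_volume("anatomical_mask")
    anat_flat = layout.flat_indices("anatomical_mask")

    auc_rows, ppi_rows, behavior_frames, subject_records = [], [], [], []

    for s in range(config.n_subjects):
        streams = subj_seqs[s].spawn(2 + len(SESSIONS))
        basis = make_pattern_basis(layout, np.random.default_rng(streams[0]))
        perm_rng = np.random.default_rng(streams[1])
        run_order = 1 + s % 2
        session_fits: dict[str, list[tuple]] = {}
        session_raw: dict[str, list[BOLDRun]] = {}
        roi_flat: np.ndarray | None = None  # set after baseline target discovery

        def _simulate_session(session: str, stream) -> None:
            srng = np.random.default_rng(stream)
            stage = f"subject {s}, session {session}"
            try:
                design_seed = int(srng.integers(2**31))
                design = generate_session_design(run_order, design_seed)
                bparams = replace(config.behavior, tms_attenuation=alphas[session])
                design = simulate_behavior(design, bparams, srng)
                behavior_frames.append(_accuracy_cells(design.trials, s, session))
                fits, raws = [], []
                for r in range(1, design.n_runs + 1):
                    alpha_r = alphas[session]
                    if config.run_alpha_sd > 0:
                        alpha_r = float(
                            np.clip(alpha_r + config.run_alpha_sd * srng.standard_normal(), 0, 1)
                        )
                    truth_r = replace(config.truth, tms_attenuation=alpha_r)
                    bold = synthesize_run(
                        design.run_trials(r), layout, truth_r, rng=srng, basis=basis,
                        attenuation_mask=roi_flat,
                    )
                    raws.append(drop_initial_volumes(bold))
                    fits.append(fit_run(bold))
                session_fits[session] = fits
                session_raw[session] = raws
            except Exception as err:
                raise RuntimeError(f"stage failed: {stage}: {err}") from err

        # --- baseline session and target discovery -------------------------
        _simulate_session("baseline", streams[2])
        base_betas = concat_betasets([b for b, _ in session_fits["baseline"]]).filter_correct()
        keep, y = binary_labels(base_betas, "goal")
        vol = base_betas.betas[keep].reshape(-1, *layout.grid_shape)
        sl_map = run_searchlight(
            vol, y[keep], base_betas.run_index[keep], brain_mask, anat_mask,
            config.sphere, config.classifier,
        )
        target = select_target(
            sl_map, brain_mask, config.roi_radius_mm, layout.voxel_size
        )
        roi_flat = np.flatnonzero(target.roi_mask.ravel())
        dist_mm = float(
            np.linalg.norm((np.array(target.center) - goal_centroid) * layout.voxel_size)
        )

        # --- TMS sessions: attenuation acts only at the selected site ------
        for j, session in enumerate(SESSIONS[1:], start=1):
            _simulate_session(session, streams[2 + j])

        # --- per-session decoding, control analyses, PPI -------------------
        subject_sessions = {}
        for session in SESSIONS:
            dec = _session_rois_decode(
                session_fits[session], roi_flat, config.classifier,
                config.n_permutations, perm_rng,
            )
            # regional-specificity control: anatomical-mask ROI, unwhitened
            anat_betas = concat_betasets(
                [b for b, _ in session_fits[session]]
            ).filter_correct().select_voxels(anat_flat)
            keep_a, y_a = binary_labels(anat_betas, "goal")
            dec["anat_auc"] = crossval_auc(
                anat_betas.betas[keep_a], y_a[keep_a], anat_betas.run_index[keep_a],
                config.classifier,
            ).mean_auc
            for run, auc in dec["run_auc"].items():
                auc_rows.append({"subject": s, "session": session, "run": run, "auc": auc})
            for raw in session_raw[session]:
                seed_ts = extract_seed_timecourse(raw, "seed")
                remote_ts = extract_seed_timecourse(raw, "remote")
                drift = _glm.build_dct_highpass(raw.n_timepoints, raw.tr)
                pdesign = build_ppi_design(seed_ts, raw.design, drift=drift, tr=raw.tr)
                betas = fit_ppi(remote_ts, pdesign)
                ppi_rows.append(
                    {
                        "subject": s,
                        "session": session,
                        "run": raw.design[0].run_index,
                        "beta_neg": betas.beta_ppi_negative,
                        "beta_pos": betas.beta_ppi_positive,
                        "contrast": betas.contrast,
                    }
                )
            subject_sessions[session] = dec
        subject_records.append(
            {
                "subject": s,
                "target_center": list(target.center),
                "target_score": target.score,
                "target_distance_mm": dist_mm,
                "sessions": {
                    k: {kk: vv for kk, vv in v.items() if kk != "run_auc"}
                    for k, v in subject_sessions.items()
                },
            }
        )

    auc_df = pd.DataFrame(auc_rows)
    ppi_df = pd.DataFrame(ppi_rows)
    behavior_df = pd.concat(behavior_frames, ignore_index=True)

    # --- group statistics --------------------------------------------------
    chance = {
        session: _estimate_dict(auc_vs_chance(auc_df, session)) for session in SESSIONS
    }
    sess_eff = session_effect_on_auc(auc_df)
    behav = behavior_model(behavior_df)

    excluded = exclude_outliers(ppi_df["contrast"].to_numpy())
    ppi_df["excluded"] = excluded
    merged = ppi_df[~ppi_df["excluded"]].merge(
        auc_df, on=["subject", "session", "run"], how="inner"
    )
    coupling = _estimate_dict(coupling_decoding_model(merged))
    coupling["n_excluded"] = int(excluded.sum())
    coupling["pct_excluded"] = 100.0 * float(excluded.mean())
    coupling["mean_contrast_by_session"] = (
        ppi_df.groupby("session")["contrast"].mean().to_dict()
    )

    session_summary = {
        session: {
            "mean_auc": float(auc_df[auc_df.session == session]["auc"].mean()),
            "mean_perm_p": float(
                np.mean([r["sessions"][session]["perm_p"] for r in subject_records])
            ),
            "mean_valence_auc": float(
                np.mean([r["sessions"][session]["valence_auc"] for r in subject_records])
            ),
            "mean_anat_auc": float(
                np.mean([r["sessions"][session]["anat_auc"] for r in subject_records])
            ),
            "mean_univariate": float(
                np.mean([r["sessions"][session]["univariate_mean"] for r in subject_records])
            ),
        }
        for session in SESSIONS
    }

    distances = [r["target_distance_mm"] for r in subject_records]
    config_echo = {
        "n_subjects": config.n_subjects,
        "master_seed": config.master_seed,
        "grid_shape": list(layout.grid_shape),
        "truth": dataclasses.asdict(config.truth),
        "behavior": dataclasses.asdict(config.behavior),
        "session_attenuation": dict(config.session_attenuation),
        "n_permutations": config.n_permutations,
        "run_alpha_sd": config.run_alpha_sd,
        "sphere_radius_voxels": config.sphere.radius_voxels,
        "roi_radius_mm": config.roi_radius_mm,
    }
    return ExperimentReport(
        config_echo=config_echo,
        session_summary=session_summary,
        auc_vs_chance=chance,
        session_contrasts={
            name: _estimate_dict(est) for name, est in sess_eff.contrasts.items()
        }
        | {"effect_sizes_d": sess_eff.effect_sizes},
        behavior={
            "nogo_negative_vs_positive": {
                k: _estimate_dict(v) for k, v in behav.nogo_negative_vs_positive.items()
            },
            "boost_reduction": {
                k: _estimate_dict(v) for k, v in behav.boost_reduction.items()
            },
            "interaction_stat": behav.interaction_stat,
            "interaction_p": behav.interaction_p,
            "random_structure": behav.random_structure,
        },
        coupling=coupling,
        target_recovery={
            "distances_mm": distances,
            "median_mm": float(np.median(distances)),
            "mean_mm": float(np.mean(distances)),
        },
        subjects=subject_records,
    )
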