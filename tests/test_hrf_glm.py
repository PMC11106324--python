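"""HRF kernel and LS-A GLM: shape constants, design structure, OLS oracles."""

import numpy as np
import pytest

from infotms import (
    GroundTruthSpec,
    HRFParams,
    build_dct_highpass,
    build_lsa_design,
    drop_initial_volumes,
    fit_lsa,
    hrf_double_gamma,
    synthesize_run,
)
from infotms.design import TrialEvent, generate_session_design
from infotms.glm import RankDeficiencyError, fit_run, spike_regressors
def _trial(onset, run=1, goal="Go", valence="Positive"):
    return TrialEvent(
        run_index=run, miniblock_index=1, onset=onset, duration=0.5,
        action_goal=goal, valence=valence, is_target=goal == "Go",
    )


class TestHRF:
    def test_peak_at_six_seconds(self):
        # 0.01 s grid
        k = hrf_double_gamma(HRFParams(), tr=1.0, oversampling=100)
        t = np.arange(k.size) * 0.01
        assert t[np.argmax(k)] == pytest.approx(6.0, abs=0.02)
        assert k.max() == pytest.approx(1.0)

    def test_zero_at_origin_and_nonnegative_single_gamma(self):
        k = hrf_double_gamma(HRFParams(), tr=2.0, oversampling=20)
        assert k[0] == 0.0
        k0 = hrf_double_gamma(HRFParams(undershoot_ratio=0.0), tr=2.0, oversampling=20)
        assert (k0 >= 0).all()

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            HRFParams(peak_delay=-1)
        with pytest.raises(ValueError):
            HRFParams(undershoot_ratio=1.2)
        with pytest.raises(ValueError):
            hrf_double_gamma(tr=0)


class TestDropVolumes:
    def test_counts_and_onsets(self, layout):
        truth = GroundTruthSpec(noise_sd=0.5)
        design = generate_session_design(1, 0)
        run = synthesize_run(design.run_trials(1), layout, truth, rng=np.random.default_rng(0))
        assert run.n_timepoints == 222
        dropped = drop_initial_volumes(run, 4)
        assert dropped.n_timepoints == 218
        for before, after in zip(run.design, dropped.design):
            assert after.onset == pytest.approx(before.onset - 8.0)
        assert drop_initial_volumes(run, 0) is run

    def test_errors(self, layout):
        truth = GroundTruthSpec(noise_sd=0.0)
        run = synthesize_run([_trial(10.0)], layout, truth, n_timepoints=20)
        with pytest.raises(ValueError):
            drop_initial_volumes(run, 20)
        with pytest.raises(ValueError):
            drop_initial_volumes(run, 6)  # onset 10.0 < 12 s


class TestDCT:
    def test_column_count_formula(self):
        basis = build_dct_highpass(218, 2.0, cutoff=90.0)
        assert basis.shape == (218, int(np.floor(2 * 218 * 2.0 / 90.0)))

    def test_removes_linear_drift(self):
        n = 218
        basis = build_dct_highpass(n, 2.0, 90.0)
        drift = np.linspace(-1, 1, n)
        X = np.column_stack([basis, np.ones(n)])
        resid = drift - X @ np.linalg.lstsq(X, drift, rcond=None)[0]
        assert resid.var() < 0.01 * drift.var()

    def test_infinite_cutoff_gives_no_columns(self):
        assert build_dct_highpass(100, 2.0, cutoff=np.inf).shape == (100, 0)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            build_dct_highpass(1, 2.0)
        with pytest.raises(ValueError):
            build_dct_highpass(100, 2.0, cutoff=3.0)


class TestLSADesign:
    def test_structure(self):
        design80 = generate_session_design(1, 3).run_trials(1)
        shifted = [_trial(t.onset - 8.0, goal=t.action_goal, valence=t.valence) for t in design80]
        drift = build_dct_highpass(218, 2.0)
        dm = build_lsa_design(shifted, 218, 2.0, drift=drift)
        n_trial_cols = sum(r.startswith("trial_") for r in dm.column_roles)
        assert n_trial_cols == 80
        assert dm.column_roles[-1] == "intercept"
        assert dm.matrix.shape == (218, 80 + drift.shape[1] + 1)

    def test_causality(self):
        dm = build_lsa_design([_trial(30.0)], 50, 2.0)
        col = dm.matrix[:, 0]
        assert np.all(col[: int(30.0 / 2.0)] == 0)
        assert col.max() > 0

    def test_duplicate_onsets_rank_deficient(self):
        with pytest.raises(RankDeficiencyError) as err:
            build_lsa_design([_trial(10.0), _trial(10.0)], 50, 2.0)
        assert "trial_" in str(err.value)

    def test_onset_outside_span(self):
        with pytest.raises(ValueError):
            build_lsa_design([_trial(120.0)], 50, 2.0)


class TestFitLSA:
    def test_exact_recovery_vs_normal_equations(self):
        """Noiseless data from a known design: OLS must invert it exactly,
        matching the brute-force normal-equations oracle."""
        rng = np.random.default_rng(0)
        trials = [_trial(o) for o in (2.0, 9.0, 17.5, 26.0)]
        dm = build_lsa_design(trials, 30, 2.0, drift=build_dct_highpass(30, 2.0, 20.0))
        true = rng.standard_normal((dm.matrix.shape[1], 5))
        data = dm.matrix @ true
        betas, resid = fit_lsa(data, dm, trials)
        assert np.allclose(betas.betas, true[:4], atol=1e-8)
        X = dm.matrix
        oracle = np.linalg.solve(X.T @ X, X.T @ data)
        assert np.allclose(betas.betas, oracle[:4], atol=1e-8)
        assert np.abs(resid.residuals).max() < 1e-8

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        trials = [_trial(o) for o in (2.0, 10.0, 20.0)]
        dm = build_lsa_design(trials, 40, 2.0)
        data = rng.standard_normal((40, 6))
        _, resid = fit_lsa(data, dm, trials)
        assert np.abs(dm.matrix.T @ resid.residuals).max() < 1e-8

    def test_unbiased_under_white_noise(self):
        rng = np.random.default_rng(2)
        trials = [_trial(o) for o in (2.0, 10.0, 20.0, 30.0)]
        dm = build_lsa_design(trials, 40, 2.0)
        means = []
        for _ in range(300):
            data = rng.standard_normal((40, 2))
            betas, _ = fit_lsa(data, dm, trials)
            means.append(betas.betas.mean())
        assert abs(np.mean(means)) < 0.05

    def test_beta_error_decreases_with_noise(self, layout):
        design = generate_session_design(1, 4)
        errors = []
        basis_rng = np.random.default_rng(99)
        from infotms import make_pattern_basis
        basis = make_pattern_basis(layout, basis_rng)
        for sd in (2.0, 0.5, 0.0):
            truth = GroundTruthSpec(pattern_separation=1.0, noise_sd=sd, spatial_fwhm=0.0)
            run = synthesize_run(
                design.run_trials(1), layout, truth, rng=np.random.default_rng(5), basis=basis
            )
            noiseless = synthesize_run(
                design.run_trials(1),
                layout,
                GroundTruthSpec(pattern_separation=1.0, noise_sd=0.0),
                rng=np.random.default_rng(5),
                basis=basis,
            )
            b, _ = fit_run(run)
            b0, _ = fit_run(noiseless)
            errors.append(np.abs(b.betas - b0.betas).mean())
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-6

    def test_filter_correct_preserves_labels(self, layout):
        from infotms import BehaviorParams, simulate_behavior

        design = generate_session_design(1, 6)
        design = simulate_behavior(design, BehaviorParams(), np.random.default_rng(3))
        truth = GroundTruthSpec(noise_sd=0.3)
        run = synthesize_run(design.run_trials(1), layout, truth, rng=np.random.default_rng(1))
        betas, _ = fit_run(run)
        kept = betas.filter_correct()
        orig = {
            i: (g, v)
            for i, (g, v, c) in enumerate(zip(betas.action_goal, betas.valence, betas.correct))
            if c
        }
        assert list(zip(kept.action_goal, kept.valence)) == list(orig.values())

    def test_spike_regressors_absorb_spikes(self, layout):
        truth = GroundTruthSpec(noise_sd=0.5, spike_probability=0.03)
        design = generate_session_design(1, 8)
        run = synthesize_run(design.run_trials(1), layout, truth, rng=np.random.default_rng(4))
        assert run.spike_volumes
        cols = spike_regressors(run.spike_volumes, run.n_timepoints)
        assert cols.shape == (222, len(run.spike_volumes))
        assert (cols.sum(axis=0) == 1).all()
        betas, resid = fit_run(run)  # should succeed and stay finite
        assert np.isfinite(betas.betas).all()
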