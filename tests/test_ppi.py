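"""PPI design construction, coupling recovery, outlier screening, group link."""

import numpy as np
import pandas as pd
import pytest

from infotms import (
    build_ppi_design,
    coupling_decoding_model,
    exclude_outliers,
    extract_seed_timecourse,
    fit_ppi,
)
from infotms.design import TrialEvent
from infotms.hrf import event_regressor


def _trials(n_time, tr=2.0, spacing=8.0):
    """Alternating Negative/Positive events filling the run."""
    out, onset, i = [], 4.0, 0
    while onset < n_time * tr - 20:
        val = "Negative" if i % 2 == 0 else "Positive"
        goal = "Go" if i % 3 else "No-Go"
        out.append(
            TrialEvent(run_index=1, miniblock_index=1, onset=onset, duration=0.5,
                       action_goal=goal, valence=val, is_target=goal == "Go")
        )
        onset += spacing
        i += 1
    return out


class TestSeedExtraction:
    def test_constant_roi_is_zero(self):
        assert np.allclose(extract_seed_timecourse(np.full((4, 50), 3.7)), 0.0)

    def test_single_voxel(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(30)
        out = extract_seed_timecourse(v[None, :])
        assert np.allclose(out, v - v.mean())

    def test_two_voxel_mean(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        out = extract_seed_timecourse(np.vstack([a, b]))
        expected = (a + b) / 2
        assert np.allclose(out, expected - expected.mean())

    def test_empty_roi(self):
        with pytest.raises(ValueError):
            extract_seed_timecourse(np.empty((0, 10)))


class TestPPIDesign:
    def test_column_structure(self):
        rng = np.random.default_rng(2)
        seed = rng.standard_normal(120)
        drift = np.linspace(-1, 1, 120)[:, None]
        d = build_ppi_design(seed, _trials(120), drift=drift)
        assert d.column_roles == [
            "psych_negative", "psych_positive", "seed_timecourse",
            "ppi_negative", "ppi_positive", "drift_0", "intercept",
        ]
        i = d.column_roles.index("seed_timecourse")
        assert abs(d.matrix[:, i].mean()) < 1e-12

    def test_zero_seed_zeroes_interactions(self):
        d = build_ppi_design(np.zeros(100), _trials(100))
        for role in ("ppi_negative", "ppi_positive"):
            assert np.allclose(d.matrix[:, d.column_roles.index(role)], 0.0)

    def test_centered_psych_decorrelates_interaction_from_seed(self):
        rng = np.random.default_rng(3)
        seed = rng.standard_normal(200)
        d = build_ppi_design(seed, _trials(200, spacing=6.0))
        ppi = d.matrix[:, d.column_roles.index("ppi_negative")]
        r = np.corrcoef(seed, ppi)[0, 1]
        assert abs(r) < 0.2

    def test_missing_valence_errors(self):
        only_neg = [t for t in _trials(100) if t.valence == "Negative"]
        with pytest.raises(ValueError):
            build_ppi_design(np.zeros(100), only_neg)


class TestFitPPI:
    def _simulate_run(self, rng, gamma_neg=0.8, gamma_pos=0.0, beta_c=0.5, noise=0.5, n=200):
        trials = _trials(n, spacing=6.0)
        seed = rng.standard_normal(n)
        neg = event_regressor(
            np.array([t.onset for t in trials if t.valence == "Negative"]), 0.5, n, 2.0
        )
        pos = event_regressor(
            np.array([t.onset for t in trials if t.valence == "Positive"]), 0.5, n, 2.0
        )
        remote = beta_c * seed + gamma_neg * seed * neg + gamma_pos * seed * pos
        remote = remote + noise * rng.standard_normal(n)
        return trials, seed, remote

    def test_contrast_recovers_gamma(self):
        """Generating model: remote = b*seed + g*(seed x neg) + noise; the mean
        fitted contrast over 100 runs recovers g within 2 SE."""
        rng = np.random.default_rng(4)
        contrasts = []
        for _ in range(100):
            trials, seed, remote = self._simulate_run(rng)
            d = build_ppi_design(seed, trials)
            contrasts.append(fit_ppi(remote, d).contrast)
        se = np.std(contrasts, ddof=1) / 10.0
        assert abs(np.mean(contrasts) - 0.8) < 2 * se + 1e-9

    def test_symmetric_modulation_gives_zero_contrast(self):
        rng = np.random.default_rng(5)
        contrasts = []
        for _ in range(60):
            trials, seed, remote = self._simulate_run(rng, gamma_neg=0.6, gamma_pos=0.6)
            contrasts.append(fit_ppi(remote, build_ppi_design(seed, trials)).contrast)
        se = np.std(contrasts, ddof=1) / np.sqrt(60)
        assert abs(np.mean(contrasts)) < 3 * se + 0.02

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        trials, seed, remote = self._simulate_run(rng)
        d = build_ppi_design(seed, trials)
        X = d.matrix
        oracle = np.linalg.solve(X.T @ X, X.T @ remote)
        res = fit_ppi(remote, d)
        i_neg = d.column_roles.index("ppi_negative")
        i_pos = d.column_roles.index("ppi_positive")
        assert res.beta_ppi_negative == pytest.approx(oracle[i_neg], abs=1e-8)
        assert res.contrast == pytest.approx(oracle[i_neg] - oracle[i_pos], abs=1e-8)

    def test_attenuation_lowers_contrast(self):
        rng = np.random.default_rng(7)
        full, atten = [], []
        for _ in range(40):
            trials, seed, remote = self._simulate_run(rng, gamma_neg=0.8)
            full.append(fit_ppi(remote, build_ppi_design(seed, trials)).contrast)
            trials, seed, remote = self._simulate_run(rng, gamma_neg=0.0)
            atten.append(fit_ppi(remote, build_ppi_design(seed, trials)).contrast)
        assert np.mean(atten) < np.mean(full)


class TestOutlierExclusion:
    def test_single_extreme_value_flagged(self):
        rng = np.random.default_rng(8)
        values = np.append(rng.standard_normal(161), 50.0)
        flags = exclude_outliers(values)
        assert flags.sum() == 1 and flags[-1]
        # report format: count and percentage of total
        assert flags.sum() / flags.size == pytest.approx(1 / 162)

    def test_no_exclusion_within_band(self):
        rng = np.random.default_rng(9)
        assert exclude_outliers(np.clip(rng.standard_normal(100), -2, 2)).sum() == 0

    def test_all_equal_input(self):
        assert exclude_outliers(np.full(10, 1.3)).sum() == 0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            exclude_outliers([1.0, 2.0])


class TestCouplingDecodingModel:
    def _records(self, rng, coupled=True, n_subj=20):
        rows = []
        for s in range(n_subj):
            subj = 0.02 * rng.standard_normal()
            for r in range(1, 7):
                alpha = rng.uniform(0, 1)
                contrast = 0.8 * (1 - alpha) + 0.15 * rng.standard_normal()
                if coupled:
                    auc = 0.5 + 0.15 * (1 - alpha) + subj + 0.04 * rng.standard_normal()
                else:
                    auc = 0.55 + subj + 0.04 * rng.standard_normal()
                rows.append({"subject": s, "run": r, "contrast": contrast, "auc": auc})
        return pd.DataFrame(rows)

    def test_positive_slope_recovered(self):
        """Run-level attenuation jointly drives decoding and coupling: the
        mixed-model slope is positive and significant in most replicates."""
        rng = np.random.default_rng(10)
        wins = sum(
            (lambda est: est.B > 0 and est.t > 2)(coupling_decoding_model(self._records(rng)))
            for _ in range(25)
        )
        assert wins >= 20

    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(11)
        covered = 0
        n_sims = 50
        for _ in range(n_sims):
            est = coupling_decoding_model(self._records(rng, coupled=False))
            if abs(est.B) <= 1.96 * est.SE:
                covered += 1
        assert covered >= 0.85 * n_sims

    def test_constant_contrast_errors(self):
        df = pd.DataFrame(
            [{"subject": s, "run": r, "contrast": 1.0, "auc": 0.6}
             for s in range(3) for r in range(1, 4)]
        )
        with pytest.raises(ValueError):
            coupling_decoding_model(df)

    def test_needs_two_subjects(self):
        df = pd.DataFrame(
            [{"subject": 0, "run": r, "contrast": float(r), "auc": 0.6} for r in range(1, 7)]
        )
        with pytest.raises(ValueError):
            coupling_decoding_model(df)
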