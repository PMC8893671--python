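import numpy as np
import pandas as pd
import pytest

from affectloop.bias import (
    fit_mixed,
    induction_predictor_test,
    novel_stimulus_validation,
    physio_validation,
    primary_bias_test,
    regulation_test,
    simulate_bias_table,
    simulate_physio_table,
    simulate_predictor_table,
    simulate_regulation_table,
    trigger_validation,
)


class TestFitMixed:
    def _table(self, seed=0, beta=0.5, ranef_sd=0.2, n_subj=15, n_per=30):
        rng = np.random.default_rng(seed)
        rows = []
        for j in range(n_subj):
            u = rng.normal(0, ranef_sd)
            x = rng.normal(size=n_per)
            y = 1.0 + beta * x + u + rng.normal(0, 0.5, n_per)
            for xi, yi in zip(x, y):
                rows.append({"subject_id": f"s{j}", "x": xi, "y": yi})
        return pd.DataFrame(rows)

    def test_recovers_known_slope(self):
        hits = 0
        for seed in range(20):
            res = fit_mixed("y ~ x", self._table(seed=seed), "subject_id")
            lo, hi = res["x"].ci()
            hits += lo <= 0.5 <= hi
        assert hits >= 17  # ~95% nominal coverage

    def test_lrt_detects_random_intercept(self):
        res = fit_mixed("y ~ x", self._table(ranef_sd=0.8), "subject_id")
        assert res.lrt_p < 0.01
        assert res.random_effect_variances["Group"] > 0.2

    def test_orthogonal_covariate_leaves_estimates(self):
        table = self._table(seed=3)
        rng = np.random.default_rng(99)
        table["z"] = rng.normal(size=len(table))  # independent noise column
        r1 = fit_mixed("y ~ x", table, "subject_id")
        r2 = fit_mixed("y ~ x + z", table, "subject_id")
        assert r2["x"].estimate == pytest.approx(r1["x"].estimate, abs=0.02)

    def test_single_group_rejected(self):
        table = self._table().assign(subject_id="s0")
        with pytest.raises(ValueError):
            fit_mixed("y ~ x", table, "subject_id")

    def test_rank_deficiency_names_terms(self):
        table = self._table()
        table["x2"] = table["x"] * 2
        with pytest.raises(ValueError, match="rank deficient"):
            fit_mixed("y ~ x + x2", table, "subject_id")

    def test_deterministic_fits(self):
        table = self._table(seed=4)
        r1 = fit_mixed("y ~ x", table, "subject_id")
        r2 = fit_mixed("y ~ x", table, "subject_id")
        assert r1["x"].estimate == r2["x"].estimate
        assert r1.loglik == r2.loglik


class TestPhysioValidation:
    @pytest.fixture(scope="class")
    @staticmethod
    def fits():
        table = simulate_physio_table(n_subjects=30, n_trials=90, seed=5)
        return physio_validation(table)

    def test_planted_gains_recovered(self, fits):
        lo, hi = fits["valence_cemg"]["cemg_z"].ci()
        assert lo <= 0.11 <= hi
        lo, hi = fits["arousal_scr"]["scr_z"].ci()
        assert lo <= 0.07 <= hi

    def test_matched_models_significant(self, fits):
        assert fits["valence_cemg"]["cemg_z"].p < 0.05
        assert fits["arousal_scr"]["scr_z"].p < 0.05

    def test_crossed_models_selective(self, fits):
        # valence-only cEMG link should not explain arousal (and vice versa)
        assert abs(fits["arousal_cemg"]["cemg_z"].estimate) < 0.08
        assert abs(fits["valence_scr"]["scr_z"].estimate) < 0.08

    def test_zero_gain_null(self):
        table = simulate_physio_table(
            n_subjects=20, n_trials=60, beta_cemg=0.0, beta_scr=0.0, slope_sd=0.0, seed=6
        )
        fits = physio_validation(table)
        assert fits["valence_cemg"]["cemg_z"].p > 0.01

    def test_missing_rows_rejected(self):
        with pytest.raises(ValueError):
            physio_validation(pd.DataFrame({"trial_type": ["Mod-PS"]}))


class TestNovelStimulusValidation:
    def _table(self, link=0.6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for j in range(15):
            for kind, n in (("Id-CR", 30), ("Mod-PS", 40)):
                nv = rng.uniform(1, 9, n)
                na = np.clip(2.9 + 0.8 * np.abs(nv - 5) + rng.normal(0, 0.9, n), 1, 9)
                dv = 0.5 + link * 0.05 * (nv - 5) + rng.normal(0, 0.12, n)
                da = 0.5 + link * 0.05 * (na - 5) + rng.normal(0, 0.12, n)
                for i in range(n):
                    rows.append(
                        {
                            "subject_id": f"s{j}",
                            "trial_type": kind,
                            "norm_valence": nv[i],
                            "norm_arousal": na[i],
                            "decoded_valence": float(np.clip(dv[i], 0, 1)),
                            "decoded_arousal": float(np.clip(da[i], 0, 1)),
                            "age": 40.0 + j,
                            "sex": j % 2,
                        }
                    )
        return pd.DataFrame(rows)

    def test_planted_link_positive_significant(self):
        fits = novel_stimulus_validation(self._table())
        assert fits["idcr_valence"]["dv_z"].estimate > 0
        assert fits["idcr_valence"]["dv_z"].p < 0.001
        assert fits["modps_valence"]["dv_z"].p < 0.001

    def test_shuffled_decodings_null(self):
        table = self._table()
        rng = np.random.default_rng(1)
        table["decoded_valence"] = rng.permutation(table["decoded_valence"].to_numpy())
        fits = novel_stimulus_validation(table)
        assert fits["idcr_valence"]["dv_z"].p > 0.05

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            novel_stimulus_validation(self._table().iloc[0:0])


class TestTriggerValidation:
    def _table(self, elevated=True, seed=0, accuracy=0.8):
        rng = np.random.default_rng(seed)
        rows = []
        for j in range(12):
            for _ in range(20):
                prev = rng.normal(0.75 if elevated else 0.5, 0.1)
                rows.append(
                    {
                        "subject_id": f"s{j}",
                        "trial_type": "Mod-FS",
                        "prev_decoded_valence": float(np.clip(prev, 0, 1)),
                        "feedback_at_trigger": rng.normal(0.9 if elevated else 0.0, 0.3),
                        "decoder_accuracy": accuracy,
                    }
                )
        return pd.DataFrame(rows)

    def test_elevated_cohort_rejects_null(self):
        wil, boot = trigger_validation(self._table(), seed=1)
        assert wil.pvalue < 0.001
        assert boot.mean > 0.5 and boot.p < 0.02

    def test_null_cohort_fails_to_reject(self):
        wil, boot = trigger_validation(self._table(elevated=False, seed=2), seed=3)
        assert boot.p > 0.05

    def test_bootstrap_seed_reproducible(self):
        t = self._table()
        _, b1 = trigger_validation(t, seed=7)
        _, b2 = trigger_validation(t, seed=7)
        assert b1.mean == b2.mean and b1.p == b2.p

    def test_no_qualifying_subjects(self):
        with pytest.raises(ValueError, match="significant"):
            trigger_validation(self._table(accuracy=0.5), seed=0)


class TestPrimaryBias:
    def test_planted_delta_recovered(self):
        covered, significant, estimates = 0, 0, []
        for seed in range(5):
            table = simulate_bias_table(n_subjects=40, delta=0.033, seed=10 + seed)
            res = primary_bias_test(table)
            lo, hi = res["induce"].ci()
            covered += lo <= 0.033 <= hi
            significant += res["induce"].p < 0.05
            estimates.append(res["induce"].estimate)
        assert covered >= 4
        assert significant == 5  # ~6-sigma planted effect
        assert np.mean(estimates) == pytest.approx(0.033, abs=0.008)

    def test_prev_volume_dominates(self):
        table = simulate_bias_table(n_subjects=30, delta=0.033, seed=11)
        res = primary_bias_test(table)
        assert res["prev_c"].estimate == pytest.approx(0.803, abs=0.1)
        assert res["prev_c"].p < 0.001

    def test_r2_scale(self):
        table = simulate_bias_table(n_subjects=40, delta=0.033, seed=12)
        res = primary_bias_test(table)
        assert 0.55 <= res.r2_adj <= 0.8

    def test_physio_outcomes_supported(self):
        table = simulate_bias_table(n_subjects=20, seed=13)
        res = primary_bias_test(table, outcome="scr")
        assert "induce" in res.fixed_effects

    def test_requires_both_trial_types(self):
        table = simulate_bias_table(n_subjects=10, seed=14)
        with pytest.raises(ValueError):
            primary_bias_test(table[table.trial_type == "Mod-PS"])


class TestRegulation:
    @pytest.fixture(scope="class")
    @staticmethod
    def tables():
        val = simulate_regulation_table(n_subjects=25, transfer=0.33, seed=20)
        aro = simulate_regulation_table(n_subjects=25, transfer=0.33, seed=21)
        return val, aro

    def test_transfer_recovered(self, tables):
        out = regulation_test(*tables)
        lo, hi = out["valence"]["fit"]["cue_c"].ci()
        assert lo <= 0.33 <= hi

    def test_surrogate_slopes_near_zero(self, tables):
        out = regulation_test(*tables)
        surr = np.array(list(out["valence"]["surrogate_slopes"].values()))
        assert abs(surr.mean()) < 0.08

    def test_signed_rank_detects_task_specific_transfer(self, tables):
        out = regulation_test(*tables)
        assert out["valence"]["comparison_p"] < 0.01

    def test_no_transfer_comparison_null(self):
        val = simulate_regulation_table(n_subjects=20, transfer=0.0, seed=22)
        aro = simulate_regulation_table(n_subjects=20, transfer=0.0, seed=23)
        out = regulation_test(val, aro)
        assert out["valence"]["comparison_p"] > 0.05


class TestInductionPredictor:
    def test_coupling_detected(self):
        table, params = simulate_predictor_table(n_subjects=40, coupling=0.85, seed=30)
        res = induction_predictor_test(table, params)
        assert res["aro_slope_z"].estimate > 0
        assert res["aro_slope_z"].p < 0.05

    def test_no_coupling_null(self):
        table, params = simulate_predictor_table(n_subjects=40, coupling=0.0, seed=31)
        res = induction_predictor_test(table, params)
        assert res["aro_slope_z"].p > 0.05

    def test_permuting_subjects_breaks_association(self):
        table, params = simulate_predictor_table(n_subjects=40, coupling=0.85, seed=32)
        rng = np.random.default_rng(0)
        params = params.copy()
        params["subject_id"] = rng.permutation(params["subject_id"].to_numpy())
        res = induction_predictor_test(table, params)
        assert res["aro_slope_z"].p > 0.05

    def test_tiny_cohort_rank_error_names_terms(self):
        table, params = simulate_predictor_table(n_subjects=4, seed=33)
        with pytest.raises(ValueError, match="aliased"):
            induction_predictor_test(table, params)
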