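"""Tests for the exclusion cascade, d' estimators and regression models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from realitymix import behavioural_analysis as ba
from realitymix import synthetic_data as syn
from realitymix.sdt_models import ModelSpec


def make_block(n_left_correct, n_right_correct, n_per_tilt=20):
    rows = []
    for i in range(n_per_tilt):
        rows.append(("left", "left" if i < n_left_correct else "right"))
    for i in range(n_per_tilt):
        rows.append(("right", "right" if i < n_right_correct else "left"))
    df = pd.DataFrame(rows, columns=["true_tilt", "response_tilt"])
    df["correct"] = (df.true_tilt == df.response_tilt).astype(int)
    df.insert(0, "trial", np.arange(len(df)))
    df.insert(0, "subject_id", 0)
    return df


class TestDprime:
    def test_hand_computed_example(self):
        # 18/20 left correct, 15/20 right correct:
        # H = 18.5/21, FA = 5.5/21 -> d' = z(0.881) - z(0.262) ~ 1.82
        d, pc = ba.dprime_from_block(make_block(18, 15))
        expected = norm.ppf(18.5 / 21) - norm.ppf(5.5 / 21)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(1.82, abs=0.01)
        assert pc == pytest.approx(33 / 40)

    def test_perfect_block_stays_finite(self):
        # log-linear correction: z(20.5/21) - z(0.5/21) = 2 * 1.9807...
        d, pc = ba.dprime_from_block(make_block(20, 20))
        assert np.isfinite(d)
        assert d == pytest.approx(2 * norm.ppf(20.5 / 21), abs=1e-12)
        assert pc == 1.0

    def test_chance_block_is_zero(self):
        d, _ = ba.dprime_from_block(make_block(10, 10))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_single_tilt_block_rejected(self):
        block = make_block(18, 15)
        with pytest.raises(ba.InvalidInputError):
            ba.dprime_from_block(block[block.true_tilt == "left"])

    @pytest.mark.parametrize(
        "disc, expected", [(0.0, 0.0), (2.1, 2.1 / np.sqrt(2)), (np.sqrt(2), 1.0)]
    )
    def test_detection_conversion(self, disc, expected):
        assert ba.detection_from_discrimination(disc) == pytest.approx(expected)

    def test_estimator_recovers_true_dprime_over_blocks(self, rng):
        """Mean of the corrected estimator over 40-trial blocks at d' = 2.1
        stays within +-0.15 of the truth (small-sample bias tolerated)."""
        n_blocks = 10_000
        trials = syn.simulate_discrimination_block(
            np.full(n_blocks, 2.1), n_trials=40, rng=rng
        )
        s = trials.assign(
            hit=((trials.true_tilt == "left") & (trials.response_tilt == "left")),
            fa=((trials.true_tilt == "right") & (trials.response_tilt == "left")),
        ).groupby("subject_id")[["hit", "fa"]].sum()
        d = norm.ppf((s.hit + 0.5) / 21) - norm.ppf((s.fa + 0.5) / 21)
        assert d.mean() == pytest.approx(2.1, abs=0.15)


class TestExclusions:
    def test_boundary_at_55_percent(self):
        ds = syn.generate_experiment(ModelSpec("mixing"), 1, 30, seed=2)
        s = ds.subjects.copy()
        s[["technical_issue", "multi_participation", "non_imaginer"]] = 0
        # subject 0: 21/40 correct (0.525, excluded); subject 1: 22/40 (kept)
        disc = ds.discrimination.copy()
        for sid, n_correct in ((0, 21), (1, 22)):
            m = disc.subject_id == sid
            disc.loc[m, "correct"] = ([1] * n_correct) + [0] * (40 - n_correct)
        filtered, report = ba.apply_exclusions(syn.BehaviouralDataset(s, disc))
        kept = set(filtered.subjects.subject_id)
        assert 0 not in kept
        assert 1 in kept

    def test_counts_match_planted_flags(self):
        ds = syn.generate_experiment(ModelSpec("mixing"), 1, 5, seed=3)
        s = ds.subjects.copy()
        s[["technical_issue", "multi_participation", "non_imaginer"]] = 0
        s.loc[0, "technical_issue"] = 1
        s.loc[1, "multi_participation"] = 1
        s.loc[2, "non_imaginer"] = 1
        disc = ds.discrimination.copy()
        disc["correct"] = 1  # nobody fails the performance screen
        disc["response_tilt"] = disc["true_tilt"]
        s["immediate_response"] = "none"  # nobody reports the wrong grating
        filtered, report = ba.apply_exclusions(syn.BehaviouralDataset(s, disc))
        assert report.counts == {
            "technical": 1,
            "multi_participation": 1,
            "low_discrimination": 0,
            "non_imaginer": 1,
            "wrong_grating": 0,
        }
        assert report.n_final == filtered.n_subjects == 7

    def test_rerun_excludes_nobody(self, exp1_mixing):
        filtered, _ = ba.apply_exclusions(exp1_mixing)
        _, second = ba.apply_exclusions(filtered)
        assert sum(second.counts.values()) == 0
        assert second.n_final == filtered.n_subjects

    def test_exp2_real_reports_are_retained(self, exp2_mixing):
        filtered, report = ba.apply_exclusions(exp2_mixing)
        assert report.counts["wrong_grating"] == 0
        s = ba.subject_measures(filtered)
        assert (s.judged_real == 1).any()

    def test_missing_flags_raise_schema_error(self, exp1_mixing):
        broken = syn.BehaviouralDataset.__new__(syn.BehaviouralDataset)
        broken.subjects = exp1_mixing.subjects.drop(columns=["non_imaginer"])
        broken.discrimination = exp1_mixing.discrimination
        with pytest.raises(syn.SchemaError, match="non_imaginer"):
            ba.apply_exclusions(broken)


class TestRealityLogistic:
    def test_null_condition_effect_is_eliminated(self):
        """Selection consistency: under source separation the condition term
        should be dropped in >= 90% of replicates."""
        rng = np.random.default_rng(50)
        retained = 0
        n_rep = 50
        for _ in range(n_rep):
            ds = syn.generate_experiment(
                ModelSpec("source_separation"), 1, 150, seed=rng
            )
            filtered, _ = ba.apply_exclusions(ds)
            fit = ba.fit_reality_logistic(filtered)
            retained += "condition" in fit.selected_terms
        assert retained <= 0.10 * n_rep

    def test_mixing_condition_effect_retained_with_correct_direction(self):
        ds = syn.generate_experiment(ModelSpec("mixing"), 1, 300, seed=51)
        filtered, _ = ba.apply_exclusions(ds)
        fit = ba.fit_reality_logistic(filtered)
        assert "condition" in fit.selected_terms
        assert fit.params["condition"] > 0  # congruent raises odds of "real"
        assert fit.odds_ratios["condition"] > 1

    def test_selected_bic_never_exceeds_full_model(self, exp1_mixing):
        filtered, _ = ba.apply_exclusions(exp1_mixing)
        fit = ba.fit_reality_logistic(filtered)
        full_bic = fit.elimination_path[0][1]
        assert fit.bic <= full_bic + 1e-9

    def test_nagelkerke_null_model_is_zero(self):
        assert ba._nagelkerke(llf=-100.0, llnull=-100.0, n=200) == 0.0

    @given(scale=st.floats(0.1, 10.0))
    def test_nagelkerke_invariant_to_predictor_rescaling(self, scale, exp1_mixing):
        filtered, _ = ba.apply_exclusions(exp1_mixing)
        fit = ba.fit_reality_logistic(filtered)
        s = ba.subject_measures(filtered)
        import statsmodels.api as sm

        y = s["judged_real"].astype(float)
        X = ba._design_matrix(s, fit.selected_terms, "treatment")
        r2_ref = ba._nagelkerke(
            sm.Logit(y, X).fit(disp=False).llf,
            sm.Logit(y, X[["const"]]).fit(disp=False).llf,
            len(y),
        )
        X2 = X.copy()
        for col in X2.columns:
            if col != "const":
                X2[col] = X2[col] * scale
        r2_scaled = ba._nagelkerke(
            sm.Logit(y, X2).fit(disp=False).llf,
            sm.Logit(y, X2[["const"]]).fit(disp=False).llf,
            len(y),
        )
        assert r2_scaled == pytest.approx(r2_ref, abs=1e-8)


class TestOrdinalVividness:
    def test_shuffled_judgments_give_null_contrast(self):
        """Permuting the judgment labels destroys the contrast: its CI should
        cover 0 in the large majority of replicates."""
        rng = np.random.default_rng(61)
        n_cover = 0
        n_rep = 50
        for _ in range(n_rep):
            ds = syn.generate_experiment(ModelSpec("mixing"), 1, 120, seed=rng)
            filtered, _ = ba.apply_exclusions(ds)
            shuffled = filtered.subjects.copy()
            resp = shuffled["immediate_response"].to_numpy().copy()
            rng.shuffle(resp)
            shuffled["immediate_response"] = resp
            contrasts = ba.fit_vividness_ordinal(
                syn.BehaviouralDataset(shuffled, filtered.discrimination), 1
            )
            c = contrasts["congruent"]
            n_cover += c.conf_int[0] <= 0 <= c.conf_int[1]
        assert n_cover >= 0.9 * n_rep

    def test_mixing_gives_positive_congruent_contrast(self, exp1_mixing):
        filtered, _ = ba.apply_exclusions(exp1_mixing)
        contrasts = ba.fit_vividness_ordinal(filtered, 1)
        c = contrasts["congruent"]
        assert c.estimate > 0
        assert c.conf_int[0] > 0

    def test_mixing_exp2_contrast_positive(self, exp2_mixing):
        filtered, _ = ba.apply_exclusions(exp2_mixing)
        contrasts = ba.fit_vividness_ordinal(filtered, 2)
        assert contrasts["absent"].estimate > 0

    def test_constant_ratings_rejected(self, exp1_mixing):
        s = exp1_mixing.subjects.copy()
        s["critical_rating"] = 3
        with pytest.raises(ba.InvalidInputError, match="identical"):
            ba.fit_vividness_ordinal(
                syn.BehaviouralDataset(s, exp1_mixing.discrimination), 1
            )


class TestGroupVividness:
    def test_identical_groups_give_zero(self, exp1_mixing):
        filtered, _ = ba.apply_exclusions(exp1_mixing)
        s = filtered.subjects.copy()
        pre_cols = [f"pre_rating_{i}" for i in range(1, 10)]
        s[pre_cols] = 3  # everyone identical
        tests, _ = ba.group_vividness_tests(
            syn.BehaviouralDataset(s, filtered.discrimination)
        )
        for t in tests.values():
            assert t.t_statistic == pytest.approx(0.0, abs=1e-12)
            assert t.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_power_matches_noncentral_t(self, rng):
        """Rejection rate for a +0.5 SD shift tracks the closed-form power of
        the two-sample t-test."""
        from scipy.stats import nct, t as t_dist

        n1 = n2 = 30
        effect = 0.5
        df = n1 + n2 - 2
        ncp = effect / np.sqrt(1 / n1 + 1 / n2)
        tcrit = t_dist.ppf(0.975, df)
        power = 1 - nct.cdf(tcrit, df, ncp) + nct.cdf(-tcrit, df, ncp)
        n_rep, rejections = 400, 0
        from scipy.stats import ttest_ind

        for _ in range(n_rep):
            a = rng.standard_normal(n1) + effect
            b = rng.standard_normal(n2)
            rejections += ttest_ind(a, b, equal_var=True).pvalue < 0.05
        se = np.sqrt(power * (1 - power) / n_rep)
        assert rejections / n_rep == pytest.approx(power, abs=4 * se)

    def test_mixing_errors_have_higher_vividness_in_exp2(self, exp2_mixing):
        filtered, _ = ba.apply_exclusions(exp2_mixing)
        tests, corr = ba.group_vividness_tests(filtered)
        t = tests["absent"]
        # "real" reports with no stimulus are errors driven by vivid imagery
        assert t.mean_real > t.mean_imagined
        assert corr["r"] < 0  # vividness anticorrelates with sensitivity

    def test_small_group_raises_in_strict_mode(self, exp1_mixing):
        filtered, _ = ba.apply_exclusions(exp1_mixing)
        s = filtered.subjects.copy()
        # force a single "real" judgment in one condition
        mask = s.condition == "incongruent"
        s.loc[mask, "immediate_response"] = "none"
        s.loc[s[mask].index[0], "immediate_response"] = "right"
        with pytest.raises(ba.InvalidInputError):
            ba.group_vividness_tests(
                syn.BehaviouralDataset(s, filtered.discrimination), strict=True
            )
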