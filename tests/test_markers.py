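"""Marker selection, ROC, group lasso, clinical and medication analyses."""

import numpy as np
import pandas as pd
import pytest

import mwaskit as mk
from mwaskit.markers import _fit_group_lasso_path


def feature_frame(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


def informative_cohort(n_per=40, n_noise=30, n_info=3, shift=1.5, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_noise + n_info, 2 * n_per))
    x[:n_info, :n_per] += shift
    labels = ["case"] * n_per + ["control"] * n_per
    return feature_frame(x), labels


class TestRfcvSelect:
    def test_recovers_informative_features(self):
        m, labels = informative_cohort(seed=1)
        sel = mk.rfcv_select(m, labels, folds=5, repeats=2, max_panel=10,
                             seed=2, n_trees=60)
        informative = {"f0", "f1", "f2"}
        assert len(set(sel.ranked_features[:5]) & informative) >= 2
        assert set(sel.chosen_panel) & informative

    def test_same_seed_bit_reproducible(self):
        m, labels = informative_cohort(n_per=20, seed=3)
        a = mk.rfcv_select(m, labels, folds=4, repeats=1, max_panel=6, seed=5, n_trees=30)
        b = mk.rfcv_select(m, labels, folds=4, repeats=1, max_panel=6, seed=5, n_trees=30)
        assert a.chosen_panel == b.chosen_panel
        pd.testing.assert_series_equal(a.error_curve, b.error_curve)
        pd.testing.assert_series_equal(a.probabilities, b.probabilities)

    def test_cutoff_rule_arithmetic(self):
        m, labels = informative_cohort(n_per=20, seed=6)
        sel = mk.rfcv_select(m, labels, folds=4, repeats=1, max_panel=6, seed=7, n_trees=30)
        assert sel.cutoff == pytest.approx(sel.error_curve.min() + sel.error_sd_at_min)
        assert all(sel.error_curve[k] < sel.cutoff for k in sel.candidate_panels)
        if sel.candidate_panels:
            assert sel.chosen_size == min(sel.candidate_panels)
        assert sel.chosen_size <= 6

    def test_panel_capped_at_max_panel(self):
        m, labels = informative_cohort(n_per=15, n_noise=40, seed=8)
        sel = mk.rfcv_select(m, labels, folds=3, repeats=1, max_panel=25, seed=9, n_trees=20)
        assert sel.error_curve.index.max() <= 25
        assert all(k <= 25 for k in sel.candidate_panels)

    def test_small_class_raises_with_guidance(self):
        m, _ = informative_cohort(n_per=10, seed=10)
        labels = ["case"] * 3 + ["control"] * 17
        with pytest.raises(ValueError, match="folds"):
            mk.rfcv_select(m, labels, folds=5)

    def test_probabilities_are_out_of_fold(self):
        # permuted labels must give chance-level out-of-fold probabilities:
        # any in-fold leakage would push AUC well above 0.5
        rng = np.random.default_rng(11)
        m = feature_frame(rng.normal(size=(20, 80)))
        labels = list(rng.permutation(["case"] * 40 + ["control"] * 40))
        sel = mk.rfcv_select(m, labels, folds=5, repeats=2, max_panel=8, seed=12, n_trees=40)
        roc = mk.roc_analysis(sel.probabilities, labels, case_label="case")
        assert 0.35 <= roc.auc <= 0.65

    def test_multilevel_with_balance(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(10, 90))
        x[0, :30] += 2.0
        x[1, 30:50] += 2.0  # deliberately unequal class sizes
        labels = ["d1"] * 30 + ["d2"] * 20 + ["ctrl"] * 40
        sel = mk.rfcv_select(feature_frame(x), labels, folds=4, repeats=1,
                             max_panel=6, balance=True, seed=14, n_trees=40)
        assert sel.probabilities is None  # multi-class: no single score
        assert set(sel.ranked_features[:3]) & {"f0", "f1"}


class TestRocAnalysis:
    def test_perfect_separation(self):
        roc = mk.roc_analysis([0.9, 0.8, 0.4, 0.2], ["+", "+", "-", "-"], case_label="+")
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_index == pytest.approx(1.0)

    def test_three_of_four_concordant(self):
        roc = mk.roc_analysis([0.9, 0.3, 0.5, 0.1], ["+", "+", "-", "-"], case_label="+")
        assert roc.auc == pytest.approx(0.75)

    def test_label_swap_symmetry(self):
        probs = [0.9, 0.3, 0.5, 0.1]
        a = mk.roc_analysis(probs, ["+", "+", "-", "-"], case_label="+")
        b = mk.roc_analysis(probs, ["-", "-", "+", "+"], case_label="+")
        assert b.auc == pytest.approx(1.0 - a.auc)

    def test_matches_concordant_pair_brute_force(self):
        rng = np.random.default_rng(15)
        for trial in range(10):
            n = int(rng.integers(6, 31))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
            labels = rng.choice(["+", "-"], size=n)
            if len(set(labels)) < 2:
                continue
            pos = scores[labels == "+"]
            neg = scores[labels == "-"]
            brute = np.mean([
                1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
            ])
            roc = mk.roc_analysis(scores, labels, case_label="+")
            assert roc.auc == pytest.approx(brute, abs=1e-12)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(16)
        scores = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])
        labels = ["+"] * 50 + ["-"] * 50
        roc = mk.roc_analysis(scores, labels, case_label="+")
        assert roc.ci_low <= roc.auc <= roc.ci_high
        assert roc.ci_high - roc.ci_low < 0.3

    def test_youden_tie_breaks_to_lower_cutoff(self):
        # all cutoffs equally useless: J = 0 everywhere, lowest cutoff returned
        roc = mk.roc_analysis([0.2, 0.4, 0.2, 0.4], ["+", "+", "-", "-"], case_label="+")
        assert roc.youden_index == pytest.approx(0.0)
        assert roc.youden_cutoff == pytest.approx(0.2)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            mk.roc_analysis([0.1, 0.2], ["+", "+"], case_label="+")


class TestEnzymeClassifier:
    def test_planted_enzyme_signal_detected(self):
        rng = np.random.default_rng(17)
        n = 40
        x = np.exp(rng.normal(size=(4, 2 * n)))
        x[2, :n] *= 4.0  # YeaW-like case enrichment
        x[3, :n] *= 4.0
        m = feature_frame(x, prefix="enz")
        labels = ["case"] * n + ["control"] * n
        sel, roc = mk.enzyme_classifier(m, labels, folds=5, repeats=2, seed=18,
                                        n_trees=60, case_label="case")
        assert roc.auc > 0.7
        assert sel.chosen_size <= 4

    def test_zero_matrix_chance_level(self):
        m = feature_frame(np.zeros((4, 40)))
        labels = ["case"] * 20 + ["control"] * 20
        sel, roc = mk.enzyme_classifier(m, labels, folds=4, repeats=1, seed=19,
                                        n_trees=20, case_label="case")
        assert abs(roc.auc - 0.5) <= 0.1


class TestGroupLasso:
    @staticmethod
    def _design(seed=20, n=60, p_per=4, n_groups=3, signal_group=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n_groups * p_per, n))
        beta = np.zeros(n_groups * p_per)
        beta[signal_group * p_per : (signal_group + 1) * p_per] = 1.0
        logits = beta @ x
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        m = feature_frame(x)
        gmap = {
            f"grp{g}": [f"f{g * p_per + i}" for i in range(p_per)] for g in range(n_groups)
        }
        return m, y, gmap

    def test_infinite_penalty_kills_all_groups(self):
        m, y, gmap = self._design()
        res = mk.group_lasso(m, y, gmap, penalty_path=[1e6, 1e-2], bootstraps=2, seed=21)
        assert np.allclose(res.regularization_path.iloc[0], 0.0)

    def test_orthonormal_single_group_soft_threshold(self):
        # squared loss, orthonormal X: solution is block soft-thresholding of
        # the least-squares coefficient
        rng = np.random.default_rng(22)
        n, p = 200, 3
        raw = rng.normal(size=(n, p))
        raw -= raw.mean(axis=0)  # centered so the free intercept stays 0
        q, _ = np.linalg.qr(raw)
        x = q * np.sqrt(n)  # X'X/n = I
        beta_true = np.array([1.0, -2.0, 0.5])
        y = x @ beta_true
        lam = 0.8
        w = np.sqrt(p)
        coefs, _, _ = _fit_group_lasso_path(
            x, y, [np.arange(p)], np.array([w]), np.array([lam]), "linear",
            max_iter=20000, tol=1e-14,
        )
        ls = x.T @ y / n
        shrink = max(0.0, 1.0 - lam * w / np.linalg.norm(ls))
        assert np.allclose(coefs[0], shrink * ls, atol=1e-6)

    def test_planted_group_selected_in_bootstraps(self):
        m, y, gmap = self._design(seed=23)
        res = mk.group_lasso(m, y, gmap, bootstraps=10, seed=24)
        assert "grp0" in res.selected_groups
        assert res.bootstrap_selection_frequency["grp0"] >= 0.8

    def test_objective_monotone_decrease(self):
        m, y, gmap = self._design(seed=25)
        res = mk.group_lasso(m, y, gmap, bootstraps=2, seed=26)
        obj = np.array(res.objective_history)
        assert np.all(np.diff(obj) <= 1e-10)

    def test_non_partition_rejected(self):
        m, y, gmap = self._design()
        gmap.pop("grp2")
        with pytest.raises(ValueError, match="partition"):
            mk.group_lasso(m, y, gmap)


class TestClinicalAssociation:
    def test_planted_pair_recovered_with_sign(self):
        rng = np.random.default_rng(27)
        n = 60
        m = feature_frame(np.exp(rng.normal(size=(8, n))), prefix="MLG")
        idx = pd.DataFrame(index=m.columns)
        idx["ast"] = np.log(m.loc["MLG0"]) + rng.normal(0, 0.3, n)
        idx["noise"] = rng.normal(size=n)
        out = mk.clinical_association(m, idx, n_perm=199, seed=28, repeats=1, n_trees=60)
        hit = out[(out["index"] == "ast") & (out["mlg"] == "MLG0")]
        assert len(hit) == 1
        assert hit["cc"].iloc[0] > 0.5
        assert set(hit["strength"]) == {"strong"}

    def test_filters_enforced_on_output(self):
        rng = np.random.default_rng(29)
        m = feature_frame(np.exp(rng.normal(size=(6, 50))), prefix="MLG")
        idx = pd.DataFrame({"i1": rng.normal(size=50)}, index=m.columns)
        out = mk.clinical_association(m, idx, n_perm=99, cc_min=0.2, p_max=0.05,
                                      seed=30, repeats=1, n_trees=40)
        if len(out):
            assert (out["cc"].abs() >= 0.2).all()
            assert (out["p_value"] < 0.05).all()

    def test_all_missing_index_skipped(self):
        rng = np.random.default_rng(31)
        m = feature_frame(np.exp(rng.normal(size=(4, 30))), prefix="MLG")
        idx = pd.DataFrame({"empty": [np.nan] * 30, "ok": rng.normal(size=30)},
                           index=m.columns)
        out = mk.clinical_association(m, idx, n_perm=49, seed=32, repeats=1, n_trees=20)
        assert "empty" in out.attrs["skipped_indices"]


class TestMedicationAnalysis:
    @staticmethod
    def _cohort(drug_effect=0.0, disease_shift=1.5, n=30, seed=33):
        rng = np.random.default_rng(seed)
        x = np.exp(rng.normal(size=(8, 2 * n)))
        x[0, :n] *= np.exp(disease_shift)  # disease effect
        samples = [f"s{j}" for j in range(2 * n)]
        labels = ["case"] * n + ["control"] * n
        treated = np.zeros(2 * n, dtype=bool)
        treated[: n // 2] = True  # half the cases are on the drug
        if drug_effect:
            x[3, treated] *= np.exp(drug_effect)
        m = feature_frame(x)
        m.columns = samples
        flags = pd.DataFrame({"drugA": treated.astype(int)}, index=samples)
        return m, labels, flags

    def test_null_drug_chance_level_and_disease_dominates(self):
        m, labels, flags = self._cohort(drug_effect=0.0)
        out = mk.medication_analysis(m, labels, flags, folds=3, repeats=1,
                                     seed=34, n_trees=40, n_perm=99)
        row = out.loc["drugA"]
        assert abs(row["case_drug_vs_case_nodrug_auc"] - 0.5) <= 0.22
        assert row["case_drug_vs_control_auc"] > row["case_drug_vs_case_nodrug_auc"]
        assert row["case_nodrug_vs_control_auc"] > row["case_drug_vs_case_nodrug_auc"]
        assert row["permanova_p"] > 0.05

    def test_planted_drug_effect_found_by_permanova(self):
        m, labels, flags = self._cohort(drug_effect=3.0, seed=35)
        out = mk.medication_analysis(m, labels, flags, folds=3, repeats=1,
                                     seed=36, n_trees=40, n_perm=199)
        assert out.loc["drugA", "permanova_p"] < 0.05

    def test_small_stratum_marked_not_computed(self):
        m, labels, flags = self._cohort(n=8, seed=37)
        flags["drugA"] = 0
        flags.iloc[0, 0] = 1  # a single treated case
        out = mk.medication_analysis(m, labels, flags, folds=3, repeats=1,
                                     seed=38, n_trees=20, n_perm=49)
        assert np.isnan(out.loc["drugA", "case_drug_vs_control_auc"])
        assert np.isnan(out.loc["drugA", "case_drug_vs_case_nodrug_auc"])
        assert not np.isnan(out.loc["drugA", "case_nodrug_vs_control_auc"])
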