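"""Differential testing, FDR, networks, reporter scores, exact tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import mwaskit as mk
from mwaskit.stats import REPORTER_BAND, REPORTER_DETECTION, _weight_class


def exact_ranksum_p(x, y):
    """Exhaustive two-sided Wilcoxon rank-sum p over all rank splits."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()  # midranks
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


class TestBenjaminiHochberg:
    def test_single_p_identity(self):
        assert mk.benjamini_hochberg([0.01]) == pytest.approx([0.01])

    def test_hand_step_up(self):
        assert np.allclose(mk.benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            mk.benjamini_hochberg([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_q_in_unit_interval_and_monotone_over_sorted_p(self, ps):
        q = mk.benjamini_hochberg(ps)
        assert np.all((q >= 0) & (q <= 1))
        assert np.all(q >= np.asarray(ps) - 1e-12)  # BH never decreases a p
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDifferentialAbundance:
    @staticmethod
    def _frame(rows, labels):
        m = pd.DataFrame(rows, columns=[f"s{i}" for i in range(len(labels))])
        m.index = [f"f{i}" for i in range(len(rows))]
        return m, labels

    def test_identical_groups_p_one(self):
        m, g = self._frame([[1, 2, 3, 1, 2, 3]], ["case"] * 3 + ["control"] * 3)
        out = mk.differential_abundance(m, g, case_label="case")
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        # {1,2,3} vs {4,5,6}: most extreme split, two-sided p = 2/20
        m, g = self._frame([[1, 2, 3, 4, 5, 6]], ["case"] * 3 + ["control"] * 3)
        out = mk.differential_abundance(m, g, case_label="case")
        assert out["p_value"].iloc[0] == pytest.approx(0.1)
        assert out["direction"].iloc[0] == "control-enriched"
        assert out["median_case"].iloc[0] == 2.0
        assert out["median_control"].iloc[0] == 5.0

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 4), (8, 8), (2, 7)])
    def test_matches_exhaustive_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x, y = rng.random(n1), rng.random(n2)
        m, g = self._frame([np.concatenate([x, y])], ["case"] * n1 + ["control"] * n2)
        out = mk.differential_abundance(m, g, case_label="case")
        assert out["p_value"].iloc[0] == pytest.approx(exact_ranksum_p(x, y), abs=1e-9)

    def test_planted_enrichment_detected(self, small_profiles, small_catalog):
        filt, meta, truth = small_profiles
        genome_ab = mk.aggregate_features(
            filt, pd.Series(small_catalog.gene_to_genome, name="feature").to_frame()
        )
        out = mk.differential_abundance(genome_ab, meta["group"], case_label="case")
        planted = truth.true_enriched | truth.true_depleted
        for gm in truth.true_enriched:
            assert out.loc[gm, "direction"] == "case-enriched"
        for gm in truth.true_depleted:
            assert out.loc[gm, "direction"] == "control-enriched"
        null = out.index.difference(planted)
        assert out.loc[sorted(planted), "q_value"].median() < 0.05
        assert out.loc[sorted(planted), "p_value"].median() < out.loc[null, "p_value"].median()

    def test_group_size_guard(self):
        m, g = self._frame([[1, 2, 3]], ["case", "control", "control"])
        with pytest.raises(ValueError):
            mk.differential_abundance(m, g)


class TestCooccurrenceNetwork:
    def test_self_copy_is_thick_positive(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        m = pd.DataFrame([base, base * 2.0], index=["a", "b"])
        edges = mk.cooccurrence_network(m)
        assert len(edges) == 1
        e = edges.iloc[0]
        assert e["cc"] == pytest.approx(1.0)
        assert (e["sign"], e["weight_class"]) == ("positive", "thick")

    def test_reversed_ranks_thick_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = pd.DataFrame([x, -x], index=["a", "b"])
        e = mk.cooccurrence_network(m).iloc[0]
        assert e["cc"] == pytest.approx(-1.0)
        assert (e["sign"], e["weight_class"]) == ("negative", "thick")

    def test_weight_bands(self):
        # rank permutation with sum(d^2)=8 on n=5 gives rho exactly 0.6
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 4.0])
        m = pd.DataFrame([x, y], index=["a", "b"])
        e = mk.cooccurrence_network(m).iloc[0]
        assert e["cc"] == pytest.approx(0.6)
        assert e["weight_class"] == "medium"
        assert _weight_class(0.71) == "thick"
        assert _weight_class(0.45) == "thin"

    def test_cc_min_excludes_weak_pairs(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.random((6, 40)))
        edges = mk.cooccurrence_network(m, cc_min=0.3)
        assert (edges["cc"].abs() >= 0.3).all()

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.random((5, 20)), columns=[f"s{i}" for i in range(20)])
        a = mk.cooccurrence_network(m)
        perm = list(rng.permutation(m.columns))
        b = mk.cooccurrence_network(m[perm])
        pd.testing.assert_frame_equal(a, b)


class TestReporterScores:
    @staticmethod
    def _cohort(n_kos=60, n=40, enriched=None, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.exp(rng.normal(0, 1, size=(n_kos, 2 * n)))
        kos = [f"K{i:05d}" for i in range(n_kos)]
        labels = ["case"] * n + ["control"] * n
        for k in enriched or []:
            vals[k, :n] *= 4.0
        m = pd.DataFrame(vals, index=kos, columns=[f"s{i}" for i in range(2 * n)])
        return m, labels, kos

    def test_printed_thresholds_are_normal_quantiles(self):
        assert REPORTER_BAND == pytest.approx(norm.ppf(0.975), abs=0.005)
        assert REPORTER_DETECTION == pytest.approx(round(norm.ppf(0.95), 1))

    def test_planted_module_scores_high(self):
        m, labels, kos = self._cohort(enriched=range(6), seed=1)
        modules = {"planted": set(kos[:6]), "null": set(kos[20:26])}
        out = mk.reporter_scores(m, labels, modules, seed=2, case_label="case")
        assert out.loc["planted", "reporter_score"] > REPORTER_BAND
        assert out.loc["planted", "direction"] == "case"
        assert abs(out.loc["null", "reporter_score"]) < REPORTER_BAND

    def test_k1_module_is_standardized_single_ko_z(self):
        m, labels, kos = self._cohort(seed=3)
        out = mk.reporter_scores(
            m, labels, {"solo": {kos[5]}}, seed=4, n_background=4000, case_label="case"
        )
        from mwaskit.stats import _ko_z_scores, two_group_masks

        case, ctrl, _, _ = two_group_masks(labels, "case")
        z = _ko_z_scores(m, case, ctrl, use_adjusted_p=False)
        expected = (z[kos[5]] - z.mean()) / z.std(ddof=0)
        assert out.loc["solo", "reporter_score"] == pytest.approx(expected, abs=0.15)

    def test_null_modules_centered(self):
        m, labels, kos = self._cohort(n_kos=80, seed=5)
        rng = np.random.default_rng(6)
        modules = {
            f"null{i}": set(np.array(kos)[rng.choice(80, size=6, replace=False)])
            for i in range(60)
        }
        out = mk.reporter_scores(m, labels, modules, seed=7, case_label="case")
        assert out["reporter_score"].abs().mean() < 0.95  # ~E|N(0,1)| = 0.8

    def test_unscored_module_excluded_with_warning(self, caplog):
        m, labels, kos = self._cohort(seed=8)
        with caplog.at_level("WARNING"):
            out = mk.reporter_scores(
                m, labels, {"ghost": {"K99999"}, "ok": {kos[0]}}, seed=9, case_label="case"
            )
        assert "ghost" not in out.index and "ok" in out.index

    def test_occurrence_filter(self):
        m, labels, kos = self._cohort(seed=10)
        m.iloc[0, :] = 0.0
        m.iloc[0, :3] = 1.0  # present in 3 samples only
        out = mk.reporter_scores(
            m, labels, {"rare": {kos[0]}, "ok": {kos[1]}}, min_samples=5,
            seed=11, case_label="case",
        )
        assert "rare" not in out.index


class TestSpearmanPermutation:
    def test_perfect_correlation_floor_p(self):
        x = np.arange(10.0)
        cc, p = mk.spearman_permutation(x, x, n_perm=99, seed=1)
        assert cc == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 100.0)

    def test_matches_exhaustive_enumeration_n5(self):
        rng = np.random.default_rng(12)
        x, y = rng.random(5), rng.random(5)
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean()) / ry.std()
        obs = abs(rx @ ry / 5)
        hits = sum(
            1 for perm in itertools.permutations(ry) if abs(rx @ np.array(perm) / 5) >= obs - 1e-12
        )
        exact = hits / 120
        cc, p = mk.spearman_permutation(x, y, n_perm=5000, seed=13)
        assert p == pytest.approx(exact, abs=0.03)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mk.spearman_permutation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_p_never_zero(self):
        x = np.arange(20.0)
        _, p = mk.spearman_permutation(x, x, n_perm=999, seed=2)
        assert p >= 1.0 / 1000.0


class TestFisherGeneContent:
    def test_equal_occurrence_p_one(self):
        pres = pd.DataFrame([[1, 1, 0, 1, 1, 0]], index=["g"],
                            columns=[f"s{i}" for i in range(6)])
        out = mk.fisher_gene_content(pres, ["case"] * 3 + ["control"] * 3)
        assert out.loc["g", "p_value"] == pytest.approx(1.0)

    def test_disjoint_occupancy_hypergeometric(self):
        # [[5,0],[0,5]]: two-sided p = 2/C(10,5) = 2/252
        pres = pd.DataFrame([[1] * 5 + [0] * 5], index=["g"],
                            columns=[f"s{i}" for i in range(10)])
        out = mk.fisher_gene_content(pres, ["case"] * 5 + ["control"] * 5)
        assert out.loc["g", "p_value"] == pytest.approx(2.0 / 252.0, rel=1e-6)

    def test_planted_differential_occupancy_recovered(self):
        rng = np.random.default_rng(14)
        n = 60
        rows = [(rng.random(2 * n) < 0.5).astype(int) for _ in range(20)]
        planted = np.concatenate([(rng.random(n) < 0.9), (rng.random(n) < 0.1)]).astype(int)
        rows.append(planted)
        pres = pd.DataFrame(rows, index=[f"g{i}" for i in range(21)],
                            columns=[f"s{i}" for i in range(2 * n)])
        out = mk.fisher_gene_content(pres, ["case"] * n + ["control"] * n)
        assert out.loc["g20", "q_value"] < 0.05
        assert (out.loc[[f"g{i}" for i in range(20)], "q_value"] > 0.05).mean() > 0.8

    def test_non_boolean_rejected(self):
        pres = pd.DataFrame([[2, 0, 1, 1]], index=["g"])
        with pytest.raises(ValueError):
            mk.fisher_gene_content(pres, ["a", "a", "b", "b"])
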