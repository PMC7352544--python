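import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hoxpress.diffexpr import (
    HighlightFilter,
    classify_de,
    fold_change,
    gene_set_de_profile,
    highlight,
    subtype_compare,
    wilcoxon_rank_sum,
)
from hoxpress.io import ExpressionMatrix
from hoxpress.simulate import SimulationConfig, generate

from conftest import make_cohort_pair


def brute_force_ranksum_p(x, y):
    """Independent oracle: exact two-sided rank-sum p by full enumeration."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    ws = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n)]
    le = sum(w <= w_obs + 1e-12 for w in ws)
    ge = sum(w >= w_obs - 1e-12 for w in ws)
    return min(1.0, 2.0 * min(le, ge) / len(ws))


class TestWilcoxonRankSum:
    def test_extreme_separation_exact_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / 20)  # 2 * 1/C(6,3)

    def test_identical_multisets_near_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p >= 0.9

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-12)

    def test_exact_path_handles_ties(self):
        x = [1.0, 1.0, 2.0]
        y = [1.0, 2.0, 3.0]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=40), rng.normal(0.5, size=35)
        _, p = wilcoxon_rank_sum(x, y)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(expected, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_two_sided_p_symmetric_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(3, 7))
        y = rng.normal(size=rng.integers(3, 7))
        assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(wilcoxon_rank_sum(y, x)[1])


class TestFoldChange:
    @pytest.mark.parametrize(
        "healthy,tumor,expected",
        [([2, 2], [2, 2], 1.0), ([1, 2, 3], [2, 3, 4], 2.0), ([1, 1, 1], [3, 3, 3], 4.0)],
    )
    def test_log2_definition(self, healthy, tumor, expected):
        assert fold_change(healthy, tumor) == pytest.approx(expected)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_reciprocal_identity(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0, 8, size=6), rng.uniform(0, 8, size=7)
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_median_and_linear_variants(self):
        h, t = [1.0, 1.0, 5.0], [2.0, 2.0, 2.0]
        assert fold_change(h, t, center="median") == pytest.approx(2.0)
        linear = fold_change(h, t, scale="linear")
        assert linear == pytest.approx(3.0 / np.mean([1.0, 1.0, 31.0]))


class TestClassifyDE:
    def test_planted_strong_gene_called_up(self, planted_cohort):
        de = classify_de(planted_cohort.cohort, n_tests=39)
        table = de.set_index("gene")
        assert table.loc["HOXA13", "call"] == "up"
        assert table.loc["HOXC10", "call"] == "down"
        assert table.loc["HOXA1", "call"] == "none"

    def test_fold_condition_gates_significance(self):
        rng = np.random.default_rng(1)
        healthy = rng.normal(3, 0.1, size=(1, 200))
        tumor = rng.normal(3.9, 0.1, size=(1, 200))  # FC ~ 1.87 < 2
        pair = make_cohort_pair(healthy, tumor)
        de = classify_de(pair, n_tests=1)
        assert de.loc[0, "p_adj"] < 1e-10
        assert de.loc[0, "call"] == "none"

    def test_significance_condition_gates_fold(self):
        rng = np.random.default_rng(2)
        healthy = rng.normal(3, 4, size=(1, 5))
        tumor = rng.normal(5, 4, size=(1, 5))
        pair = make_cohort_pair(np.clip(healthy, 0, None), np.clip(tumor, 0, None))
        de = classify_de(pair, n_tests=39)
        assert de.loc[0, "call"] == "none"

    def test_bonferroni_invariants(self, planted_cohort):
        de = classify_de(planted_cohort.cohort, n_tests=39)
        assert (de["p_adj"] >= de["p_raw"] - 1e-15).all()
        assert (de["p_adj"] <= 1.0).all()

    def test_bonferroni_monotonicity_never_creates_calls(self, planted_cohort):
        few = classify_de(planted_cohort.cohort, n_tests=10).set_index("gene")["call"]
        many = classify_de(planted_cohort.cohort, n_tests=1000).set_index("gene")["call"]
        for gene in few.index:
            if many[gene] != "none":
                assert few[gene] != "none"

    def test_shift_invariance_of_calls(self):
        rng = np.random.default_rng(3)
        healthy = np.clip(rng.normal(4, 1, size=(3, 60)), 0, None)
        tumor = np.clip(rng.normal(5.5, 1, size=(3, 60)), 0, None)
        base = classify_de(make_cohort_pair(healthy, tumor), n_tests=3)
        shifted = classify_de(make_cohort_pair(healthy + 2, tumor + 2), n_tests=3)
        assert base["call"].tolist() == shifted["call"].tolist()
        np.testing.assert_allclose(base["FC"], shifted["FC"], rtol=1e-9)

    def test_missing_gene_lists_symbols(self, planted_cohort):
        with pytest.raises(KeyError, match="NOPE"):
            classify_de(planted_cohort.cohort, ["HOXA1", "NOPE"])


class TestHighlight:
    def _frame(self, fc, mean_healthy, mean_tumor=5.0):
        return pd.DataFrame(
            {
                "gene": ["g"], "mean_healthy": [mean_healthy], "mean_tumor": [mean_tumor],
                "FC": [fc], "p_raw": [1e-6], "p_adj": [1e-5], "call": ["up"],
            }
        )

    def test_kept_when_fold_and_floor_pass(self):
        assert len(highlight(self._frame(3.4, 1.2), HighlightFilter(3, "healthy", 1))) == 1

    def test_dropped_when_floor_fails(self):
        assert len(highlight(self._frame(5.0, 0.4), HighlightFilter(3, "healthy", 1))) == 0

    def test_downregulation_counts_via_reciprocal(self):
        assert len(highlight(self._frame(0.25, 3.0), HighlightFilter(3, "healthy", 1))) == 1

    def test_bundled_pronounced_change_table_self_consistent(self):
        # Every transcribed entry respects its own selection thresholds.
        from hoxpress.fixtures import load_pronounced_changes

        table = load_pronounced_changes()
        assert (table["fold_change"].abs() >= 3.0).all()
        assert len(table) == 28


class TestGeneSetProfile:
    def test_planted_panel_recovery(self, planted_cohort):
        profile = gene_set_de_profile(planted_cohort.cohort, ["HOXA13", "HOXB9", "HOXA1"])
        assert profile["n_tested"] == 3
        assert profile["n_de"] == 2

    def test_single_gene_list_uses_no_correction(self, planted_cohort):
        profile = gene_set_de_profile(planted_cohort.cohort, ["HOXA1"])
        res = profile["results"]
        assert res.loc[0, "p_adj"] == pytest.approx(res.loc[0, "p_raw"])

    def test_absent_genes_reported_not_dropped_silently(self, planted_cohort):
        profile = gene_set_de_profile(planted_cohort.cohort, ["HOXA1", "NOT_A_GENE"])
        assert profile["n_absent"] == 1 and profile["absent"] == ["NOT_A_GENE"]

    def test_empty_intersection_rejected(self, planted_cohort):
        with pytest.raises(ValueError):
            gene_set_de_profile(planted_cohort.cohort, ["NOT_A_GENE"])


class TestSubtypeCompare:
    @staticmethod
    def _expr_and_clinical(shift=2.0, seed=0, n=60):
        rng = np.random.default_rng(seed)
        pos = np.clip(rng.normal(4 + shift, 1, size=(1, n)), 0, None)
        neg = np.clip(rng.normal(4, 1, size=(1, n)), 0, None)
        cols = [f"P{i}" for i in range(n)] + [f"N{i}" for i in range(n)]
        expr = ExpressionMatrix(
            pd.DataFrame(np.concatenate([pos, neg], axis=1), index=["HOXB13"], columns=cols)
        )
        clinical = pd.DataFrame(
            {
                "time": 100.0,
                "event": 1,
                "her2": ["positive"] * n + ["negative"] * n,
                "pr": ["negative"] * (2 * n),
                "er": ["negative"] * (2 * n),
            },
            index=pd.Index(cols, name="sample_id"),
        )
        return expr, clinical

    def test_planted_4fold_her2_shift_detected(self):
        expr, clinical = self._expr_and_clinical(shift=2.0)
        res = subtype_compare(expr, clinical, "her2")
        assert res.loc[0, "FC"] == pytest.approx(4.0, rel=0.15)
        assert res.loc[0, "call"] == "up"

    def test_triple_negative_grouping(self):
        expr, clinical = self._expr_and_clinical(shift=0.0)
        # her2-negative + pr/er negative = triple negative group
        res = subtype_compare(expr, clinical, "triple_negative")
        assert res.loc[0, "call"] == "none"

    def test_all_missing_statuses_rejected(self):
        expr, clinical = self._expr_and_clinical()
        clinical[["her2", "pr", "er"]] = "missing"
        with pytest.raises(ValueError, match="insufficient"):
            subtype_compare(expr, clinical, "her2")

    def test_null_comparison_rarely_calls(self):
        hits = 0
        for seed in range(30):
            expr, clinical = self._expr_and_clinical(shift=0.0, seed=seed)
            res = subtype_compare(expr, clinical, "her2", n_tests=39)
            hits += (res["call"] != "none").any()
        assert hits <= 1
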