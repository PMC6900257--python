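"""The trained scorer, the naive comparator, thresholds and group tests."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import rankdata

from hscscore import (
    ConfigurationError,
    CountMatrix,
    HscScorer,
    ScoreTable,
    ValidationError,
    compare_groups,
    fraction_above,
    naive_geneset_score,
    percentile_threshold,
    r2_score,
    score_cells,
    total_count_normalize,
    wilcoxon_rank_sum,
)
from hscscore.geneset import SignedGeneSet


class TestTrainScorer:
    def test_missing_gene_set_without_fallback_is_config_error(
        self, standard_training
    ):
        cm, st, _ = standard_training
        with pytest.raises(ConfigurationError):
            HscScorer(derive_gene_set=False).fit(cm, st)

    def test_final_mlp_fits_training_data_well(
        self, default_scorer, standard_training
    ):
        cm, st, _ = standard_training
        preds = default_scorer.predict(cm)
        assert r2_score(st.score, preds) >= 0.9

    def test_scoring_training_matrix_matches_model_predictions(
        self, default_scorer, standard_training
    ):
        cm, _, _ = standard_training
        a = default_scorer.predict(cm)
        b = score_cells(default_scorer, cm).score
        np.testing.assert_array_equal(a, b)

    def test_provenance_records_search_summary(self, default_scorer):
        prov = default_scorer.provenance_
        assert prov["n_training_cells"] == 100
        assert prov["test_r2"] == default_scorer.grid_result_.test_r2

    def test_score_table_unaligned_scores_rejected(self, standard_training):
        cm, st, _ = standard_training
        bad = ScoreTable(cell_ids=["nope"], score=[1.0])
        with pytest.raises(ValidationError):
            HscScorer(model_family="linear").fit(cm, bad)


class TestScoreCells:
    def test_rank_normalized_scorer_is_depth_invariant(self, standard_training):
        cm, st, _ = standard_training
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scorer = HscScorer(
                normalization="rank", model_family="linear", random_state=0
            ).fit(cm, st)
        scaled = CountMatrix(cm.counts * 10, cm.cell_ids, cm.gene_ids)
        np.testing.assert_allclose(
            scorer.predict(cm), scorer.predict(scaled), atol=1e-10
        )

    def test_missing_genes_zero_filled_with_warning(
        self, default_scorer, standard_training
    ):
        cm, _, _ = standard_training
        keep = [g for g in cm.gene_ids if g not in default_scorer.resolved_genes_[:5]]
        idx = cm.gene_indexer()
        sub = CountMatrix(
            cm.counts[:, [idx[g] for g in keep]], cm.cell_ids, keep
        )
        with pytest.warns(UserWarning, match="inserted as zeros"):
            out = default_scorer.predict(sub)
        assert out.shape == (cm.n_cells,)

    def test_mostly_missing_genes_refused(self, default_scorer, standard_training):
        cm, _, _ = standard_training
        keep = default_scorer.resolved_genes_[: len(default_scorer.resolved_genes_) // 3]
        idx = cm.gene_indexer()
        sub = CountMatrix(cm.counts[:, [idx[g] for g in keep]], cm.cell_ids, keep)
        with pytest.raises(ValidationError):
            default_scorer.predict(sub)

    def test_hsc_analogs_score_highest(self, default_scorer, mixture):
        cm, truth, labels = mixture
        table = score_cells(default_scorer, cm)
        la = np.array(labels)
        assert np.median(table.score[la == "HSC"]) > np.median(
            table.score[la != "HSC"]
        )

    def test_scoring_is_deterministic(self, default_scorer, mixture):
        cm, _, _ = mixture
        a = score_cells(default_scorer, cm)
        b = score_cells(default_scorer, cm)
        np.testing.assert_array_equal(a.score, b.score)


class TestNaiveGeneSetScore:
    def test_all_genes_equals_mean_normalized_expression(self, toy_counts):
        table = naive_geneset_score(toy_counts, toy_counts.gene_ids)
        t = float(np.median(toy_counts.counts.sum(axis=1)))
        expected = total_count_normalize(toy_counts.counts, t).mean(axis=1)
        np.testing.assert_allclose(table.score, expected)

    def test_zero_overlap_rejected(self, toy_counts):
        with pytest.raises(ValidationError):
            naive_geneset_score(toy_counts, ["absent1", "absent2"])

    def test_separates_groups_on_mixture(self, default_scorer, mixture):
        cm, _, labels = mixture
        table = naive_geneset_score(cm, default_scorer.gene_set_.positive_genes)
        la = np.array(labels)
        assert np.median(table.score[la == "HSC"]) > np.median(
            table.score[la != "HSC"]
        )


class TestPercentileThreshold:
    def test_interpolated_99th_of_1_to_100(self):
        st = ScoreTable([f"c{i}" for i in range(100)], np.arange(1.0, 101.0))
        thr = percentile_threshold(st, 99)
        assert thr == pytest.approx(99.01)
        assert fraction_above(st, thr) == pytest.approx(0.01)

    def test_median_of_three(self):
        st = ScoreTable(["a", "b", "c"], [1.0, 2.0, 3.0])
        assert percentile_threshold(st, 50) == 2.0

    def test_all_equal_scores_none_above(self):
        st = ScoreTable(["a", "b"], [5.0, 5.0])
        assert fraction_above(st, percentile_threshold(st, 99)) == 0.0

    def test_invalid_percentile_rejected(self):
        st = ScoreTable(["a"], [1.0])
        with pytest.raises(ValidationError):
            percentile_threshold(st, 100)


def enumeration_rank_sum_p(x, y):
    """Literal full enumeration over all assignments of pooled midranks."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n1)]
    sums = np.asarray(sums)
    p_le = np.mean(sums <= w_obs + 1e-9)
    p_ge = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_textbook_exact_case(self):
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], method="exact") == 1.0

    def test_exact_matches_full_enumeration_small_groups(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (5, 6), (6, 6)]:
            x = rng.integers(0, 6, n1).astype(float)  # ties likely
            y = rng.integers(0, 6, n2).astype(float)
            assert wilcoxon_rank_sum(x, y, method="exact") == pytest.approx(
                enumeration_rank_sum_p(x, y), abs=1e-12
            )

    def test_exact_and_asymptotic_agree_at_n12(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=12)
            y = rng.normal(0.5, 1, size=12)
            exact = wilcoxon_rank_sum(x, y, method="exact")
            approx = wilcoxon_rank_sum(x, y, method="asymptotic")
            assert abs(exact - approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


class TestCompareGroups:
    def test_reference_must_exist(self):
        st = ScoreTable(["a", "b"], [1.0, 2.0], ["x", "y"])
        with pytest.raises(ValidationError):
            compare_groups(st, "missing")

    def test_small_group_warns_and_reports_nan(self):
        st = ScoreTable(
            ["a", "b", "c", "d"], [1.0, 2.0, 3.0, 4.0], ["ref", "ref", "ref", "tiny"]
        )
        with pytest.warns(UserWarning):
            out = compare_groups(st, "ref")
        assert np.isnan(out.loc[out["group"] == "tiny", "p_value"]).all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(5, 1, 40)
        low = rng.normal(0, 1, 40)
        st = ScoreTable(
            [f"c{i}" for i in range(80)],
            np.concatenate([ref, low]),
            ["ref"] * 40 + ["low"] * 40,
        )
        out = compare_groups(st, "ref")
        assert out.loc[0, "p_value"] < 1e-6
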