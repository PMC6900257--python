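"""QC, feature selection, normalization, scaling, PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from hscscore import (
    ConfigurationError,
    CountMatrix,
    QCThresholds,
    ValidationError,
    apply_scaler,
    compute_target_total,
    find_hvgs,
    fit_pca,
    fit_scaler,
    project,
    qc_filter,
    rank_normalize,
    total_count_normalize,
)
from hscscore.synthetic import SyntheticConfig, generate_training_data


class TestQCFilter:
    def test_detected_genes_rule(self):
        rng = np.random.default_rng(0)
        counts = np.zeros((3, 2500), dtype=int)
        for i, n_detected in enumerate([1500, 900, 2000]):
            counts[i, :n_detected] = 1
        cm = CountMatrix(counts, ["a", "b", "c"], [f"g{j}" for j in range(2500)])
        kept, report = qc_filter(
            cm, QCThresholds(min_mapped_reads=None, min_detected_genes=1000,
                             max_spikein_fraction=None)
        )
        assert kept.cell_ids == ["a", "c"]
        rule_counts = dict(zip(report["rule"], report["n_cells"]))
        assert rule_counts["min_detected_genes"] == 1
        assert rule_counts["retained"] == 2

    def test_spikein_fraction_rule(self, toy_counts):
        # c3 has 30000/80000 = 0.375 spike-in fraction
        kept, _ = qc_filter(
            toy_counts,
            QCThresholds(min_mapped_reads=None, min_detected_genes=None,
                         max_spikein_fraction=0.30),
        )
        assert "c3" not in kept.cell_ids and len(kept.cell_ids) == 2

    def test_all_disabled_is_identity(self, toy_counts):
        kept, report = qc_filter(toy_counts, QCThresholds(None, None, None))
        assert kept.cell_ids == toy_counts.cell_ids
        np.testing.assert_array_equal(kept.counts, toy_counts.counts)

    def test_first_failing_rule_partitions(self, toy_counts):
        # c2 fails mapped reads (40k < 50k); c3 fails spike-ins; partition
        # must attribute each excluded cell to exactly one rule
        kept, report = qc_filter(toy_counts, QCThresholds(50_000, None, 0.30))
        rule_counts = dict(zip(report["rule"], report["n_cells"]))
        assert rule_counts["min_mapped_reads"] == 1
        assert rule_counts["max_spikein_fraction"] == 1
        assert sum(report["n_cells"]) == toy_counts.n_cells

    def test_enabled_rule_without_metadata_is_config_error(self):
        cm = CountMatrix(np.ones((2, 2), int), ["a", "b"], ["g1", "g2"])
        with pytest.raises(ConfigurationError):
            qc_filter(cm, QCThresholds(min_mapped_reads=1))


class TestRankNormalize:
    @pytest.mark.parametrize(
        "cell,expected",
        [
            ([0, 5, 5, 10], [1, 2.5, 2.5, 4]),
            ([7, 7, 7], [2, 2, 2]),  # all tied -> (n+1)/2
            ([0, 0, 0, 0], [2.5, 2.5, 2.5, 2.5]),
        ],
    )
    def test_average_ranks(self, cell, expected):
        out = rank_normalize(np.array([cell]))
        np.testing.assert_allclose(out[0], expected)

    def test_monotone_invariance(self):
        a = rank_normalize(np.array([[0, 5, 5, 10]]))
        b = rank_normalize(np.array([[0, 50, 50, 100]]))
        np.testing.assert_array_equal(a, b)

    @given(
        hnp.arrays(
            np.int64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=8),
            elements=hst.integers(0, 50),
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_row_sums_are_exact(self, counts):
        out = rank_normalize(counts)
        n = counts.shape[1]
        np.testing.assert_allclose(out.sum(axis=1), n * (n + 1) / 2)


class TestTotalCountNormalize:
    def test_target_total_median(self):
        counts = np.diag([5, 7, 100])
        cm = CountMatrix(counts, list("abc"), list("xyz"))
        assert compute_target_total(cm) == 7.0

    def test_target_total_single_cell_and_even(self):
        cm1 = CountMatrix(np.array([[3, 4]]), ["a"], ["g1", "g2"])
        assert compute_target_total(cm1) == 7.0
        cm2 = CountMatrix(np.array([[4, 0], [8, 0]]), ["a", "b"], ["g1", "g2"])
        assert compute_target_total(cm2) == 6.0  # mean of middle pair

    def test_forced_arithmetic(self):
        out = total_count_normalize(np.array([[1, 1, 2]]), target_total=8)
        np.testing.assert_allclose(out[0], np.log([3.0, 3.0, 5.0]))

    def test_prelog_row_sums_equal_target(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 20, size=(10, 30))
        x[3] = 0  # an empty cell stays zero
        with pytest.warns(UserWarning):
            out = total_count_normalize(x, 123.0)
        prelog = np.expm1(out)
        sums = prelog.sum(axis=1)
        np.testing.assert_allclose(np.delete(sums, 3), 123.0)
        np.testing.assert_array_equal(out[3], 0.0)

    def test_scale_invariance_per_cell(self):
        x = np.array([[1, 2, 3]])
        np.testing.assert_allclose(
            total_count_normalize(x, 10), total_count_normalize(2 * x, 10)
        )


class TestScaler:
    def test_standardizes_training_data(self):
        x = np.array([[1.0], [2.0], [3.0]])
        params = fit_scaler(x)
        out = apply_scaler(x, params)
        assert abs(out.mean()) < 1e-10
        np.testing.assert_allclose(out.std(), 1.0)

    def test_zero_variance_convention(self):
        x = np.full((4, 1), 7.0)
        params = fit_scaler(x)
        assert params.std[0] == 1.0 and params.zero_variance[0]
        np.testing.assert_array_equal(apply_scaler(x, params), 0.0)

    def test_frozen_stats_on_shifted_copy(self):
        x = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 8.0]])
        params = fit_scaler(x)
        shift = 1.5
        shifted = apply_scaler(x + shift, params)
        base = apply_scaler(x, params)
        np.testing.assert_allclose(
            shifted - base, np.tile(shift / params.std, (3, 1))
        )

    def test_feature_mismatch_rejected(self):
        params = fit_scaler(np.ones((3, 2)))
        with pytest.raises(ValidationError):
            apply_scaler(np.ones((3, 5)), params)


class TestPCA:
    def test_rank_one_data_fully_explained(self):
        t = np.linspace(0, 1, 9)[:, None]
        x = t @ np.array([[1.0, -2.0, 0.5]])
        pca = fit_pca(x, 1)
        total_var = x.var(axis=0, ddof=1).sum()
        assert pca.explained_variance[0] / total_var == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 4))
        pca = fit_pca(x, 4)
        proj = project(x, pca)
        recon = proj @ pca.component_matrix.T + pca.mean
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_deterministic_sign_and_refit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 6))
        p1, p2 = fit_pca(x, 3), fit_pca(x, 3)
        np.testing.assert_array_equal(p1.component_matrix, p2.component_matrix)
        k = p1.component_matrix.shape[1]
        top = p1.component_matrix[
            np.abs(p1.component_matrix).argmax(axis=0), np.arange(k)
        ]
        assert np.all(top > 0)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            fit_pca(np.ones((3, 5)), 3)  # k must be <= n_cells - 1


class TestHVGs:
    def test_planted_high_dispersion_genes_recovered(self):
        # 20 genes with 10x the baseline overdispersion among 500 baseline
        # genes: dispersion-based selection should find nearly all of them
        cfg = SyntheticConfig(
            n_cells=300, n_genes=500, n_pos_informative=0, n_neg_informative=0,
            baseline_mean_log_params=(1.0, 0.5), seed=7,
        )
        cm, _, _ = generate_training_data(cfg)
        rng = np.random.default_rng(7)
        counts = cm.counts.copy()
        planted = rng.choice(500, 20, replace=False)
        mean = np.maximum(counts[:, planted].mean(axis=0), 1.0)
        noisy = rng.negative_binomial(
            1 / 4.0, (1 / 4.0) / (1 / 4.0 + mean), size=(cm.n_cells, 20)
        )
        counts[:, planted] = noisy
        cm2 = CountMatrix(counts, cm.cell_ids, cm.gene_ids)
        hvgs = find_hvgs(cm2)
        planted_ids = {cm.gene_ids[j] for j in planted}
        assert len(planted_ids & set(hvgs)) >= 15

    def test_constant_genes_never_selected(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, size=(50, 30))
        counts[:, :10] = 3  # constant columns
        cm = CountMatrix(counts, [f"c{i}" for i in range(50)],
                         [f"g{j}" for j in range(30)])
        hvgs = find_hvgs(cm)
        assert not {f"g{j}" for j in range(10)} & set(hvgs)

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.negative_binomial(2, 0.2, size=(60, 40))
        ids = [f"g{j}" for j in range(40)]
        cm = CountMatrix(counts, [f"c{i}" for i in range(60)], ids)
        perm = rng.permutation(40)
        cm_perm = CountMatrix(counts[:, perm], cm.cell_ids, [ids[j] for j in perm])
        assert set(find_hvgs(cm)) == set(find_hvgs(cm_perm))

    def test_single_cell_rejected(self):
        cm = CountMatrix(np.ones((1, 5), int), ["c"], [f"g{j}" for j in range(5)])
        with pytest.raises(ValidationError):
            find_hvgs(cm)
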