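"""The user-facing HSC scorer.

:class:`HscScorer` is a scikit-learn-style regressor that learns, from a
score-annotated training count matrix, a frozen pipeline

    feature resolution -> normalization -> standardization -> (optional PCA)
    -> regression model

and applies it unchanged to new count matrices, yielding one continuous
HSC score per cell (unbounded; negative values are legal).  The default
configuration — signed-gene-set features, total-count normalization, an MLP
regressor, no PCA — is the combination that transfers best across
platforms.  Module-level functions (:func:`train_scorer`,
:func:`score_cells`, :func:`naive_geneset_score`, group statistics) are thin
wrappers around it.
"""

from __future__ import annotations

import warnings
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import model_train, preprocess
from .exceptions import ConfigurationError, ValidationError
from .geneset import SignedGeneSet, derive_signed_gene_set
from .matrix_io import CountMatrix, ScoreTable
from .preprocess import NormalizationSpec

__all__ = [
    "HscScorer",
    "train_scorer",
    "score_cells",
    "naive_geneset_score",
    "percentile_threshold",
    "fraction_above",
    "wilcoxon_rank_sum",
    "compare_groups",
]

FEATURE_MODES = ("all_protein_coding", "hvg", "signed_gene_set")
EXACT_WILCOXON_MAX_N = 12


class HscScorer(BaseEstimator, RegressorMixin):
    """Continuous HSC-similarity scorer for single-cell count data.

    Parameters
    ----------
    feature_mode
        ``"signed_gene_set"`` (default), ``"hvg"``, or
        ``"all_protein_coding"``.
    gene_set
        :class:`~hscscore.geneset.SignedGeneSet` for the signed mode.  When
        omitted and ``derive_gene_set`` is true, a set is derived from the
        training data by score correlation (BH-adjusted p < ``geneset_alpha``).
    protein_coding_genes
        Gene list for the ``all_protein_coding`` mode; ``None`` keeps every
        gene in the training matrix (appropriate when the matrix is already
        restricted to protein-coding genes).
    normalization
        ``"total_count"`` (default; target = training-median total over the
        resolved genes, then log1p) or ``"rank"`` (within-cell average
        ranks, depth-invariant).
    use_pca, n_components
        Whether to project standardized features onto the top principal
        components of the training split before regression.
    model_family, param_grid
        One of ``linear``, ``random_forest``, ``knn``, ``svr``, ``mlp``
        (default) with an optional grid overriding the family default.
    test_fraction
        Fraction of training cells held back to report generalization
        (default 0.25); the final model is refit on all cells.
    random_state
        Single seed driving the split, fold partition and stochastic fits.

    Attributes (after :meth:`fit`)
    ------------------------------
    resolved_genes_ : ordered feature list frozen at training time
    normalization_ : frozen :class:`NormalizationSpec`
    scaler_, pca_ : frozen transform statistics (``pca_`` may be ``None``)
    model_ : fitted regressor
    grid_result_ : CV table, best parameters and held-out ``test_r2``
    provenance_ : training metadata (cell count, seed, CV summary)
    """

    def __init__(
        self,
        feature_mode: str = "signed_gene_set",
        gene_set: SignedGeneSet | None = None,
        derive_gene_set: bool = True,
        geneset_alpha: float = 0.1,
        protein_coding_genes: list[str] | None = None,
        hvg_kwargs: dict | None = None,
        normalization: str = "total_count",
        use_pca: bool = False,
        n_components: int = 10,
        model_family: str = "mlp",
        param_grid: dict | None = None,
        test_fraction: float = 0.25,
        cv_folds: int = 5,
        random_state: int = 0,
    ) -> None:
        self.feature_mode = feature_mode
        self.gene_set = gene_set
        self.derive_gene_set = derive_gene_set
        self.geneset_alpha = geneset_alpha
        self.protein_coding_genes = protein_coding_genes
        self.hvg_kwargs = hvg_kwargs
        self.normalization = normalization
        self.use_pca = use_pca
        self.n_components = n_components
        self.model_family = model_family
        self.param_grid = param_grid
        self.test_fraction = test_fraction
        self.cv_folds = cv_folds
        self.random_state = random_state

    # -- training -----------------------------------------------------------

    def _resolve_features(self, cm: CountMatrix, y: np.ndarray) -> list[str]:
        present = set(cm.gene_ids)
        if self.feature_mode == "all_protein_coding":
            if self.protein_coding_genes is None:
                return list(cm.gene_ids)
            resolved = [g for g in cm.gene_ids if g in set(self.protein_coding_genes)]
        elif self.feature_mode == "hvg":
            resolved = preprocess.find_hvgs(cm, **(self.hvg_kwargs or {}))
        elif self.feature_mode == "signed_gene_set":
            gs = self.gene_set
            if gs is None:
                if not self.derive_gene_set:
                    raise ConfigurationError(
                        "feature_mode='signed_gene_set' needs a gene_set or "
                        "derive_gene_set=True"
                    )
                t_all = preprocess.compute_target_total(cm)
                log_all = preprocess.total_count_normalize(cm.counts, t_all)
                gs = derive_signed_gene_set(
                    log_all, cm.gene_ids, y, alpha=self.geneset_alpha
                )
            missing = [g for g in gs.all_genes if g not in present]
            if missing:
                warnings.warn(
                    f"{len(missing)} gene-set genes absent from training matrix "
                    f"(e.g. {missing[:5]}); dropped",
                    stacklevel=2,
                )
            self.gene_set_ = gs
            resolved = [g for g in gs.all_genes if g in present]
        else:
            raise ConfigurationError(
                f"unknown feature_mode {self.feature_mode!r}; choose from "
                f"{FEATURE_MODES}"
            )
        resolved = list(dict.fromkeys(resolved))
        if not resolved:
            raise ValidationError("feature resolution produced an empty gene list")
        return resolved

    def _normalize(self, counts: np.ndarray) -> np.ndarray:
        if self.normalization_.method == "rank":
            return preprocess.rank_normalize(counts)
        return preprocess.total_count_normalize(
            counts, self.normalization_.target_total
        )

    def fit(self, X: CountMatrix, y) -> "HscScorer":
        """Train the full pipeline on a count matrix and per-cell scores.

        ``y`` may be a :class:`ScoreTable` (matched to the matrix by cell id;
        must cover every cell) or a plain vector aligned with the rows.
        """
        if not isinstance(X, CountMatrix):
            raise ValidationError("HscScorer.fit expects a CountMatrix")
        if isinstance(y, ScoreTable):
            lookup = dict(zip(y.cell_ids, y.score))
            missing = [c for c in X.cell_ids if c not in lookup]
            if missing:
                raise ValidationError(
                    f"{len(missing)} training cells have no score (e.g. {missing[:5]})"
                )
            y = np.array([lookup[c] for c in X.cell_ids], dtype=float)
        else:
            y = np.asarray(y, dtype=float)
        if y.shape != (X.n_cells,):
            raise ValidationError("one score required per training cell")
        if not np.all(np.isfinite(y)):
            raise ValidationError("training scores must be finite")

        try:
            self.resolved_genes_ = self._resolve_features(X, y)
        except (ValidationError, ConfigurationError) as exc:
            raise type(exc)(f"feature resolution: {exc}") from exc
        if self.feature_mode != "signed_gene_set":
            self.gene_set_ = None

        idx = X.gene_indexer()
        counts = X.counts[:, [idx[g] for g in self.resolved_genes_]]

        if self.normalization == "total_count":
            t = float(np.median(counts.sum(axis=1)))
            if t <= 0:
                raise ValidationError(
                    "normalization: median total count over resolved genes is 0"
                )
            self.normalization_ = NormalizationSpec("total_count", t)
        elif self.normalization == "rank":
            self.normalization_ = NormalizationSpec("rank")
        else:
            raise ConfigurationError(
                f"unknown normalization {self.normalization!r}"
            )
        xn = self._normalize(counts)

        seed = int(self.random_state)
        train_idx, test_idx = model_train.split_train_test(
            X.n_cells, self.test_fraction, seed
        )
        # Scaler and optional PCA are fitted on the training split only and
        # frozen; the regression model alone is refit on all cells at the end.
        self.scaler_ = preprocess.fit_scaler(xn[train_idx])
        x_train = preprocess.apply_scaler(xn[train_idx], self.scaler_)
        x_test = preprocess.apply_scaler(xn[test_idx], self.scaler_)
        if self.use_pca:
            self.pca_ = preprocess.fit_pca(x_train, self.n_components)
            x_train = preprocess.project(x_train, self.pca_)
            x_test = preprocess.project(x_test, self.pca_)
        else:
            self.pca_ = None

        try:
            result = model_train.grid_search_cv(
                x_train,
                y[train_idx],
                self.model_family,
                param_grid=self.param_grid,
                k_folds=self.cv_folds,
                seed=seed,
            )
            eval_model = model_train.fit_final(
                x_train, y[train_idx], self.model_family, result.best_params, seed
            )
            result.test_r2 = model_train.r2_score(
                y[test_idx], eval_model.predict(x_test)
            )
            x_all = preprocess.apply_scaler(xn, self.scaler_)
            if self.pca_ is not None:
                x_all = preprocess.project(x_all, self.pca_)
            self.model_ = model_train.fit_final(
                x_all, y, self.model_family, result.best_params, seed
            )
        except (ValidationError, ConfigurationError) as exc:
            raise type(exc)(f"model training: {exc}") from exc
        self.best_params_ = result.best_params
        self.grid_result_ = result
        self.provenance_ = {
            "n_training_cells": X.n_cells,
            "n_features": len(self.resolved_genes_),
            "seed": seed,
            "mean_cv_r2": result.best_mean_cv_r2,
            "test_r2": result.test_r2,
        }
        self.n_features_in_ = len(self.resolved_genes_)
        return self

    # -- scoring ------------------------------------------------------------

    def _align_counts(self, cm: CountMatrix) -> np.ndarray:
        """Restrict a new matrix to the frozen feature list, zero-filling
        missing genes; refuse when more than half the features are absent."""
        idx = cm.gene_indexer()
        missing = [g for g in self.resolved_genes_ if g not in idx]
        if len(missing) > 0.5 * len(self.resolved_genes_):
            raise ValidationError(
                f"{len(missing)}/{len(self.resolved_genes_)} model genes missing "
                "from the dataset; refusing to score"
            )
        if missing:
            warnings.warn(
                f"{len(missing)} model genes absent, inserted as zeros: "
                f"{missing[:10]}{'...' if len(missing) > 10 else ''}",
                stacklevel=3,
            )
        out = np.zeros((cm.n_cells, len(self.resolved_genes_)), dtype=np.int64)
        for j, g in enumerate(self.resolved_genes_):
            if g in idx:
                out[:, j] = cm.counts[:, idx[g]]
        return out

    def predict(self, X: CountMatrix) -> np.ndarray:
        """Apply the frozen pipeline; returns one raw score per cell."""
        if not hasattr(self, "model_"):
            raise ValidationError("scorer is not fitted")
        if not isinstance(X, CountMatrix):
            raise ValidationError("HscScorer.predict expects a CountMatrix")
        if X.n_cells == 0:
            raise ValidationError("empty count matrix")
        counts = self._align_counts(X)
        xn = self._normalize(counts)
        xs = preprocess.apply_scaler(xn, self.scaler_)
        if self.pca_ is not None:
            xs = preprocess.project(xs, self.pca_)
        return np.asarray(self.model_.predict(xs), dtype=float)

    def score_table(self, X: CountMatrix) -> ScoreTable:
        """Like :meth:`predict`, but packaged with cell ids and any
        ``group_label`` metadata carried by the matrix."""
        scores = self.predict(X)
        group = None
        if X.cell_meta is not None and "group_label" in X.cell_meta.columns:
            group = X.cell_meta["group_label"].astype(str).tolist()
        return ScoreTable(cell_ids=list(X.cell_ids), score=scores, group_label=group)


def train_scorer(
    counts: CountMatrix, scores: ScoreTable, config: dict | None = None
):
    """Train an :class:`HscScorer` from a config mapping; returns
    ``(fitted scorer, grid search result)``."""
    scorer = HscScorer(**(config or {}))
    scorer.fit(counts, scores)
    return scorer, scorer.grid_result_


def score_cells(scorer: HscScorer, counts: CountMatrix) -> ScoreTable:
    return scorer.score_table(counts)


def naive_geneset_score(cm: CountMatrix, genes) -> ScoreTable:
    """Baseline comparator: per-cell mean of total-count-normalized log1p
    expression over the listed genes (no training, no per-gene weights).

    The normalization target is the dataset's own median per-cell total.
    """
    genes = list(genes)
    idx = cm.gene_indexer()
    cols = [idx[g] for g in genes if g in idx]
    if not cols:
        raise ValidationError("none of the listed genes are present")
    t = preprocess.compute_target_total(cm)
    log_all = preprocess.total_count_normalize(cm.counts, t)
    scores = log_all[:, cols].mean(axis=1)
    group = None
    if cm.cell_meta is not None and "group_label" in cm.cell_meta.columns:
        group = cm.cell_meta["group_label"].astype(str).tolist()
    return ScoreTable(cell_ids=list(cm.cell_ids), score=scores, group_label=group)


# ---------------------------------------------------------------------------
# thresholds and group statistics


def percentile_threshold(reference: ScoreTable, q: float) -> float:
    """Linear-interpolation percentile of the reference scores."""
    if not 0 < q < 100:
        raise ValidationError("q must lie in (0, 100)")
    if len(reference.score) == 0:
        raise ValidationError("empty reference score table")
    return float(np.percentile(reference.score, q))


def fraction_above(table: ScoreTable, threshold: float) -> float:
    """Proportion of cells scoring strictly above the threshold."""
    if len(table.score) == 0:
        raise ValidationError("empty score table")
    return float(np.mean(table.score > threshold))


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration.

    Counts, over all C(n1+n2, n1) assignments of the pooled (mid)ranks to
    the first group, how extreme the observed rank sum is.  Midranks are
    multiples of 1/2, so doubling them gives integers and the enumeration
    reduces to a subset-sum count (dynamic programming); ties are thereby
    handled exactly.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(int)
    w_obs = int(ranks2[:n1].sum())
    max_sum = int(ranks2.sum())
    # counts[j, s] = number of size-j subsets of the doubled ranks with sum s
    counts = np.zeros((n1 + 1, max_sum + 1))
    counts[0, 0] = 1.0
    for r in ranks2:
        for j in range(n1, 0, -1):  # descending: each rank used at most once
            counts[j, r:] += counts[j - 1, : max_sum + 1 - r]
    dist = counts[n1]
    total = comb(n1 + n2, n1)
    p_le = dist[: w_obs + 1].sum() / total
    p_ge = dist[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    ``method="auto"`` uses exact enumeration when both groups have at most
    12 observations and the tie-corrected normal approximation otherwise;
    ``"exact"`` and ``"asymptotic"`` force a branch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    if method == "auto":
        method = (
            "exact"
            if max(len(x), len(y)) <= EXACT_WILCOXON_MAX_N
            else "asymptotic"
        )
    if method == "exact":
        return _exact_rank_sum_p(x, y)
    if method == "asymptotic":
        return float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
    raise ValidationError(f"unknown method {method!r}")


def compare_groups(table: ScoreTable, reference_label: str) -> pd.DataFrame:
    """Wilcoxon rank-sum test of each labeled group against a reference.

    Returns one row per non-reference group with its size, median score and
    two-sided p-value; groups with fewer than 2 cells get ``NaN`` with a
    warning.
    """
    if table.group_label is None:
        raise ValidationError("score table carries no group labels")
    labels = np.asarray(table.group_label)
    if reference_label not in labels:
        raise ValidationError(f"reference group {reference_label!r} not found")
    ref = table.score[labels == reference_label]
    rows = []
    for group in dict.fromkeys(table.group_label):
        if group == reference_label:
            continue
        scores = table.score[labels == group]
        if len(scores) < 2 or len(ref) < 2:
            warnings.warn(
                f"group {group!r} vs {reference_label!r}: fewer than 2 cells; "
                "p undefined",
                stacklevel=2,
            )
            p = float("nan")
        else:
            p = wilcoxon_rank_sum(scores, ref)
        rows.append(
            {
                "group": group,
                "n_cells": int(len(scores)),
                "median_score": float(np.median(scores)) if len(scores) else float("nan"),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
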