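"""Deterministic front half of the scoring pipeline.

Covers per-cell quality control, the three feature-selection modes
(all protein-coding genes, highly variable genes, signed gene set), the two
normalization schemes (within-cell rank normalization and total-count
normalization to a fixed training-derived target), per-feature
standardization, and optional PCA.

All operations are pure functions of their inputs; the fit/apply pairs
(scaler, PCA) store their statistics in small dataclasses so a frozen
pipeline can be replayed bit-identically on new data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .matrix_io import CountMatrix

__all__ = [
    "QCThresholds",
    "NormalizationSpec",
    "ScalerParams",
    "PCAProjection",
    "qc_filter",
    "find_hvgs",
    "rank_normalize",
    "compute_target_total",
    "total_count_normalize",
    "fit_scaler",
    "apply_scaler",
    "fit_pca",
    "project",
]


# ---------------------------------------------------------------------------
# quality control


@dataclass
class QCThresholds:
    """Per-cell QC cutoffs; ``None`` disables a rule.

    Defaults follow common plate-based scRNA-seq practice: at least 50,000
    mapped reads, at least 1,000 detected genes, and at most 30% of reads
    mapping to ERCC spike-ins.  Rules needing metadata (mapped reads,
    spike-ins) can only be enabled when the matrix carries that metadata.
    """

    min_mapped_reads: int | None = 50_000
    min_detected_genes: int | None = 1_000
    max_spikein_fraction: float | None = 0.30

    def __post_init__(self) -> None:
        for name in ("min_mapped_reads", "min_detected_genes"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative")
        f = self.max_spikein_fraction
        if f is not None and not (0 <= f <= 1):
            raise ValidationError("max_spikein_fraction must lie in [0, 1]")


def qc_filter(
    cm: CountMatrix, thresholds: QCThresholds
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop cells failing QC; report exclusions by first failing rule.

    Detected genes are counted strictly above zero; the spike-in fraction is
    ``spikein_counts / total_mapped_reads``.  Rules are checked in the order
    mapped reads, detected genes, spike-in fraction, and each excluded cell
    is attributed to the first rule it fails.
    """
    n = cm.n_cells
    meta = cm.cell_meta

    def _meta_column(col: str, rule: str) -> np.ndarray:
        if meta is None or col not in meta.columns:
            raise ConfigurationError(
                f"QC rule {rule!r} enabled but cell_meta lacks column {col!r}"
            )
        return meta[col].to_numpy(dtype=float)

    failing = np.full(n, "", dtype=object)

    if thresholds.min_mapped_reads is not None:
        reads = _meta_column("total_mapped_reads", "min_mapped_reads")
        bad = reads < thresholds.min_mapped_reads
        failing[(failing == "") & bad] = "min_mapped_reads"
    if thresholds.min_detected_genes is not None:
        detected = (cm.counts > 0).sum(axis=1)
        bad = detected < thresholds.min_detected_genes
        failing[(failing == "") & bad] = "min_detected_genes"
    if thresholds.max_spikein_fraction is not None:
        spike = _meta_column("spikein_counts", "max_spikein_fraction")
        reads = _meta_column("total_mapped_reads", "max_spikein_fraction")
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(reads > 0, spike / reads, 0.0)
        bad = frac > thresholds.max_spikein_fraction
        failing[(failing == "") & bad] = "max_spikein_fraction"

    keep = np.flatnonzero(failing == "")
    rules = ["min_mapped_reads", "min_detected_genes", "max_spikein_fraction"]
    report = pd.DataFrame(
        {
            "rule": rules + ["retained"],
            "n_cells": [int((failing == r).sum()) for r in rules] + [len(keep)],
        }
    )
    return cm.subset_cells(keep), report


# ---------------------------------------------------------------------------
# feature selection


def find_hvgs(
    cm: CountMatrix,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
    min_disp: float = 0.5,
    n_bins: int = 20,
) -> list[str]:
    """Highly variable genes by mean-binned normalized dispersion.

    Counts are total-count normalized (to the median per-cell total) and
    log1p transformed; per-gene mean and dispersion are computed on these
    values, genes are binned by mean expression (``n_bins`` bins), dispersion
    is z-scored within each bin, and genes pass if their mean lies in
    ``(min_mean, max_mean)`` and the z-scored dispersion is at least
    ``min_disp``.  This is the standard dispersion-based selection as
    implemented in scanpy, which does the heavy lifting here.
    """
    if cm.n_cells < 2:
        raise ValidationError("need at least 2 cells for HVG selection")
    import anndata
    import scanpy as sc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adata = anndata.AnnData(
            X=cm.counts.astype(np.float64),
            obs=pd.DataFrame(index=cm.cell_ids),
            var=pd.DataFrame(index=cm.gene_ids),
        )
        sc.pp.normalize_total(adata)
        sc.pp.log1p(adata)
        sc.pp.highly_variable_genes(
            adata,
            flavor="seurat",
            min_mean=min_mean,
            max_mean=max_mean,
            min_disp=min_disp,
            n_bins=n_bins,
        )
    hvgs = [g for g, hv in zip(cm.gene_ids, adata.var["highly_variable"]) if hv]
    if not hvgs:
        warnings.warn("no highly variable genes found", stacklevel=2)
    return hvgs


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizationSpec:
    """Frozen normalization choice: ``rank`` or ``total_count`` (with the
    training-derived target total ``target_total``)."""

    method: str
    target_total: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("rank", "total_count"):
            raise ValidationError(f"unknown normalization method {self.method!r}")
        if self.method == "total_count":
            if self.target_total is None or self.target_total <= 0:
                raise ValidationError("total_count normalization needs target_total > 0")


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, CountMatrix):
        return x.counts.astype(float)
    return np.asarray(x, dtype=float)


def rank_normalize(counts) -> np.ndarray:
    """Replace each cell's values by their within-cell average ranks.

    Ranks are ascending and 1-based; ties receive the mean of the ranks they
    span, so each row sums to n(n+1)/2 exactly.  The output depends only on
    the within-cell ordering, making it invariant to any strictly increasing
    per-cell transform (sequencing-depth differences in particular).
    """
    x = _as_matrix(counts)
    if x.ndim != 2:
        raise ValidationError("expected a 2-D cells x genes matrix")
    return stats.rankdata(x, axis=1)


def compute_target_total(cm: CountMatrix, resolved_genes=None) -> float:
    """Median per-cell total count over the chosen gene set.

    This is the anchor T to which all cells (training and new data alike)
    are rescaled under total-count normalization.  Even cell counts use the
    mean-of-middle-pair median.
    """
    counts = cm.counts
    if resolved_genes is not None:
        idx = cm.gene_indexer()
        cols = [idx[g] for g in resolved_genes if g in idx]
        counts = counts[:, cols]
    totals = counts.sum(axis=1)
    t = float(np.median(totals))
    if t <= 0:
        raise ValidationError("median total count is 0 on the chosen gene set")
    return t


def total_count_normalize(counts, target_total: float) -> np.ndarray:
    """Scale each cell to total ``target_total``, then log1p.

    All-zero cells cannot be rescaled; they are left as zeros with a warning.
    """
    if target_total <= 0:
        raise ValidationError("target_total must be positive")
    x = _as_matrix(counts)
    totals = x.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} all-zero cells left unnormalized", stacklevel=2
        )
    scale = np.where(empty, 0.0, target_total / np.where(empty, 1.0, totals))
    return np.log1p(x * scale[:, None])


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScalerParams:
    """Per-feature standardization statistics fitted on training rows only.

    Zero-variance features keep std 1 (scaling them to exactly 0) so the
    model's input dimension never changes; they are flagged in
    ``zero_variance``.
    """

    mean: np.ndarray
    std: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.zero_variance is None:
            self.zero_variance = np.zeros_like(self.mean, dtype=bool)
        self.zero_variance = np.asarray(self.zero_variance, dtype=bool)
        if not (self.mean.shape == self.std.shape == self.zero_variance.shape):
            raise ValidationError("scaler statistic vectors must share a shape")
        if np.any(self.std <= 0):
            raise ValidationError("stored std entries must be positive")


def fit_scaler(x) -> ScalerParams:
    """Per-feature mean and population (ddof=0) standard deviation."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    zero = std == 0
    std = np.where(zero, 1.0, std)
    return ScalerParams(mean=mean, std=std, zero_variance=zero)


def apply_scaler(x, params: ScalerParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[1] != params.mean.shape[0]:
        raise ValidationError(
            f"matrix has {x.shape[1]} features, scaler expects {params.mean.shape[0]}"
        )
    return (x - params.mean) / params.std


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAProjection:
    """Top-k principal axes of the (centered) scaled training matrix.

    ``component_matrix`` is features x k with columns orthonormal; each
    column's sign is fixed so its largest-magnitude loading is positive,
    making repeated fits identical.
    """

    mean: np.ndarray
    component_matrix: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.component_matrix = np.asarray(self.component_matrix, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        k = self.component_matrix.shape[1]
        gram = self.component_matrix.T @ self.component_matrix
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValidationError("components are not orthonormal")

    @property
    def n_components(self) -> int:
        return self.component_matrix.shape[1]


def fit_pca(x, n_components: int) -> PCAProjection:
    """Exact SVD-based PCA of the centered input."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValidationError(
            f"n_components={n_components} must lie in [1, min(n_cells-1, n_features)"
            f"={min(n - 1, p)}]"
        )
    mean = x.mean(axis=0)
    _, s, vt = np.linalg.svd(x - mean, full_matrices=False)
    components = vt[:n_components].T  # features x k
    # deterministic sign: largest-magnitude loading positive
    flip = components[np.abs(components).argmax(axis=0), np.arange(n_components)] < 0
    components[:, flip] *= -1
    explained = (s[:n_components] ** 2) / (n - 1)
    return PCAProjection(
        mean=mean, component_matrix=components, explained_variance=explained
    )


def project(x, pca: PCAProjection) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[1] != pca.mean.shape[0]:
        raise ValidationError(
            f"matrix has {x.shape[1]} features, PCA expects {pca.mean.shape[0]}"
        )
    return (x - pca.mean) @ pca.component_matrix
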