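"""Signed marker gene sets correlated with a per-cell stemness score.

A *signed gene set* splits genes into a positive list (expression rises with
the HSC score; "MolO-like") and a negative list (expression falls with the
score; "NoMO-like").  Such sets are derived by correlating each gene's
normalized log expression with the score across cells and keeping genes whose
Benjamini–Hochberg-adjusted two-sided p-value falls below ``alpha``
(default 0.1), split by the sign of the correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

__all__ = ["SignedGeneSet", "bh_adjust", "derive_signed_gene_set"]


@dataclass
class SignedGeneSet:
    """Disjoint positive ("MolO-like") and negative ("NoMO-like") gene lists."""

    positive_genes: list[str] = field(default_factory=list)
    negative_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positive_genes = list(self.positive_genes)
        self.negative_genes = list(self.negative_genes)
        overlap = set(self.positive_genes) & set(self.negative_genes)
        if overlap:
            raise ValidationError(
                f"genes listed with both signs: {sorted(overlap)[:5]}"
            )
        for name, lst in (("positive", self.positive_genes),
                          ("negative", self.negative_genes)):
            if len(set(lst)) != len(lst):
                raise ValidationError(f"duplicate gene ids in {name} list")

    @property
    def all_genes(self) -> list[str]:
        """Positive genes followed by negative genes, order preserved."""
        return self.positive_genes + self.negative_genes

    def __len__(self) -> int:
        return len(self.positive_genes) + len(self.negative_genes)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.  Values outside [0, 1] raise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pearson_columns(x: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every column of ``x`` against ``s``, with two-sided
    t-distribution p-values on n - 2 df.  Constant columns get r = 0, p = 1."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    sc = s - s.mean()
    x_ss = np.einsum("ij,ij->j", xc, xc)
    s_ss = float(sc @ sc)
    denom = np.sqrt(x_ss * s_ss)
    constant = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(constant, 0.0, (xc.T @ sc) / np.where(constant, 1.0, denom))
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) == 1.0] = 0.0
    p[constant] = 1.0
    return r, p


def derive_signed_gene_set(
    log_expression: np.ndarray,
    gene_ids,
    scores,
    alpha: float = 0.1,
    method: str = "pearson",
) -> SignedGeneSet:
    """Derive a signed gene set from normalized log expression and scores.

    Parameters
    ----------
    log_expression
        Cells x genes matrix of normalized, log-transformed expression.
    gene_ids
        Column labels of ``log_expression``.
    scores
        Per-cell HSC score, one value per row.
    alpha
        Significance cutoff on the BH-adjusted two-sided p-value.
    method
        ``"pearson"`` (default) or ``"spearman"``.  Spearman is Pearson on
        within-column ranks of both expression and score.
    """
    x = np.asarray(log_expression, dtype=float)
    s = np.asarray(scores, dtype=float)
    gene_ids = list(gene_ids)
    if x.ndim != 2:
        raise ValidationError("expression must be a 2-D cells x genes matrix")
    if x.shape[0] != s.shape[0]:
        raise ValidationError(
            f"{x.shape[0]} cells in expression but {s.shape[0]} scores"
        )
    if x.shape[1] != len(gene_ids):
        raise ValidationError("gene_ids length does not match matrix columns")
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 cells to test correlations")
    if np.ptp(s) == 0:
        raise ValidationError("score vector is constant; correlations undefined")
    if method == "spearman":
        x = stats.rankdata(x, axis=0)
        s = stats.rankdata(s)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")

    r, p = _pearson_columns(x, s)
    p_adj = bh_adjust(p)
    selected = p_adj < alpha
    positive = [g for g, sel, ri in zip(gene_ids, selected, r) if sel and ri > 0]
    negative = [g for g, sel, ri in zip(gene_ids, selected, r) if sel and ri < 0]
    if not positive and not negative:
        warnings.warn(
            f"no genes passed adjusted p < {alpha}; returning empty gene set",
            stacklevel=2,
        )
    return SignedGeneSet(positive_genes=positive, negative_genes=negative)
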