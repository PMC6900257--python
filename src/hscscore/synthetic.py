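"""Score-annotated scRNA-seq-like count simulator.

The generator emulates the structure the scoring method assumes: each cell
carries a latent stemness score s in [0, 1]; a small set of genes is
positively loaded on the score (HSC-marker analogs) and another set
negatively loaded (differentiation-marker analogs); counts are overdispersed
(negative binomial) around lognormal baseline gene means scaled by a
lognormal per-cell library-size factor; and lower-depth platforms are
emulated by per-entry binomial thinning.

Formally, the expected count of gene g in cell i is

    lambda_ig = l_i * m_g * exp(+beta * s_i)   (positive-informative genes)
                l_i * m_g * exp(-beta * s_i)   (negative-informative genes)
                l_i * m_g                      (all other genes)

with l_i ~ LogNormal(libsize_log_params), m_g ~
LogNormal(baseline_mean_log_params), and counts drawn negative-binomially
with Var = mu + alpha * mu^2 (``nb_dispersion`` = alpha; alpha = 0 is
Poisson).  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .geneset import SignedGeneSet
from .matrix_io import CountMatrix, ScoreTable

__all__ = [
    "SyntheticConfig",
    "generate_training_data",
    "generate_population_mixture",
    "downsample_counts",
]


@dataclass
class SyntheticConfig:
    """Full parameterization of the simulator.

    Defaults describe the training regime the method is built for: on the
    order of a hundred deeply sequenced (plate-based) cells, a few hundred
    genes of which 30 rise and 30 fall with the latent score at log-slope
    1.5, lognormal baseline means with a long right tail (median ~7 counts),
    moderate overdispersion, and ~1.5-fold cell-to-cell depth variation.
    """

    n_cells: int = 100
    n_genes: int = 500
    n_pos_informative: int = 30
    n_neg_informative: int = 30
    effect_size: float = 1.5
    baseline_mean_log_params: tuple[float, float] = (2.0, 1.5)
    nb_dispersion: float = 0.4
    libsize_log_params: tuple[float, float] = (0.0, 0.4)
    score_distribution: tuple = ("uniform", (0.0, 1.0))
    group_structure: list[tuple[str, float, tuple[float, float]]] | None = None
    thinning_rate: float = 1.0
    seed: int = 0
    biology_seed: int = 1729

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValidationError("n_cells and n_genes must be positive")
        if self.n_pos_informative + self.n_neg_informative > self.n_genes:
            raise ValidationError("more informative genes than genes")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be positive")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be non-negative")
        if not 0 < self.thinning_rate <= 1:
            raise ValidationError("thinning_rate must lie in (0, 1]")


def _draw_scores(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    kind, params = cfg.score_distribution
    if kind == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size=n)
    if kind == "beta":
        a, b = params
        return rng.beta(a, b, size=n)
    raise ValidationError(f"unknown score distribution {kind!r}")


def _nb_counts(mean: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with Var = mu + alpha mu^2; alpha = 0 is Poisson."""
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _gene_params(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, SignedGeneSet]:
    """Gene-level parameters: baseline means, signed loadings, planted set.

    Drawn from ``biology_seed``, not ``seed``: which genes track the latent
    score (and how strongly each is expressed) is fixed biology, shared by
    every dataset simulated with the same biology seed, while ``seed``
    governs cells and sampling noise.  A scorer trained on one simulated
    dataset is therefore applicable to another.
    """
    rng = np.random.default_rng(cfg.biology_seed)
    mu_m, sd_m = cfg.baseline_mean_log_params
    baseline = rng.lognormal(mu_m, sd_m, size=cfg.n_genes)
    n_inf = cfg.n_pos_informative + cfg.n_neg_informative
    informative = rng.choice(cfg.n_genes, n_inf, replace=False)
    pos_idx = np.sort(informative[: cfg.n_pos_informative])
    neg_idx = np.sort(informative[cfg.n_pos_informative :])
    loading = np.zeros(cfg.n_genes)
    loading[pos_idx] = cfg.effect_size
    loading[neg_idx] = -cfg.effect_size
    gene_ids = _gene_names(cfg.n_genes)
    truth = SignedGeneSet(
        positive_genes=[gene_ids[j] for j in pos_idx],
        negative_genes=[gene_ids[j] for j in neg_idx],
    )
    return baseline, loading, truth


def _gene_names(n_genes: int) -> list[str]:
    width = len(str(n_genes - 1))
    return [f"gene{j:0{width}d}" for j in range(n_genes)]


def _cell_names(n_cells: int) -> list[str]:
    width = len(str(n_cells - 1))
    return [f"cell{i:0{width}d}" for i in range(n_cells)]


def _simulate_counts(
    cfg: SyntheticConfig, scores: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, SignedGeneSet]:
    baseline, loading, truth = _gene_params(cfg)
    mu_l, sd_l = cfg.libsize_log_params
    libsize = rng.lognormal(mu_l, sd_l, size=len(scores))
    lam = libsize[:, None] * baseline[None, :] * np.exp(np.outer(scores, loading))
    counts = _nb_counts(lam, cfg.nb_dispersion, rng).astype(np.int64)
    if cfg.thinning_rate < 1:
        counts = rng.binomial(counts, cfg.thinning_rate)
    return counts, truth


def generate_training_data(
    cfg: SyntheticConfig,
) -> tuple[CountMatrix, ScoreTable, SignedGeneSet]:
    """Simulate a score-annotated training set.

    Returns the count matrix, the per-cell latent scores as a
    :class:`ScoreTable`, and the planted signed gene set for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    scores = _draw_scores(cfg, cfg.n_cells, rng)
    counts, truth = _simulate_counts(cfg, scores, rng)
    cell_ids = _cell_names(cfg.n_cells)
    cm = CountMatrix(
        counts=counts, cell_ids=cell_ids, gene_ids=_gene_names(cfg.n_genes)
    )
    st = ScoreTable(cell_ids=cell_ids, score=scores)
    return cm, st, truth


def generate_population_mixture(
    cfg: SyntheticConfig,
) -> tuple[CountMatrix, ScoreTable, list[str]]:
    """Simulate a heterogeneous population with labeled groups.

    ``cfg.group_structure`` lists ``(label, fraction, (score_lo, score_hi))``;
    fractions must sum to 1.  Each group's latent scores are uniform on its
    range, so e.g. an HSC-analog group on (0.7, 1.0) against progenitor
    analogs on (0.0, 0.4) emulates a rare stem-cell population inside a
    progenitor landscape.
    """
    if not cfg.group_structure:
        raise ValidationError("group_structure is required for a mixture")
    fractions = [f for _, f, _ in cfg.group_structure]
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValidationError(f"group fractions sum to {sum(fractions)}, not 1")
    rng = np.random.default_rng(cfg.seed)

    sizes = [int(round(cfg.n_cells * f)) for f in fractions]
    sizes[-1] = cfg.n_cells - sum(sizes[:-1])  # rounding remainder to last group
    if min(sizes) < 0:
        raise ValidationError("group fractions produce a negative group size")
    labels: list[str] = []
    scores = np.empty(cfg.n_cells)
    start = 0
    for (label, _, (lo, hi)), size in zip(cfg.group_structure, sizes):
        scores[start : start + size] = rng.uniform(lo, hi, size=size)
        labels.extend([label] * size)
        start += size

    counts, _ = _simulate_counts(cfg, scores, rng)
    cell_ids = _cell_names(cfg.n_cells)
    meta = pd.DataFrame({"group_label": labels}, index=cell_ids)
    cm = CountMatrix(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=_gene_names(cfg.n_genes),
        cell_meta=meta,
    )
    st = ScoreTable(cell_ids=cell_ids, score=scores, group_label=labels)
    return cm, st, labels


def downsample_counts(cm: CountMatrix, rate: float, seed: int = 0) -> CountMatrix:
    """Binomially thin every count with retention probability ``rate``.

    This is exact reads-level subsampling: relative gene composition is
    preserved in expectation, emulating a lower-depth platform.
    """
    if not 0 < rate <= 1:
        raise ValidationError("rate must lie in (0, 1]")
    if rate == 1:
        counts = cm.counts.copy()
    else:
        counts = np.random.default_rng(seed).binomial(cm.counts, rate)
    return CountMatrix(
        counts=counts,
        cell_ids=list(cm.cell_ids),
        gene_ids=list(cm.gene_ids),
        cell_meta=cm.cell_meta.copy() if cm.cell_meta is not None else None,
    )
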