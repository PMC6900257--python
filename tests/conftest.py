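"""Shared fixtures: the standard synthetic training set, a trained default
scorer, and a labeled population mixture.  Everything is generated
programmatically and seeded."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hscscore import CountMatrix, HscScorer, ScoreTable
from hscscore.synthetic import SyntheticConfig, generate_population_mixture

# 5% HSC-analog cells (latent score 0.7-1.0) inside a progenitor landscape
MIXTURE_GROUPS = [
    ("HSC", 0.05, (0.7, 1.0)),
    ("MPP", 0.45, (0.0, 0.4)),
    ("progenitor", 0.50, (0.0, 0.4)),
]


@pytest.fixture(scope="session")
def standard_training():
    """The standard training fixture: 100 cells x 500 genes, 30 positive and
    30 negative informative genes at log-slope 1.5, seed 0."""
    from hscscore.synthetic import generate_training_data

    return generate_training_data(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_scorer(standard_training):
    """Default configuration trained on the standard fixture."""
    cm, st, _ = standard_training
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scorer = HscScorer(random_state=0).fit(cm, st)
    return scorer


@pytest.fixture(scope="session")
def mixture():
    """2,000-cell labeled mixture sharing the training biology."""
    cfg = SyntheticConfig(n_cells=2000, seed=1, group_structure=MIXTURE_GROUPS)
    return generate_population_mixture(cfg)


@pytest.fixture
def toy_counts():
    """Tiny hand-written matrix with QC metadata."""
    counts = np.array([[5, 0, 3], [1, 2, 0], [0, 0, 7]])
    meta = pd.DataFrame(
        {
            "total_mapped_reads": [60_000, 40_000, 80_000],
            "spikein_counts": [6_000, 2_000, 30_000],
        },
        index=["c1", "c2", "c3"],
    )
    return CountMatrix(
        counts=counts,
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["g1", "g2", "g3"],
        cell_meta=meta,
    )


@pytest.fixture
def toy_scores():
    return ScoreTable(cell_ids=["c1", "c2", "c3"], score=[0.1, -0.2, 0.9])
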