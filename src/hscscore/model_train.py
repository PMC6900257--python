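"""Regression model zoo, train/test split and cross-validated grid search.

Five model families are supported: ordinary linear regression, random
forest, k-nearest-neighbor regression, support vector regression (RBF), and
a multilayer perceptron.  Hyperparameters are selected by grid search with
k-fold cross-validation (default fivefold) on the training split, scored by
R-squared; the best combination is then refit.

Every source of randomness (the train/test shuffle, the fold partition,
stochastic model fits) is derived from one top-level seed: split seed =
seed, fold seed = seed + 1, model seed = seed + 2, all reduced mod 2^31.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "MODEL_FAMILIES",
    "default_param_grid",
    "make_model",
    "split_train_test",
    "r2_score",
    "GridSearchResult",
    "grid_search_cv",
    "fit_final",
]

_SEED_MOD = 2**31

# Default hyperparameter grids per family.  These reproduce the shape of a
# realistic small search rather than any particular published table; all are
# overridable through the ``param_grid`` argument/config.
_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "linear": {},
    "random_forest": {"n_estimators": [100, 500], "max_depth": [None, 10]},
    "knn": {"n_neighbors": [5, 10, 20], "weights": ["uniform", "distance"]},
    "svr": {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
    "mlp": {"hidden_layer_sizes": [(50,), (100,), (100, 50)], "alpha": [1e-4, 1e-2]},
}

MODEL_FAMILIES = tuple(_DEFAULT_GRIDS)


def default_param_grid(family: str) -> dict[str, list]:
    if family not in _DEFAULT_GRIDS:
        raise ConfigurationError(
            f"unknown model family {family!r}; choose from {MODEL_FAMILIES}"
        )
    return {k: list(v) for k, v in _DEFAULT_GRIDS[family].items()}


def make_model(family: str, params: dict | None = None, seed: int = 0):
    """Instantiate an unfitted regressor of the given family."""
    params = dict(params or {})
    model_seed = (seed + 2) % _SEED_MOD
    if family == "linear":
        est = LinearRegression()
    elif family == "random_forest":
        est = RandomForestRegressor(random_state=model_seed)
    elif family == "knn":
        est = KNeighborsRegressor()
    elif family == "svr":
        est = SVR()
    elif family == "mlp":
        # lbfgs: full-batch quasi-Newton, the reliable optimizer at the
        # ~100-cell training sizes this tool targets
        est = MLPRegressor(solver="lbfgs", max_iter=2000, random_state=model_seed)
    else:
        raise ConfigurationError(
            f"unknown model family {family!r}; choose from {MODEL_FAMILIES}"
        )
    if "hidden_layer_sizes" in params and isinstance(params["hidden_layer_sizes"], list):
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
    if params:
        est.set_params(**params)
    return est


def split_train_test(
    n_cells: int, test_fraction: float = 0.25, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split; |test| = round(n * test_fraction)."""
    if n_cells < 4:
        raise ValidationError("need at least 4 cells to split")
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must lie in (0, 1)")
    n_test = int(round(n_cells * test_fraction))
    n_test = min(max(n_test, 1), n_cells - 1)
    perm = np.random.default_rng(seed % _SEED_MOD).permutation(n_cells)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValidationError("y_true and y_pred must be equal-length vectors")
    if y_true.size < 2:
        raise ValidationError("need at least 2 observations")
    if np.ptp(y_true) == 0:
        raise ValidationError("R^2 undefined for constant y_true")
    return float(metrics.r2_score(y_true, y_pred))


@dataclass
class GridSearchResult:
    """Cross-validation outcome for one model family.

    ``table`` has one row per parameter combination with its per-fold R^2
    scores, mean and std; ``best_params`` maximizes the mean CV R^2 with
    ties broken by grid order.  ``test_r2`` is filled in by the trainer once
    the refit model is evaluated on the held-out split.
    """

    family: str
    table: list[dict] = field(default_factory=list)
    best_params: dict = field(default_factory=dict)
    best_mean_cv_r2: float = float("nan")
    test_r2: float | None = None

    def to_json(self) -> dict:
        return {
            "family": self.family,
            "table": self.table,
            "best_params": {k: _plain(v) for k, v in self.best_params.items()},
            "best_mean_cv_r2": self.best_mean_cv_r2,
            "test_r2": self.test_r2,
        }


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, np.generic):
        return v.item()
    return v


def grid_search_cv(
    x,
    y,
    family: str,
    param_grid: dict | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Grid search with seeded k-fold CV, scored by R^2.

    The fold partition is shared across all parameter combinations.  Ties on
    the mean CV score go to the first combination in grid order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if param_grid is None:
        param_grid = default_param_grid(family)
    if not isinstance(param_grid, dict):
        raise ConfigurationError("param_grid must be a dict of lists")
    if x.shape[0] // k_folds < 2:
        raise ValidationError(
            f"{x.shape[0]} samples in {k_folds} folds leaves folds below 2 samples"
        )
    grid = {
        k: [tuple(v) if isinstance(v, list) and k == "hidden_layer_sizes" else v
            for v in vals]
        for k, vals in param_grid.items()
    }
    folds = KFold(n_splits=k_folds, shuffle=True, random_state=(seed + 1) % _SEED_MOD)
    search = GridSearchCV(
        make_model(family, seed=seed),
        param_grid=grid,
        scoring="r2",
        cv=folds,
        refit=False,
        error_score="raise",
    )
    search.fit(x, y)
    cvr = search.cv_results_
    means = np.asarray(cvr["mean_test_score"])
    best = int(np.argmax(means))  # first max = first combination in grid order
    table = []
    for i, params in enumerate(cvr["params"]):
        fold_scores = [float(cvr[f"split{j}_test_score"][i]) for j in range(k_folds)]
        table.append(
            {
                "params": {k: _plain(v) for k, v in params.items()},
                "fold_r2": fold_scores,
                "mean_cv_r2": float(means[i]),
                "std_cv_r2": float(cvr["std_test_score"][i]),
            }
        )
    return GridSearchResult(
        family=family,
        table=table,
        best_params=dict(cvr["params"][best]),
        best_mean_cv_r2=float(means[best]),
    )


def fit_final(x, y, family: str, params: dict | None = None, seed: int = 0):
    """Refit the chosen combination on all provided rows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    model = make_model(family, params, seed=seed)
    try:
        model.fit(x, y)
    except Exception as exc:
        raise ValidationError(f"final {family} fit failed: {exc}") from exc
    return model
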