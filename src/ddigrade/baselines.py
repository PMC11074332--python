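"""Classical-ML comparison models on the same pair features.

Gaussian naive Bayes, decision tree and random forest (scikit-learn as
the estimator engine) are tuned by exhaustive grid search over the
published hyperparameter grids with stratified internal CV, then
benchmarked against the ensemble with the identical metric code path
(`evaluation`), so metric conventions cannot drift between models.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .evaluation import evaluate_predictions

logger = logging.getLogger(__name__)

#: prior emphasis orders follow the grade code order Green, Yellow, Amber, Red
GAUSSIAN_NB_GRID = {
    "priors": [(0.72, 0.076, 0.16, 0.044), (0.1, 0.1, 0.3, 0.5)],
    "var_smoothing": [1e-9, 1e-8, 1e-7],
}

DECISION_TREE_GRID = {
    "max_depth": [None, 5, 10, 20],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
    "max_features": ["sqrt", "log2"],
    "criterion": ["gini", "entropy"],
}

RANDOM_FOREST_GRID = {
    "n_estimators": [100, 200, 300],
    **DECISION_TREE_GRID,
    "bootstrap": [True, False],
}

BASELINE_GRIDS = {
    "gaussian_nb": GAUSSIAN_NB_GRID,
    "decision_tree": DECISION_TREE_GRID,
    "random_forest": RANDOM_FOREST_GRID,
}


def _make_estimator(name: str, seed: int):
    if name == "gaussian_nb":
        return GaussianNB()
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown baseline {name!r}; choose from {sorted(BASELINE_GRIDS)}")


def grid_size(grid: dict) -> int:
    size = 1
    for options in grid.values():
        size *= len(options)
    return size


def fit_baseline(
    name: str,
    X,
    y,
    grid: dict | None = None,
    cv_k: int = 5,
    seed: int = 0,
):
    """Exhaustive grid search with stratified internal CV; refits the best
    candidate on the full training data.

    Returns (fitted GridSearchCV, best parameter dict).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    grid = BASELINE_GRIDS[name] if grid is None else grid
    search = GridSearchCV(
        _make_estimator(name, seed),
        param_grid=grid,
        cv=StratifiedKFold(n_splits=cv_k, shuffle=True, random_state=seed),
        scoring="balanced_accuracy",
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    logger.info("%s grid search (%d candidates): best %s score %.3f",
                name, grid_size(grid), search.best_params_, search.best_score_)
    return search, search.best_params_


def benchmark(
    datasets: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    models: tuple[str, ...] = ("gaussian_nb", "decision_tree", "random_forest", "ensemble"),
    grids: dict[str, dict] | None = None,
    cv_k: int = 5,
    seed: int = 0,
    ensemble_kwargs: dict | None = None,
) -> list[dict]:
    """One benchmark row per (model x featurizer backend).

    `datasets` maps a backend label to (X_train, y_train, X_test, y_test)
    built over a drug-anchored split.  Metrics (weighted macro precision,
    sensitivity, specificity, F1, balanced accuracy) come from the
    evaluation module — the same code path as the ensemble's report.
    """
    from .ensemble import EnsembleDDIClassifier

    rows = []
    for backend, (X_train, y_train, X_test, y_test) in datasets.items():
        for model_name in models:
            if model_name == "ensemble":
                kwargs = {"network": "small"}
                kwargs.update(ensemble_kwargs or {})
                clf = EnsembleDDIClassifier(random_state=seed, **kwargs)
                clf.fit(X_train, y_train)
                pred = clf.predict(X_test)
                probs = clf.predict_proba(X_test)
                best_params = clf.get_params()
            else:
                grid = (grids or {}).get(model_name)
                search, best_params = fit_baseline(
                    model_name, X_train, y_train, grid=grid, cv_k=cv_k, seed=seed
                )
                clf = search.best_estimator_
                pred = clf.predict(X_test)
                probs = None
            report = evaluate_predictions(y_test, pred, probs)
            rows.append(
                {
                    "model": model_name,
                    "backend": backend,
                    "precision": report.weighted["precision"],
                    "sensitivity": report.weighted["sensitivity"],
                    "specificity": report.weighted["specificity"],
                    "f1": report.weighted["f1"],
                    "balanced_accuracy": report.weighted["balanced_accuracy"],
                    "macro_recall": report.macro_recall,
                    "best_params": {
                        k: v for k, v in best_params.items()
                        if not k.startswith("_")
                    } if model_name != "ensemble" else None,
                }
            )
    return rows
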