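"""Brain-age regressors trained on cognitively-unimpaired subjects only.

Three model families predict chronological age from the predictor columns of
a cohort: ordinary linear regression, random forests, and gradient-boosted
trees.  The tree families are tuned by a cross-validated grid search scored
by mean absolute error.  Training on CU rows only is a hard contract — the
regressor learns *normal* aging, and any upward shift of its predictions on
AD subjects is then attributable to accelerated atrophy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error
from sklearn.model_selection import KFold, ParameterGrid

from ._errors import ConfigurationError, ContractViolationError, SchemaError
from .cohort import Cohort, DIAG_CU

__all__ = ["ModelSpec", "FittedModel", "fit_model", "predict_age", "default_model_specs"]

FAMILIES = ("linear", "random_forest", "gradient_boosting")

#: Small, standard tuning grids for the tree ensembles.
DEFAULT_GRIDS = {
    "random_forest": {
        "n_estimators": [200, 500],
        "max_depth": [None, 10],
        "min_samples_leaf": [1, 5],
    },
    "gradient_boosting": {
        "n_estimators": [200, 500],
        "learning_rate": [0.05, 0.1],
        "max_depth": [3, 6],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameter search grid.

    ``grid`` maps hyperparameter names to candidate value lists; it is
    required (non-empty) for the tree families and ignored for ``linear``.
    A single-cell grid skips cross-validation and is fit directly.
    """

    family: str
    grid: dict | None = None
    grid_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )
        if self.grid_cv_folds < 2:
            raise ConfigurationError(
                f"grid_cv_folds must be >= 2, got {self.grid_cv_folds}"
            )
        if self.family != "linear":
            grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]
            if not grid or any(len(v) == 0 for v in grid.values()):
                raise ConfigurationError(
                    f"hyperparameter grid for family {self.family!r} must be nonempty"
                )

    def resolved_grid(self) -> dict:
        if self.family == "linear":
            return {}
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]


@dataclass(frozen=True)
class FittedModel:
    """A trained regressor plus the provenance needed to apply it safely."""

    family: str
    params: dict
    estimator: object
    n_train: int
    feature_manifest: tuple[str, ...]
    cv_scores: tuple = field(default_factory=tuple)  # ((params, mean MAE), ...)


def _make_estimator(family: str, params: dict, seed: int):
    if family == "linear":
        return LinearRegression()
    if family == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if family == "gradient_boosting":
        from xgboost import XGBRegressor

        return XGBRegressor(
            random_state=seed, n_jobs=1, verbosity=0, tree_method="hist", **params
        )
    raise ConfigurationError(f"unknown family {family!r}")  # pragma: no cover


def _grid_search(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    """Mean-MAE cross-validated search; ties keep the first grid cell."""
    cells = list(ParameterGrid(spec.resolved_grid()))
    if len(cells) == 1:
        return cells[0], ()
    kf = KFold(n_splits=spec.grid_cv_folds, shuffle=True, random_state=spec.seed)
    splits = list(kf.split(X))
    scores = []
    for params in cells:
        maes = []
        for tr, te in splits:
            est = _make_estimator(spec.family, params, spec.seed)
            est.fit(X[tr], y[tr])
            maes.append(mean_absolute_error(y[te], est.predict(X[te])))
        scores.append((params, float(np.mean(maes))))
    best = min(range(len(scores)), key=lambda i: scores[i][1])  # first-wins on ties
    return scores[best][0], tuple(scores)


def fit_model(spec: ModelSpec, train: Cohort) -> FittedModel:
    """Fit one regressor family on a CU-only training cohort.

    Raises
    ------
    ContractViolationError
        If any non-CU row is present in the training cohort.
    ConfigurationError
        If the training set is too small for the grid-search folds.
    """
    bad = train.data["diagnosis"] != DIAG_CU
    if bad.any():
        counts = train.data.loc[bad, "diagnosis"].value_counts().to_dict()
        raise ContractViolationError(
            f"training cohort must contain only CU rows; found {counts}"
        )
    n = len(train)
    if n < 2 * spec.grid_cv_folds:
        raise ConfigurationError(
            f"need at least {2 * spec.grid_cv_folds} training rows for "
            f"{spec.grid_cv_folds}-fold grid search, got {n}"
        )

    X = train.feature_matrix().to_numpy(dtype=float)
    y = train.data["age"].to_numpy(dtype=float)
    if spec.family == "linear":
        params, scores = {}, ()
    else:
        params, scores = _grid_search(spec, X, y)
    est = _make_estimator(spec.family, params, spec.seed)
    est.fit(X, y)
    return FittedModel(
        family=spec.family,
        params=dict(params),
        estimator=est,
        n_train=n,
        feature_manifest=tuple(train.predictors),
        cv_scores=scores,
    )


def predict_age(model: FittedModel, table: Cohort) -> pd.DataFrame:
    """Predict brain age for every row of ``table``.

    Returns a prediction set: one row per subject with ``age``,
    ``predicted_age`` and the diagnosis/apoe4/gender labels carried through
    unchanged.  The table's predictor columns must match the training
    manifest exactly (same names, same order).
    """
    if tuple(table.predictors) != model.feature_manifest:
        missing = [c for c in model.feature_manifest if c not in table.predictors]
        extra = [c for c in table.predictors if c not in model.feature_manifest]
        raise SchemaError(
            "predictor columns do not match the training manifest: "
            f"missing={missing} extra={extra} "
            f"(order must also match)"
        )
    out_cols = ["subject_id", "age", "diagnosis", "apoe4", "gender"]
    if len(table) == 0:
        return pd.DataFrame(columns=out_cols + ["predicted_age"])
    X = table.feature_matrix().to_numpy(dtype=float)
    preds = np.asarray(model.estimator.predict(X), dtype=float)
    out = table.data[out_cols].copy()
    out["predicted_age"] = preds
    return out


def default_model_specs(seed: int = 0, grid_cv_folds: int = 5) -> list[ModelSpec]:
    """The three-family comparison set with the default tuning grids."""
    return [
        ModelSpec("random_forest", grid_cv_folds=grid_cv_folds, seed=seed),
        ModelSpec("gradient_boosting", grid_cv_folds=grid_cv_folds, seed=seed),
        ModelSpec("linear", seed=seed),
    ]
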