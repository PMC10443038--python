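"""Gradient-boosted regression of normalised titer from sequence features.

The estimator wraps an XGBoost squared-error regressor behind the
scikit-learn estimator contract (``fit`` / ``predict`` / ``get_params``),
so it composes with sklearn pipelines and model selection.  Defaults are
the grid-search optimum used for the single-chain screens:

    colsample_bytree 0.7, learning_rate 0.05, max_depth 3,
    min_child_weight 1, n_estimators 100, subsample 1,
    early stopping after 5 rounds on a randomised 90/10 validation split.

Early stopping is monitored with RMSE: the objective is squared error and
log loss is undefined for unbounded regression, so a squared-error-
consistent validation metric is used (the metric is configurable).

Model quality is summarised by repeated K-fold cross-validated MAE
(5 splits x 10 repeats by default) and held-out R^2; per-row feature
attributions use XGBoost's native TreeSHAP, whose base value plus
attribution sum reproduces each prediction exactly (local accuracy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import RepeatedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted


class TiterRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted regressor for normalised expression titers.

    Parameters mirror the XGBoost names; ``test_fraction`` is the held-out
    validation share used both for early stopping and for the reported
    held-out metrics.  All randomness (split and booster) derives from
    ``random_state``.

    Attributes (after ``fit``)
    --------------------------
    booster_ : fitted ``xgb.XGBRegressor``
    feature_names_ : column order required by ``predict``
    train_index_, test_index_ : row labels of the 90/10 split
    train_r2_, test_r2_, train_mae_, test_mae_ : split metrics
    """

    def __init__(
        self,
        colsample_bytree: float = 0.7,
        learning_rate: float = 0.05,
        max_depth: int = 3,
        min_child_weight: float = 1,
        n_estimators: int = 100,
        subsample: float = 1.0,
        early_stopping_rounds: int = 5,
        eval_metric: str = "rmse",
        test_fraction: float = 0.10,
        random_state: int = 0,
    ) -> None:
        self.colsample_bytree = colsample_bytree
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.min_child_weight = min_child_weight
        self.n_estimators = n_estimators
        self.subsample = subsample
        self.early_stopping_rounds = early_stopping_rounds
        self.eval_metric = eval_metric
        self.test_fraction = test_fraction
        self.random_state = random_state

    def _make_booster(self, early_stopping: bool) -> xgb.XGBRegressor:
        return xgb.XGBRegressor(
            objective="reg:squarederror",
            colsample_bytree=self.colsample_bytree,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            min_child_weight=self.min_child_weight,
            n_estimators=self.n_estimators,
            subsample=self.subsample,
            eval_metric=self.eval_metric,
            early_stopping_rounds=self.early_stopping_rounds if early_stopping else None,
            random_state=self.random_state,
            n_jobs=1,
            tree_method="exact",
        )

    @staticmethod
    def _to_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])

    def fit(self, X, y) -> "TiterRegressor":
        """Fit on a feature table and min-max-normalised titers in [0, 1]."""
        X = self._to_frame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("feature/target length mismatch")
        if not np.all(np.isfinite(X.to_numpy())) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in features or targets")
        self.feature_names_ = list(X.columns)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=self.test_fraction, random_state=self.random_state
        )
        self.train_index_ = list(X_tr.index)
        self.test_index_ = list(X_te.index)
        self.booster_ = self._make_booster(early_stopping=True)
        self.booster_.fit(X_tr, y_tr, eval_set=[(X_te, y_te)], verbose=False)
        self.train_r2_ = float(r2_score(y_tr, self.booster_.predict(X_tr)))
        self.test_r2_ = float(r2_score(y_te, self.booster_.predict(X_te)))
        self.train_mae_ = float(mean_absolute_error(y_tr, self.booster_.predict(X_tr)))
        self.test_mae_ = float(mean_absolute_error(y_te, self.booster_.predict(X_te)))
        return self

    def _check_schema(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise ValueError(f"schema mismatch: missing feature column(s) {missing}")
        return X[self.feature_names_]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "booster_")
        X = self._check_schema(self._to_frame(X))
        return np.asarray(self.booster_.predict(X), dtype=float)

    def attribute(self, X) -> pd.DataFrame:
        """Per-row, per-feature TreeSHAP attributions plus a ``base_value`` column.

        For every row, ``base_value + sum(attributions)`` equals the model
        prediction (local accuracy).
        """
        check_is_fitted(self, "booster_")
        X = self._check_schema(self._to_frame(X))
        dmat = xgb.DMatrix(X, feature_names=self.feature_names_)
        # honour early stopping: contributions must cover the same trees predict uses
        best = getattr(self.booster_, "best_iteration", None)
        iteration_range = (0, best + 1) if best is not None else (0, 0)
        contribs = self.booster_.get_booster().predict(
            dmat, pred_contribs=True, iteration_range=iteration_range
        )
        out = pd.DataFrame(
            contribs, index=X.index, columns=self.feature_names_ + ["base_value"]
        )
        return out

    def save(self, directory: str | Path) -> None:
        """Serialise booster (native JSON) plus plain-text metadata."""
        check_is_fitted(self, "booster_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.booster_.get_booster().save_model(str(directory / "booster.json"))
        meta = {
            "params": self.get_params(),
            "feature_names": self.feature_names_,
            "train_index": self.train_index_,
            "test_index": self.test_index_,
            "metrics": {
                "train_r2": self.train_r2_,
                "test_r2": self.test_r2_,
                "train_mae": self.train_mae_,
                "test_mae": self.test_mae_,
            },
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TiterRegressor":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        est = cls(**meta["params"])
        est.feature_names_ = meta["feature_names"]
        est.train_index_ = meta["train_index"]
        est.test_index_ = meta["test_index"]
        for key, value in meta["metrics"].items():
            setattr(est, key + "_", value)
        est.booster_ = est._make_booster(early_stopping=False)
        booster = xgb.Booster()
        booster.load_model(str(directory / "booster.json"))
        est.booster_._Booster = booster
        return est


def cross_validate(
    X, y, estimator: TiterRegressor | None = None, cv_splits: int = 5, cv_repeats: int = 10
) -> tuple[float, float]:
    """Repeated K-fold CV mean and SD of per-fold MAE (fresh shuffle per repeat)."""
    est = estimator or TiterRegressor()
    X = TiterRegressor._to_frame(X)
    y = np.asarray(y, dtype=float)
    if len(X) < cv_splits:
        raise ValueError("too few rows for K-fold")
    rkf = RepeatedKFold(n_splits=cv_splits, n_repeats=cv_repeats, random_state=est.random_state)
    maes = []
    for train_idx, test_idx in rkf.split(X):
        booster = est._make_booster(early_stopping=False)
        booster.fit(X.iloc[train_idx], y[train_idx], verbose=False)
        maes.append(mean_absolute_error(y[test_idx], booster.predict(X.iloc[test_idx])))
    return float(np.mean(maes)), float(np.std(maes))


@dataclass(frozen=True)
class CandidatePanel:
    """Ranked candidate ids with a flag when the percentile pool was short."""

    ids: tuple[str, ...]
    threshold: float
    short_pool: bool = False


def select_candidates(predictions: dict[str, float], percentile: float = 95.0, k: int = 3) -> CandidatePanel:
    """Top-*k* ids from the upper *percentile* of predicted values.

    Candidates at or above the percentile threshold are ranked by predicted
    value (descending), ties broken lexicographically by id.  When fewer
    than *k* candidates clear the threshold, all of them are returned with
    ``short_pool=True``.
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile {percentile} outside (0, 100)")
    if k < 1:
        raise ValueError("k must be >= 1")
    values = np.array(list(predictions.values()), dtype=float)
    threshold = float(np.percentile(values, percentile))
    pool = [(pid, v) for pid, v in predictions.items() if v >= threshold]
    pool.sort(key=lambda t: (-t[1], t[0]))
    short = len(pool) < k
    return CandidatePanel(tuple(pid for pid, _ in pool[:k]), threshold, short)
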