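"""Regression contract shared by the whole package: forests, ridge, errors, ensembles.

Every model predicts one target gene's z-scored expression at t+1 from TF
expression at t.  Two estimator families are supported: random forests
(the non-linear workhorse) and ridge regression (the linear baseline).
Training-error vectors -- the per-pair absolute errors fed to the paired
significance gate -- are estimated out-of-bag for forests and by K-fold
cross-validation for ridge, so the gate compares honest generalization
errors rather than near-zero in-sample fits; a strict in-sample mode is
available.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, cross_val_predict

from tfsynergy.expression import LaggedDataset

__all__ = [
    "ModelConfig",
    "FittedModel",
    "fit_regressor",
    "rmse",
    "feature_importance_ranking",
    "ensemble_predict",
    "derive_seed",
]


def derive_seed(root: int, *keys) -> int:
    """Deterministically fan a root seed out to per-(target, method, stage) seeds."""
    tag = "|".join(str(k) for k in keys).encode()
    return (int(root) * 1_000_003 + zlib.crc32(tag)) % (2**31 - 1)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for one regression fit.

    error_mode
        "auto" estimates training error out-of-bag for forests and by
        ``cv_folds``-fold cross-validation for ridge; "oob", "cv" and
        "insample" force a specific estimator.
    """

    n_trees: int = 100
    max_depth: int | None = None
    ridge_alpha: float = 1.0
    error_mode: str = "auto"  # {"auto", "oob", "cv", "insample"}
    cv_folds: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.error_mode not in ("auto", "oob", "cv", "insample"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")


@dataclass
class FittedModel:
    """A trained predictor for one target gene over an ordered TF feature set."""

    model_kind: str  # {"forest", "ridge"}
    feature_ids: list[str]
    target_id: str
    importance: pd.Series
    train_error_vector: pd.Series  # per training pair, absolute error
    seed: int
    config: ModelConfig
    estimator: object = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Predict the target from TF expression rows (columns may be a superset)."""
        preds = self.estimator.predict(X[self.feature_ids].to_numpy())
        return pd.Series(preds, index=X.index, name=self.target_id)

    def test_errors(self, data: LaggedDataset) -> pd.Series:
        """Absolute prediction errors on the dataset's test pairs."""
        idx = data.test_index
        preds = self.predict(data.X.loc[idx])
        return (preds - data.Y.loc[idx, self.target_id]).abs()

    def test_rmse(self, data: LaggedDataset) -> float:
        idx = data.test_index
        return rmse(self.predict(data.X.loc[idx]).to_numpy(),
                    data.Y.loc[idx, self.target_id].to_numpy())

    def to_descriptor(self) -> dict:
        """A JSON-serializable descriptor sufficient to refit exactly."""
        return {
            "model_kind": self.model_kind,
            "feature_ids": list(self.feature_ids),
            "target_id": self.target_id,
            "seed": int(self.seed),
            "config": asdict(self.config),
            "importance": {k: float(v) for k, v in self.importance.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_descriptor(), indent=2))


def _oob_errors(est: RandomForestRegressor, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample out-of-bag absolute errors.

    A sample's OOB prediction averages the trees whose bootstrap missed it;
    the rare sample present in every bootstrap falls back to the in-sample
    forest prediction.
    """
    n = len(y)
    sums = np.zeros(n)
    counts = np.zeros(n)
    for tree, sampled in zip(est.estimators_, est.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        if oob.any():
            sums[oob] += tree.predict(X[oob])
            counts[oob] += 1
    preds = np.where(counts > 0, sums / np.maximum(counts, 1), est.predict(X))
    return np.abs(preds - y)


def fit_regressor(data: LaggedDataset, features, target: str, kind: str = "forest",
                  config: ModelConfig | None = None) -> FittedModel:
    """Fit a forest or ridge model predicting ``target`` at t+1 from ``features`` at t.

    Only training pairs are used.  The target gene is never its own
    predictor: if present among ``features`` it is dropped, and a sole
    self-feature is an error.  The fit is deterministic given
    ``config.seed``.
    """
    config = config or ModelConfig()
    features = list(features)
    if not features:
        raise ValueError("empty feature set")
    if features == [target]:
        raise ValueError(f"target {target!r} cannot be its own sole predictor")
    features = [f for f in features if f != target]
    missing = [f for f in features if f not in data.X.columns]
    if missing:
        raise KeyError(f"features absent from the lagged dataset: {missing}")
    if target not in data.Y.columns:
        raise KeyError(f"target {target!r} absent from the lagged dataset")

    train_idx = data.train_index
    if len(train_idx) < 2:
        raise ValueError(f"target {target!r} has fewer than 2 training pairs")
    Xtr = data.X.loc[train_idx, features].to_numpy()
    ytr = data.Y.loc[train_idx, target].to_numpy()

    if kind == "forest":
        est = RandomForestRegressor(
            n_estimators=config.n_trees, max_depth=config.max_depth,
            random_state=config.seed, bootstrap=True,
        )
        est.fit(Xtr, ytr)
        importance = pd.Series(est.feature_importances_, index=features)
        mode = "oob" if config.error_mode == "auto" else config.error_mode
    elif kind == "ridge":
        est = Ridge(alpha=config.ridge_alpha)
        est.fit(Xtr, ytr)
        importance = pd.Series(np.abs(est.coef_), index=features)
        mode = "cv" if config.error_mode in ("auto", "oob") else config.error_mode
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    if mode == "oob":
        errs = _oob_errors(est, Xtr, ytr)
    elif mode == "cv":
        folds = min(config.cv_folds, len(ytr))
        kf = KFold(n_splits=folds, shuffle=True, random_state=config.seed)
        preds = cross_val_predict(est.__class__(**est.get_params()), Xtr, ytr, cv=kf)
        errs = np.abs(preds - ytr)
    else:  # insample
        errs = np.abs(est.predict(Xtr) - ytr)

    return FittedModel(
        model_kind=kind,
        feature_ids=features,
        target_id=target,
        importance=importance,
        train_error_vector=pd.Series(errs, index=train_idx),
        seed=config.seed,
        config=config,
        estimator=est,
    )


def rmse(predictions, truths) -> float:
    """Root mean square error, sqrt(mean((pred - truth)^2))."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def feature_importance_ranking(model: FittedModel) -> list[str]:
    """Feature ids sorted by descending importance; ties break by ascending id."""
    imp = model.importance
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return order


def ensemble_predict(models: list[FittedModel], X: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of the member models' predictions (all for one target)."""
    if not models:
        raise ValueError("empty model list")
    targets = {m.target_id for m in models}
    if len(targets) > 1:
        raise ValueError(f"ensemble members disagree on the target: {sorted(targets)}")
    preds = pd.concat([m.predict(X) for m in models], axis=1)
    out = preds.mean(axis=1)
    out.name = models[0].target_id
    return out
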