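"""Machine-learning predictors with seeded inner-CV hyperparameter search.

Uniform wrappers over random forest (scikit-learn), the two gradient
boosting backends (LightGBM, XGBoost) and two convolutional network
variants (unphased 1-D codes, phased 0/1 gamete layers). Hyperparameters
are chosen by 3-fold inner cross-validation on the training fold,
maximizing the mean Pearson correlation between observed and predicted
values, with a seeded random sampler over declared search spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from ._cnn import CnnRegressor

__all__ = ["SearchSpace", "default_search_spaces", "fit_predict_ml", "ML_METHODS"]

# the lightgbm sklearn wrapper tracks feature names internally and warns on
# plain ndarray prediction; the arrays are positionally consistent here
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)

ML_METHODS = ("rf", "gbdt_a", "gbdt_b", "cnn1d", "cnn2d")


@dataclass
class SearchSpace:
    """Named hyperparameter ranges for one method.

    ``params`` maps name -> ("int"|"float"|"logfloat"|"choice", spec).
    """

    method: str
    params: dict
    budget: int = 10
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")

    def sample(self, rng: np.random.Generator) -> dict:
        out = {}
        for name, (kind, spec) in self.params.items():
            if kind == "int":
                out[name] = int(rng.integers(spec[0], spec[1] + 1))
            elif kind == "float":
                out[name] = float(rng.uniform(*spec))
            elif kind == "logfloat":
                out[name] = float(np.exp(rng.uniform(np.log(spec[0]), np.log(spec[1]))))
            elif kind == "choice":
                out[name] = spec[int(rng.integers(len(spec)))]
            else:
                raise ValueError(f"unknown parameter kind {kind!r}")
        return out

    def contains(self, point: dict) -> bool:
        for name, v in point.items():
            kind, spec = self.params[name]
            if kind == "choice":
                if v not in spec:
                    return False
            elif not (spec[0] <= v <= spec[1]):
                return False
        return True


def default_search_spaces(budget: int = 10, seed: int = 0) -> dict:
    """Declared search spaces: 8 tunable parameters per GBDT backend
    (including max depth and leaf/child complexity controls), 5 for the
    random forest and 7 common ones for the CNNs."""
    spaces = {
        "rf": SearchSpace("rf", {
            "n_estimators": ("int", (100, 500)),
            "max_depth": ("int", (2, 20)),
            "max_features": ("float", (0.1, 1.0)),
            "min_samples_split": ("int", (2, 10)),
            "min_samples_leaf": ("int", (1, 8)),
        }, budget=budget, seed=seed),
        "gbdt_a": SearchSpace("gbdt_a", {     # LightGBM
            "n_estimators": ("int", (50, 400)),
            "learning_rate": ("logfloat", (1e-3, 0.3)),
            "num_leaves": ("int", (4, 64)),
            "max_depth": ("int", (2, 12)),
            "min_child_samples": ("int", (2, 30)),
            "subsample": ("float", (0.5, 1.0)),
            "colsample_bytree": ("float", (0.3, 1.0)),
            "reg_lambda": ("logfloat", (1e-3, 10.0)),
        }, budget=budget, seed=seed),
        "gbdt_b": SearchSpace("gbdt_b", {     # XGBoost
            "n_estimators": ("int", (50, 400)),
            "learning_rate": ("logfloat", (1e-3, 0.3)),
            "max_depth": ("int", (2, 12)),
            "min_child_weight": ("float", (1.0, 10.0)),
            "subsample": ("float", (0.5, 1.0)),
            "colsample_bytree": ("float", (0.3, 1.0)),
            "reg_lambda": ("logfloat", (1e-3, 10.0)),
            "gamma": ("logfloat", (1e-4, 1.0)),
        }, budget=budget, seed=seed),
    }
    cnn_params = {
        "n_blocks": ("int", (1, 2)),
        "filters": ("int", (4, 16)),
        "kernel_width": ("int", (2, 5)),
        "dense_units": ("int", (8, 32)),
        "dropout": ("float", (0.0, 0.4)),
        "learning_rate": ("logfloat", (1e-4, 1e-2)),
        "batch_size": ("choice", (16, 32, 64)),
    }
    spaces["cnn1d"] = SearchSpace("cnn1d", dict(cnn_params), budget=budget, seed=seed)
    spaces["cnn2d"] = SearchSpace("cnn2d", dict(cnn_params), budget=budget, seed=seed)
    return spaces


_CNN_FULL_SET_LIMIT = 1024  # CNNs accept marker subsets only


def _build(method: str, params: dict, seed: int):
    if method == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if method == "gbdt_a":
        from lightgbm import LGBMRegressor
        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **params)
    if method == "gbdt_b":
        from xgboost import XGBRegressor
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **params)
    if method == "cnn1d":
        return CnnRegressor(phased=False, seed=seed, **params)
    if method == "cnn2d":
        return CnnRegressor(phased=True, seed=seed, **params)
    raise ValueError(f"unknown method {method!r}")


def _inner_cv_score(method, params, X, y, folds, seed):
    rs = []
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for fi, (tr, te) in enumerate(kf.split(X)):
        if np.std(y[tr]) == 0:
            warnings.warn("constant response in an inner fold; scoring it 0")
            rs.append(0.0)
            continue
        model = _build(method, params, seed + fi)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        if np.all(pred == pred[0]) or np.all(y[te] == y[te][0]):
            rs.append(0.0)
        else:
            rs.append(float(stats.pearsonr(y[te], pred)[0]))
    return float(np.mean(rs))


def fit_predict_ml(
    method: str,
    X_train,
    y_train,
    X_val,
    space: SearchSpace | None = None,
    seed: int = 0,
):
    """Inner-CV hyperparameter search, refit on the full training fold,
    predict the validation fold.

    CNN methods refuse inputs wider than the subset limit (they are meant
    for selected-SNP matrices, not the full marker set). Scaling is the
    caller's responsibility (training-fold parameters only).

    Returns ``(predictions, best_params, best_score)``.
    """
    if method not in ML_METHODS:
        raise ValueError(f"unknown method {method!r}")
    X_train = np.asarray(X_train, float)
    X_val = np.asarray(X_val, float)
    y_train = np.asarray(y_train, float)
    n_markers = X_train.shape[1]
    if method in ("cnn1d", "cnn2d") and n_markers > _CNN_FULL_SET_LIMIT:
        raise ValueError(
            f"{method} accepts at most {_CNN_FULL_SET_LIMIT} markers "
            "(use a GWAS-selected subset, not the full SNP set)"
        )
    if space is None:
        space = default_search_spaces()[method]
    rng = np.random.default_rng(seed + space.seed)

    # inner CV operates on flattened input; reshaped for the phased CNN
    if method == "cnn2d":
        if X_train.ndim != 3:
            raise ValueError("cnn2d expects (N, L, 2) phase input")
        flat_tr = X_train.reshape(len(X_train), -1)
    else:
        flat_tr = X_train

    best_params, best_score = None, -np.inf
    for _ in range(space.budget):
        params = space.sample(rng)
        if method == "cnn2d":
            score = _inner_cv_score_phased(params, X_train, y_train,
                                           space.inner_folds, seed)
        else:
            score = _inner_cv_score(method, params, flat_tr, y_train,
                                    space.inner_folds, seed)
        if score > best_score:
            best_score, best_params = score, params

    model = _build(method, best_params, seed)
    model.fit(X_train, y_train)
    preds = model.predict(X_val)
    return np.asarray(preds, float), best_params, best_score


def _inner_cv_score_phased(params, X, y, folds, seed):
    rs = []
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for fi, (tr, te) in enumerate(kf.split(X)):
        if np.std(y[tr]) == 0:
            warnings.warn("constant response in an inner fold; scoring it 0")
            rs.append(0.0)
            continue
        model = CnnRegressor(phased=True, seed=seed + fi, **params)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        if np.all(pred == pred[0]) or np.all(y[te] == y[te][0]):
            rs.append(0.0)
        else:
            rs.append(float(stats.pearsonr(y[te], pred)[0]))
    return float(np.mean(rs))
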