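"""Linear models with feature importance (LMFI) for genotype→phenotype inference.

Training is plaintext and per phenotype: a boosting model (gradient boosting
by default, AdaBoost or an absolute-correlation fallback as alternatives)
supplies nonnegative feature importances F; the genotype matrix columns are
scaled by F; a ridge-penalized linear (continuous phenotype) or logistic
(binary phenotype) regression is fitted on the scaled matrix; and the
importance is folded into the published weights, W = F ∘ M̂, so that secure
inference needs only the raw genotypes: score = X·W + w0.

Binary phenotypes use the standard sigmoid orientation — larger X·W + w0
means higher probability of class 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, AdaBoostRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge

from .errors import DegenerateModelError, ParameterError

CONTINUOUS = "continuous"
BINARY = "binary"

IMPORTANCE_METHODS = ("xgboost", "adaboost", "correlation")


@dataclass
class PhenotypeModel:
    kind: str                 # continuous | binary
    weights: np.ndarray       # folded weights W = F ∘ M̂, length n
    intercept: float
    importance: np.ndarray    # F, retained for audit
    name: str = ""


@dataclass
class LMFIModel:
    phenotypes: list[PhenotypeModel] = field(default_factory=list)
    importance_method: str = "xgboost"
    seed: int = 0

    @property
    def n_variants(self) -> int:
        return len(self.phenotypes[0].weights)

    def weight_matrix(self) -> np.ndarray:
        return np.column_stack([p.weights for p in self.phenotypes])

    def to_json(self) -> str:
        return json.dumps(
            {
                "importance_method": self.importance_method,
                "seed": self.seed,
                "phenotypes": [
                    {
                        "name": p.name,
                        "kind": p.kind,
                        "intercept": p.intercept,
                        "weights": p.weights.tolist(),
                        "importance": p.importance.tolist(),
                    }
                    for p in self.phenotypes
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LMFIModel":
        obj = json.loads(text)
        model = cls(importance_method=obj["importance_method"], seed=obj["seed"])
        for p in obj["phenotypes"]:
            model.phenotypes.append(
                PhenotypeModel(p["kind"], np.asarray(p["weights"], dtype=float),
                               float(p["intercept"]),
                               np.asarray(p["importance"], dtype=float),
                               p.get("name", "")))
        return model


def compute_importance(X: np.ndarray, y: np.ndarray, method: str = "xgboost",
                       seed: int = 0) -> np.ndarray:
    """Nonnegative per-variant importance of X's columns for target y."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] != len(y):
        raise ParameterError("X rows must match y length")
    if np.ptp(y) == 0:
        raise DegenerateModelError("constant target admits no importance")
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if method == "xgboost":
        import xgboost as xgb

        cls = xgb.XGBClassifier if binary else xgb.XGBRegressor
        booster = cls(n_estimators=60, max_depth=3, learning_rate=0.3,
                      random_state=seed, n_jobs=1, verbosity=0)
        booster.fit(X, y)
        F = booster.feature_importances_.astype(np.float64)
    elif method == "adaboost":
        cls = AdaBoostClassifier if binary else AdaBoostRegressor
        booster = cls(n_estimators=60, random_state=seed)
        booster.fit(X, y)
        F = booster.feature_importances_.astype(np.float64)
    elif method == "correlation":
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sx = np.sqrt((Xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.abs(Xc.T @ yc) / (sx * sy)
        F[~np.isfinite(F)] = 0.0  # constant columns carry no signal
    else:
        raise ParameterError(f"unknown importance method {method!r}; "
                             f"choose from {IMPORTANCE_METHODS}")
    return np.maximum(F, 0.0)


def fit_continuous(X: np.ndarray, y: np.ndarray, F: np.ndarray,
                   ridge: float | None = None) -> tuple[np.ndarray, float]:
    """Penalized least squares on X·diag(F); returns folded (W, w0)."""
    X, y, F, ridge = _check_fit_args(X, y, F, ridge)
    Xs = X * F
    if ridge == 0:
        reg = LinearRegression()
    else:
        reg = Ridge(alpha=ridge, solver="svd")
    reg.fit(Xs, y)
    return F * reg.coef_.ravel(), float(reg.intercept_)


def fit_binary(X: np.ndarray, y: np.ndarray, F: np.ndarray,
               ridge: float | None = None) -> tuple[np.ndarray, float]:
    """Penalized logistic regression on X·diag(F); returns folded (W, w0)."""
    X, y, F, ridge = _check_fit_args(X, y, F, ridge)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateModelError("binary fit needs both classes present")
    Xs = X * F
    # sklearn's C is the inverse penalty strength
    clf = LogisticRegression(C=1.0 / max(ridge, 1e-12), max_iter=2000)
    clf.fit(Xs, y.astype(int))
    return F * clf.coef_.ravel(), float(clf.intercept_[0])


def _check_fit_args(X, y, F, ridge):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    F = np.asarray(F, dtype=np.float64)
    if X.shape != (len(y), len(F)):
        raise ParameterError("shape mismatch between X, y and F")
    if not np.any(F):
        raise DegenerateModelError("all-zero importance yields a degenerate model")
    if ridge is None:
        ridge = 1e-3 * X.shape[0]
    if ridge < 0:
        raise ParameterError("ridge penalty must be nonnegative")
    return X, y, F, float(ridge)


def train(X: np.ndarray, Y: np.ndarray, kinds: list[str],
          method: str = "xgboost", ridge: float | None = None, seed: int = 0,
          names: list[str] | None = None) -> LMFIModel:
    """Fit one importance-scaled model per phenotype column of Y."""
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if Y.shape[0] != np.asarray(X).shape[0]:
        Y = Y.T
    if len(kinds) != Y.shape[1]:
        raise ParameterError("one kind per phenotype column required")
    model = LMFIModel(importance_method=method, seed=seed)
    for k, kind in enumerate(kinds):
        F = compute_importance(X, Y[:, k], method, seed=seed + k)
        if not np.any(F):  # importance degenerate: fall back to uniform scaling
            F = np.ones(np.asarray(X).shape[1])
        fit = fit_binary if kind == BINARY else fit_continuous
        W, w0 = fit(X, Y[:, k], F, ridge)
        name = names[k] if names else f"phenotype_{k}"
        model.phenotypes.append(PhenotypeModel(kind, W, w0, F, name))
    return model


def predict_plain(X: np.ndarray, model: LMFIModel,
                  sigmoid_binary: bool = False) -> np.ndarray:
    """Linear scores X·W_k + w0k per phenotype (m × K)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.n_variants:
        raise ParameterError("variant count mismatch")
    scores = X @ model.weight_matrix() + np.array(
        [p.intercept for p in model.phenotypes])
    if sigmoid_binary:
        for k, p in enumerate(model.phenotypes):
            if p.kind == BINARY:
                scores[:, k] = 1.0 / (1.0 + np.exp(-scores[:, k]))
    return scores
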