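"""Accuracy metrics: 1−NRMSE for continuous phenotypes, AUC for binary ones."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import ParameterError


def nrmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error normalized by the range of the *true* values."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.size < 2:
        raise ParameterError("nrmse needs two equal-length vectors, length ≥ 2")
    rng = np.max(y) - np.min(y)
    if rng == 0:
        raise ParameterError("constant true values: NRMSE denominator is zero")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)) / rng)


def auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties ½)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ParameterError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def phenotype_score(kind: str, y: np.ndarray, y_hat: np.ndarray) -> float:
    """S_k: 1−NRMSE for continuous phenotypes, AUC otherwise."""
    if kind == "continuous":
        return 1.0 - nrmse(y, y_hat)
    return auc(y, y_hat)


def average_score(scores: list[float]) -> float:
    """S̄: the arithmetic mean of the per-phenotype accuracies."""
    if not scores:
        raise ParameterError("empty score report")
    return float(np.mean(scores))
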