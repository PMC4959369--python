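"""Agreement statistics, cross-validation folds, and experiment orchestration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "kappa_index",
    "kappa_from_labels",
    "kfold_splits",
    "population_correlation",
    "run_experiment",
    "EvaluationError",
    "UndefinedKappaError",
]


class EvaluationError(ValueError):
    pass


class UndefinedKappaError(EvaluationError):
    """Chance agreement pc = 1: kappa has no defined value."""


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes); rows = true, cols = predicted

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def p0(self) -> float:
        """Observed agreement: proportion of coincidences."""
        return float(np.trace(self.counts)) / self.n

    @property
    def pc(self) -> float:
        """Chance agreement from the row/column margins."""
        rows = self.counts.sum(axis=1)
        cols = self.counts.sum(axis=0)
        return float((rows * cols).sum()) / self.n**2


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=int)
    predicted_labels = np.asarray(predicted_labels, dtype=int)
    if true_labels.shape != predicted_labels.shape or true_labels.size < 1:
        raise EvaluationError("label arrays must be equal-length and non-empty")
    for arr, name in ((true_labels, "true"), (predicted_labels, "predicted")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise EvaluationError(f"{name} labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (true_labels, predicted_labels), 1)
    return ConfusionMatrix(counts=counts)


def kappa_index(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p0 - pc) / (1 - pc)."""
    pc = cm.pc
    if pc >= 1.0:
        raise UndefinedKappaError("degenerate margins: pc = 1")
    return (cm.p0 - pc) / (1.0 - pc)


def kappa_from_labels(true_labels, predicted_labels, n_classes: int) -> float:
    return kappa_index(confusion_matrix(true_labels, predicted_labels, n_classes))


def kfold_splits(labels, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions.

    Validation folds are disjoint and cover every index exactly once.  If the
    smallest class has fewer than ``k`` members, ``k`` is lowered to that size
    (with a warning).
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise EvaluationError("k must be >= 2")
    class_sizes = np.bincount(labels)
    smallest = int(class_sizes[class_sizes > 0].min())
    if smallest < k:
        warnings.warn(
            f"smallest class has {smallest} members < k={k}; using k={smallest}",
            stacklevel=2,
        )
        k = smallest
        if k < 2:
            raise EvaluationError("a class has < 2 members; cannot cross-validate")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        fold_of[members] = np.arange(members.size) % k
    all_idx = np.arange(labels.size)
    splits = []
    for f in range(k):
        val = all_idx[fold_of == f]
        train = all_idx[fold_of != f]
        splits.append((train, val))
    return splits


def population_correlation(cost_pairs: np.ndarray) -> tuple[float, float]:
    """Pearson r (with two-sided t-based p) between the two cost columns."""
    cost_pairs = np.asarray(cost_pairs, dtype=float)
    if cost_pairs.ndim != 2 or cost_pairs.shape[1] != 2 or cost_pairs.shape[0] < 3:
        raise EvaluationError("need >= 3 (C1, C2) pairs")
    c1, c2 = cost_pairs[:, 0], cost_pairs[:, 1]
    if np.ptp(c1) == 0 or np.ptp(c2) == 0:
        raise EvaluationError("correlation undefined for constant costs")
    result = stats.pearsonr(c1, c2)
    return float(result.statistic), float(result.pvalue)


def run_experiment(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    test_labels: np.ndarray,
    method: str,
    n_repetitions: int = 15,
    seed: int = 0,
    **method_kwargs,
):
    """Repeated train/evaluate runs of one method; returns a summary dict.

    ``method`` is one of opt0 / opt1 / opt2 / opt3 / sr-lda / sr-svc.  Each
    repetition reseeds stochastic stages; the test-set kappa per repetition
    plus (mean, std, max) are reported, mirroring the per-method result-table
    layout.
    """
    from .pipeline import fit_predict_method  # local import avoids a cycle

    n_classes = int(np.unique(train_labels).size)
    kappas = []
    for rep in range(n_repetitions):
        predicted = fit_predict_method(
            train_features,
            train_labels,
            test_features,
            method=method,
            seed=seed + rep,
            **method_kwargs,
        )
        kappas.append(kappa_from_labels(test_labels, predicted, n_classes))
    kappas = np.asarray(kappas)
    return {
        "method": method,
        "kappa": kappas,
        "mean": float(kappas.mean()),
        "std": float(kappas.std(ddof=1)) if kappas.size > 1 else 0.0,
        "max": float(kappas.max()),
    }
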