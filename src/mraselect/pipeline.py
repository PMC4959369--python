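"""End-to-end train/predict orchestration for every method tag."""

from __future__ import annotations

import numpy as np

from .classifiers import build_ensemble, fit_lda, predict_ensemble, predict_lda
from .moo import CostEvaluator, Encoding, decode_genome, run_nsga2, select_operating_point
from .mra import flatten_features
from .sparse import predict_sr, train_sr

__all__ = ["fit_predict_method", "select_mask"]


def select_mask(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    tag: str,
    seed: int = 0,
    pop_size: int = 50,
    generations: int = 50,
    rule: str = "min_c2",
    shrinkage: "float | str" = "auto",
    n_folds: int = 10,
):
    """Run NSGA-II selection and return (mask, archive, history, evaluator)."""
    _, _, S, E, L = np.asarray(train_features).shape
    encoding = Encoding(tag, S, E, L)
    evaluator = CostEvaluator(
        train_features, train_labels, encoding, cv_seed=seed, n_folds=n_folds, shrinkage=shrinkage
    )
    archive, history = run_nsga2(evaluator, pop_size=pop_size, generations=generations, seed=seed)
    chosen = select_operating_point(archive, rule)
    return decode_genome(chosen.genome, encoding), archive, history, evaluator


def fit_predict_method(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    method: str,
    seed: int = 0,
    pop_size: int = 50,
    generations: int = 50,
    rule: str = "min_c2",
    shrinkage: "float | str" = "auto",
    **kwargs,
) -> np.ndarray:
    """Train one method on feature tensors and predict test labels.

    ``method``: opt0 | opt1 | opt2 | opt3 | sr-lda | sr-svc.  OPT0 is
    deterministic; the selection methods reseed NSGA-II with ``seed``; the
    sparse baselines reseed dictionary initialization.
    """
    method = method.lower()
    if method == "opt0":
        model = build_ensemble(train_features, train_labels, "OPT0", shrinkage=shrinkage)
        return predict_ensemble(model, test_features)
    if method in ("opt1", "opt2", "opt3"):
        mask, *_ = select_mask(
            train_features,
            train_labels,
            method.upper(),
            seed=seed,
            pop_size=pop_size,
            generations=generations,
            rule=rule,
            shrinkage=shrinkage,
            n_folds=kwargs.get("n_folds", 10),
        )
        if method == "opt1":
            cols = np.flatnonzero(mask)
            lda = fit_lda(flatten_features(train_features)[:, cols], train_labels, shrinkage)
            return predict_lda(lda, flatten_features(test_features)[:, cols])[0]
        model = build_ensemble(train_features, train_labels, method.upper(), mask, shrinkage)
        return predict_ensemble(model, test_features)
    if method in ("sr-lda", "sr-svc"):
        head = method.split("-")[1]
        sr = train_sr(
            train_features,
            train_labels,
            head=head,
            atoms_per_class=kwargs.get("atoms_per_class", 30),
            train_sparsity=kwargs.get("train_sparsity", 7),
            code_sparsity=kwargs.get("code_sparsity", 15),
            n_iterations=kwargs.get("n_iterations", 30),
            seed=seed,
        )
        return predict_sr(sr, test_features)
    raise ValueError(f"unknown method {method!r}")
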