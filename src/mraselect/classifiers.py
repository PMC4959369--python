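"""Shrinkage LDA, linear SVC, and majority-voting ensemble structures.

Three ensemble layouts over the (type, segment, electrode, level) feature
tensor:

* ``OPT0`` — the full bank: one LDA per (type, segment, level) member, each
  reading the E electrode features of its slice; all 2*S*L members vote.
* ``OPT2`` — same members as OPT0, but only those enabled by a binary member
  mask vote.
* ``OPT3`` — one LDA per segment, each reading a selectable subset of that
  segment's 2*E*L features.

The final label is the majority vote over member predictions; ties are broken
by the largest per-class score summed across members, then by the smallest
class index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import LinearSVC

__all__ = [
    "LDAModel",
    "SVCModel",
    "EnsembleModel",
    "fit_lda",
    "predict_lda",
    "fit_linear_svc",
    "predict_svc",
    "majority_vote",
    "build_ensemble",
    "predict_ensemble",
    "DegenerateSelectionError",
    "ClassifierError",
]


class ClassifierError(ValueError):
    pass


class DegenerateSelectionError(ClassifierError):
    """Selection decodes to an ensemble with zero members / zero features."""


@dataclass
class LDAModel:
    estimator: LinearDiscriminantAnalysis
    feature_indices: np.ndarray | None = None
    n_features: int = 0


@dataclass
class SVCModel:
    estimator: LinearSVC
    n_features: int = 0


def fit_lda(patterns: np.ndarray, labels: np.ndarray, shrinkage: "float | str" = "auto") -> LDAModel:
    """Multiclass LDA with shared shrunk covariance.

    ``shrinkage`` is the convex weight gamma of the scaled-identity target in
    Sigma = (1-gamma) * S_pooled + gamma * (tr(S_pooled)/p) * I, or "auto" for
    the Ledoit-Wolf analytic choice.  Shrinkage keeps the fit well-posed when
    n_features >= n_samples.
    """
    patterns = np.asarray(patterns, dtype=float)
    labels = np.asarray(labels)
    if patterns.ndim != 2 or patterns.shape[1] < 1:
        raise ClassifierError("patterns must be a (n_samples, n_features>=1) matrix")
    if np.unique(labels).size < 2:
        raise ClassifierError("fit_lda requires >= 2 classes in the training labels")
    est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    est.fit(patterns, labels)
    return LDAModel(estimator=est, n_features=patterns.shape[1])


def _class_scores(est, patterns: np.ndarray) -> np.ndarray:
    scores = est.decision_function(patterns)
    if scores.ndim == 1:  # binary: map to per-class columns
        scores = np.column_stack([-scores, scores])
    return scores


def predict_lda(model: LDAModel, patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (labels, per-class score matrix); argmax of scores == label."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[1] != model.n_features:
        raise ClassifierError(
            f"pattern width {patterns.shape[-1]} != model width {model.n_features}"
        )
    scores = _class_scores(model.estimator, patterns)
    labels = model.estimator.classes_[np.argmax(scores, axis=1)]
    return labels, scores


def fit_linear_svc(patterns: np.ndarray, labels: np.ndarray, C: float = 1.0) -> SVCModel:
    """One-vs-all linear max-margin classifier (liblinear, deterministic)."""
    patterns = np.asarray(patterns, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ClassifierError("fit_linear_svc requires >= 2 classes")
    est = LinearSVC(C=C, dual=False, tol=1e-6, random_state=0)
    est.fit(patterns, labels)
    return SVCModel(estimator=est, n_features=patterns.shape[1])


def predict_svc(model: SVCModel, patterns: np.ndarray) -> np.ndarray:
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[1] != model.n_features:
        raise ClassifierError("pattern width mismatch")
    return model.estimator.predict(patterns)


def majority_vote(member_labels: np.ndarray, member_scores: np.ndarray, n_classes: int) -> np.ndarray:
    """Majority vote across ensemble members for a batch of trials.

    Parameters
    ----------
    member_labels : (n_members, n_trials) int
    member_scores : (n_members, n_trials, n_classes)
    """
    member_labels = np.atleast_2d(np.asarray(member_labels))
    member_scores = np.asarray(member_scores, dtype=float)
    if member_labels.shape[0] < 1:
        raise ClassifierError("majority_vote needs >= 1 member")
    n_members, n_trials = member_labels.shape
    votes = np.zeros((n_trials, n_classes), dtype=int)
    for m in range(n_members):
        votes[np.arange(n_trials), member_labels[m]] += 1
    top = votes.max(axis=1)
    tied = votes == top[:, None]
    # Tie-break: summed per-class scores over members (restricted to tied
    # classes), then smallest class index (argmax picks the first maximum).
    summed = member_scores.sum(axis=0)
    summed = np.where(tied, summed, -np.inf)
    return np.argmax(summed, axis=1)


def _member_slices_opt0(S: int, L: int):
    """Member order for OPT0/OPT2: C-order ravel over (type, segment, level)."""
    return [(t, s, l) for t in range(2) for s in range(S) for l in range(L)]


@dataclass
class EnsembleModel:
    structure: str  # OPT0 | OPT2 | OPT3
    members: list  # list of (slice spec, LDAModel)
    n_classes: int
    shape: tuple[int, int, int, int]  # (2, S, E, L)

    @property
    def n_members(self) -> int:
        return len(self.members)


def _member_matrix(features: np.ndarray, spec) -> np.ndarray:
    """Extract a member's design matrix from (n, 2, S, E, L) features."""
    kind = spec[0]
    if kind == "tsl":  # OPT0/OPT2 member: electrodes of one (type, segment, level)
        _, t, s, l = spec
        return features[:, t, s, :, l]
    if kind == "seg":  # OPT3 member: masked flat slice of one segment
        _, s, mask = spec
        n = features.shape[0]
        # (type, E, L) -> (type, L, E) not needed: mask is defined on the
        # C-order ravel of (type, E, L)
        block = features[:, :, s, :, :].reshape(n, -1)
        return block[:, mask]
    raise ClassifierError(f"unknown member spec {spec!r}")


def build_ensemble(
    features: np.ndarray,
    labels: np.ndarray,
    structure: str,
    selection: np.ndarray | None = None,
    shrinkage: "float | str" = "auto",
) -> EnsembleModel:
    """Train a voting ensemble on (n_trials, 2, S, E, L) features.

    ``selection`` is ignored for OPT0 (all members active), a binary mask of
    length 2*S*L for OPT2, and an (S, 2*E*L) binary matrix for OPT3 (members
    whose row is all-zero are dropped).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 5 or features.shape[1] != 2:
        raise ClassifierError("features must be (n_trials, 2, S, E, L)")
    _, _, S, E, L = features.shape
    labels = np.asarray(labels)
    n_classes = int(np.unique(labels).size)
    structure = structure.upper()

    specs = []
    if structure in ("OPT0", "OPT2"):
        members = _member_slices_opt0(S, L)
        if structure == "OPT0":
            active = np.ones(len(members), dtype=bool)
        else:
            active = np.asarray(selection, dtype=bool).ravel()
            if active.size != len(members):
                raise ClassifierError(
                    f"OPT2 selection length {active.size} != 2*S*L = {len(members)}"
                )
        specs = [("tsl", t, s, l) for (t, s, l), a in zip(members, active) if a]
    elif structure == "OPT3":
        sel = np.asarray(selection, dtype=bool)
        if sel.shape != (S, 2 * E * L):
            raise ClassifierError(
                f"OPT3 selection shape {sel.shape} != (S={S}, 2*E*L={2 * E * L})"
            )
        specs = [("seg", s, sel[s].copy()) for s in range(S) if sel[s].any()]
    else:
        raise ClassifierError(f"unknown ensemble structure {structure!r}")

    if not specs:
        raise DegenerateSelectionError(f"{structure} selection yields zero members")

    trained = [(spec, fit_lda(_member_matrix(features, spec), labels, shrinkage)) for spec in specs]
    return EnsembleModel(
        structure=structure, members=trained, n_classes=n_classes, shape=(2, S, E, L)
    )


def predict_ensemble(model: EnsembleModel, features: np.ndarray) -> np.ndarray:
    """Per-trial majority vote over member LDA predictions."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 5 or features.shape[1:] != model.shape:
        raise ClassifierError(
            f"feature shape {features.shape[1:]} != training shape {model.shape}"
        )
    n = features.shape[0]
    labels = np.empty((model.n_members, n), dtype=int)
    scores = np.empty((model.n_members, n, model.n_classes))
    for m, (spec, lda) in enumerate(model.members):
        pred, sc = predict_lda(lda, _member_matrix(features, spec))
        labels[m] = pred
        # align score columns with global class ids
        full = np.full((n, model.n_classes), -np.inf)
        full[:, lda.estimator.classes_.astype(int)] = sc
        scores[m] = np.where(np.isfinite(full), full, 0.0)
    return majority_vote(labels, scores, model.n_classes)
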