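"""Sparse-representation baselines: K-SVD dictionaries, OMP, histogram pooling.

Per-segment reduced feature vectors (length 2*L*E) are the training samples.
One unit-atom dictionary is learned per class with K-SVD, the per-class
dictionaries are concatenated, every segment is sparse-coded against the
joint dictionary with orthogonal matching pursuit, the segment codes of a
trial are summed into a histogram vector, and a linear head (LDA or one-vs-all
SVC) classifies the histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import LDAModel, SVCModel, fit_lda, fit_linear_svc, predict_lda, predict_svc

__all__ = [
    "SparseDictionary",
    "SRModel",
    "build_segment_vectors",
    "ksvd_learn",
    "concat_dictionaries",
    "omp_encode",
    "encode_segments",
    "pool_histogram",
    "train_sr",
    "predict_sr",
    "SparseError",
]


class SparseError(ValueError):
    pass


def build_segment_vectors(features: np.ndarray) -> np.ndarray:
    """(n_trials, 2, S, E, L) feature tensors -> (n_trials, S, 2*L*E) vectors.

    Component ordering is type-major, then level, then electrode:
    index = (type * L + level) * E + electrode.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 5 or features.shape[1] != 2:
        raise SparseError("features must be (n_trials, 2, S, E, L)")
    n, _, S, E, L = features.shape
    # (n, 2, S, E, L) -> (n, S, 2, L, E) -> flatten the last three axes
    return features.transpose(0, 2, 1, 4, 3).reshape(n, S, 2 * L * E)


def scatter_segment_vector(vector: np.ndarray, n_electrodes: int, n_levels: int) -> np.ndarray:
    """Inverse ordering: length-2*L*E vector -> (2, E, L) tensor slice."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != 2 * n_levels * n_electrodes:
        raise SparseError("segment vector length mismatch")
    return vector.reshape(2, n_levels, n_electrodes).transpose(0, 2, 1)


def omp_encode(vector: np.ndarray, dictionary: np.ndarray, max_nonzero: int, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal matching pursuit against unit-norm atoms.

    Greedily selects the atom most correlated with the residual and refits the
    coefficients of the active set by least squares at every step; stops after
    ``max_nonzero`` atoms or when the residual norm drops below ``tol``.  A
    zero input yields the all-zero code.
    """
    y = np.asarray(vector, dtype=float)
    D = np.asarray(dictionary, dtype=float)
    if max_nonzero < 1:
        raise SparseError("max_nonzero must be >= 1")
    if y.size != D.shape[0]:
        raise SparseError(f"vector length {y.size} != atom length {D.shape[0]}")
    code = np.zeros(D.shape[1])
    residual = y.copy()
    support: list[int] = []
    for _ in range(min(max_nonzero, D.shape[1])):
        if np.linalg.norm(residual) < tol:
            break
        correlations = np.abs(D.T @ residual)
        correlations[support] = -1.0
        atom = int(np.argmax(correlations))
        support.append(atom)
        coeffs, *_ = np.linalg.lstsq(D[:, support], y, rcond=None)
        residual = y - D[:, support] @ coeffs
    if support:
        code[support] = coeffs
    return code


def _omp_batch(Y: np.ndarray, D: np.ndarray, max_nonzero: int) -> np.ndarray:
    return np.stack([omp_encode(y, D, max_nonzero) for y in Y])


def _normalize_atoms(D: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(D, axis=0)
    norms[norms == 0] = 1.0
    return D / norms


def ksvd_learn(
    vectors: np.ndarray,
    n_atoms: int = 30,
    train_sparsity: int = 7,
    n_iterations: int = 30,
    seed: int = 0,
    return_history: bool = False,
):
    """Learn a unit-atom dictionary by K-SVD.

    Alternates OMP sparse coding (``train_sparsity`` nonzeros) with
    atom-by-atom rank-1 SVD updates; atoms that no sample uses are replaced by
    the worst-reconstructed training vector.  The procedure is elitist: the
    incumbent is the best dictionary measured so far (sum of squared OMP
    residuals at the training sparsity), so the recorded objective is
    non-increasing and the returned dictionary attains its final value, even
    though individual coding passes may transiently regress.

    Parameters
    ----------
    vectors : (n_samples, dim) training matrix, n_samples >= n_atoms.
    return_history : also return the per-iteration incumbent objective.
    """
    Y = np.asarray(vectors, dtype=float).T  # (dim, n_samples)
    dim, n_samples = Y.shape
    if n_samples < n_atoms:
        raise SparseError(f"need >= {n_atoms} training vectors, got {n_samples}")
    rng = np.random.default_rng(seed)
    D = _normalize_atoms(Y[:, rng.choice(n_samples, size=n_atoms, replace=False)].copy())
    if n_iterations == 0:
        return (D, []) if return_history else D
    best_err = np.inf
    best_D = D.copy()
    history: list[float] = []
    for _ in range(n_iterations):
        X = _omp_batch(Y.T, D, train_sparsity).T  # (n_atoms, n_samples)
        err = float(np.linalg.norm(Y - D @ X) ** 2)
        if err < best_err:
            best_err, best_D = err, D.copy()
        history.append(best_err)
        residual_norms = np.linalg.norm(Y - D @ X, axis=0)
        for j in range(n_atoms):
            users = np.flatnonzero(X[j])
            if users.size == 0:
                worst = int(np.argmax(residual_norms))
                atom = Y[:, worst]
                norm = np.linalg.norm(atom)
                D[:, j] = atom / norm if norm > 0 else atom
                continue
            X[j, users] = 0.0
            E = Y[:, users] - D @ X[:, users]
            U, s, Vt = np.linalg.svd(E, full_matrices=False)
            D[:, j] = U[:, 0]
            X[j, users] = s[0] * Vt[0]
    # score the final atom update too
    X = _omp_batch(Y.T, D, train_sparsity).T
    err = float(np.linalg.norm(Y - D @ X) ** 2)
    if err < best_err:
        best_err, best_D = err, D
    history.append(best_err)
    return (best_D, history) if return_history else best_D


@dataclass
class SparseDictionary:
    """Concatenated per-class dictionaries with unit-norm atoms."""

    atoms: np.ndarray  # (dim, n_atoms)
    class_ranges: list[tuple[int, int]]  # half-open column range per class

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.atoms, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise SparseError("dictionary atoms must be unit-norm")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]


def concat_dictionaries(per_class: list[np.ndarray]) -> SparseDictionary:
    """Column-wise concatenation preserving per-class atom index ranges."""
    if not per_class:
        raise SparseError("no dictionaries to concatenate")
    dim = per_class[0].shape[0]
    ranges = []
    start = 0
    for D in per_class:
        if D.shape[0] != dim:
            raise SparseError("dictionary row dimensions differ")
        ranges.append((start, start + D.shape[1]))
        start += D.shape[1]
    return SparseDictionary(atoms=np.concatenate(per_class, axis=1), class_ranges=ranges)


def encode_segments(
    segment_vectors: np.ndarray, dictionary: SparseDictionary, max_nonzero: int = 15
) -> np.ndarray:
    """OMP-code every (trial, segment) vector: (n, S, dim) -> (n, S, n_atoms)."""
    V = np.asarray(segment_vectors, dtype=float)
    n, S, _ = V.shape
    codes = np.empty((n, S, dictionary.n_atoms))
    for i in range(n):
        for s in range(S):
            codes[i, s] = omp_encode(V[i, s], dictionary.atoms, max_nonzero)
    return codes


def pool_histogram(codes: np.ndarray, absolute: bool = False) -> np.ndarray:
    """Sum segment codes into one per-trial histogram vector.

    ``codes`` is (S, n_atoms) for one trial or (n, S, n_atoms) for a batch;
    signed sum by default, absolute-value sum when ``absolute``.
    """
    codes = np.asarray(codes, dtype=float)
    if codes.shape[-2] < 1:
        raise SparseError("no segment codes to pool")
    if absolute:
        codes = np.abs(codes)
    return codes.sum(axis=-2)


@dataclass
class SRModel:
    dictionary: SparseDictionary
    head: "LDAModel | SVCModel"
    head_kind: str  # "lda" | "svc"
    max_nonzero: int
    shape: tuple[int, int]  # (E, L) for segment-vector reconstruction checks


def train_sr(
    train_features: np.ndarray,
    labels: np.ndarray,
    head: str = "lda",
    atoms_per_class: int = 30,
    train_sparsity: int = 7,
    code_sparsity: int = 15,
    n_iterations: int = 30,
    seed: int = 0,
) -> SRModel:
    """Fit the full sparse-representation pipeline on training feature tensors."""
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise SparseError("train_sr requires >= 2 classes")
    vectors = build_segment_vectors(train_features)
    per_class = []
    for cls in classes:
        samples = vectors[labels == cls].reshape(-1, vectors.shape[-1])
        per_class.append(
            ksvd_learn(samples, atoms_per_class, train_sparsity, n_iterations, seed=seed + int(cls))
        )
    dictionary = concat_dictionaries(per_class)
    codes = encode_segments(vectors, dictionary, code_sparsity)
    histograms = pool_histogram(codes)
    if head == "lda":
        model = fit_lda(histograms, labels)
    elif head == "svc":
        model = fit_linear_svc(histograms, labels)
    else:
        raise SparseError(f"unknown head {head!r}")
    E, L = train_features.shape[3], train_features.shape[4]
    return SRModel(
        dictionary=dictionary,
        head=model,
        head_kind=head,
        max_nonzero=code_sparsity,
        shape=(E, L),
    )


def predict_sr(model: SRModel, features: np.ndarray) -> np.ndarray:
    """Encode with the frozen dictionary and classify the pooled histograms."""
    vectors = build_segment_vectors(features)
    codes = encode_segments(vectors, model.dictionary, model.max_nonzero)
    histograms = pool_histogram(codes)
    if model.head_kind == "lda":
        return predict_lda(model.head, histograms)[0]
    return predict_svc(model.head, histograms)


def compute_histograms(
    features: np.ndarray, dictionary: SparseDictionary, code_sparsity: int = 15
) -> np.ndarray:
    """Histogram vectors for a feature-tensor stack (shared by both heads)."""
    return pool_histogram(encode_segments(build_segment_vectors(features), dictionary, code_sparsity))
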