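import numpy as np
import pytest

from mraselect import sparse
from mraselect.evaluation import kappa_from_labels


def planted_problem(rng, dim=20, n_atoms=10, sparsity=3, n_samples=300):
    D0 = rng.standard_normal((dim, n_atoms))
    D0 /= np.linalg.norm(D0, axis=0)
    X0 = np.zeros((n_atoms, n_samples))
    for i in range(n_samples):
        support = rng.choice(n_atoms, sparsity, replace=False)
        X0[support, i] = rng.standard_normal(sparsity)
    return (D0 @ X0).T, D0


class TestSegmentVectors:
    def test_essex_dimensions(self, rng):
        features = rng.random((2, 2, 20, 15, 6))
        vectors = sparse.build_segment_vectors(features)
        assert vectors.shape == (2, 20, 180)

    def test_roundtrip_scatter(self, rng):
        features = rng.random((1, 2, 4, 3, 2))
        vectors = sparse.build_segment_vectors(features)
        recovered = sparse.scatter_segment_vector(vectors[0, 2], n_electrodes=3, n_levels=2)
        assert np.array_equal(recovered, features[0, :, 2, :, :])

    def test_bad_shape_raises(self, rng):
        with pytest.raises(sparse.SparseError):
            sparse.build_segment_vectors(rng.random((2, 3, 4)))


class TestOMP:
    def test_single_atom_signal(self, rng):
        D = rng.standard_normal((12, 6))
        D /= np.linalg.norm(D, axis=0)
        code = sparse.omp_encode(D[:, 2], D, max_nonzero=4)
        assert np.count_nonzero(code) == 1
        assert np.isclose(code[2], 1.0)

    def test_orthogonal_pair_recovery(self):
        D = np.eye(8)[:, :4]
        y = 2.0 * D[:, 0] + 3.0 * D[:, 1]
        code = sparse.omp_encode(y, D, max_nonzero=5)
        assert np.allclose(code[:2], [2.0, 3.0], atol=1e-10)
        assert np.allclose(code[2:], 0.0)

    def test_zero_vector_zero_code(self, rng):
        D = rng.standard_normal((6, 9))
        D /= np.linalg.norm(D, axis=0)
        assert np.all(sparse.omp_encode(np.zeros(6), D, 3) == 0.0)

    def test_support_limit_and_residual_orthogonality(self, rng):
        D = rng.standard_normal((30, 60))
        D /= np.linalg.norm(D, axis=0)
        y = rng.standard_normal(30)
        code = sparse.omp_encode(y, D, max_nonzero=7)
        support = np.flatnonzero(code)
        assert support.size <= 7
        residual = y - D @ code
        assert np.max(np.abs(D[:, support].T @ residual)) <= 1e-8

    def test_residual_strictly_decreasing(self, rng):
        D = rng.standard_normal((20, 40))
        D /= np.linalg.norm(D, axis=0)
        y = rng.standard_normal(20)
        norms = []
        for k in range(1, 8):
            code = sparse.omp_encode(y, D, max_nonzero=k)
            norms.append(np.linalg.norm(y - D @ code))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_default_code_sparsity_is_15(self):
        import inspect

        assert inspect.signature(sparse.encode_segments).parameters["max_nonzero"].default == 15
        assert inspect.signature(sparse.train_sr).parameters["code_sparsity"].default == 15


class TestKSVD:
    def test_default_atoms_per_class(self):
        import inspect

        assert inspect.signature(sparse.ksvd_learn).parameters["n_atoms"].default == 30
        assert inspect.signature(sparse.train_sr).parameters["atoms_per_class"].default == 30
        assert inspect.signature(sparse.train_sr).parameters["train_sparsity"].default == 7

    def test_planted_dictionary_recovery(self):
        rng = np.random.default_rng(42)
        Y, _ = planted_problem(rng)
        D = sparse.ksvd_learn(Y, n_atoms=10, train_sparsity=3, n_iterations=60, seed=0)
        codes = np.stack([sparse.omp_encode(y, D, 3) for y in Y])
        rel = np.linalg.norm(Y - codes @ D.T) / np.linalg.norm(Y)
        assert rel <= 1e-3

    def test_zero_iterations_returns_normalized_init(self, rng):
        Y = rng.standard_normal((40, 12))
        D = sparse.ksvd_learn(Y, n_atoms=8, n_iterations=0, seed=3)
        assert D.shape == (12, 8)
        assert np.allclose(np.linalg.norm(D, axis=0), 1.0)
        # each atom is a normalized training vector
        normalized = Y / np.linalg.norm(Y, axis=1, keepdims=True)
        for atom in D.T:
            assert np.min(np.linalg.norm(normalized - atom, axis=1)) < 1e-12

    def test_objective_non_increasing(self, rng):
        Y, _ = planted_problem(rng, n_samples=80)
        Y += 0.05 * rng.standard_normal(Y.shape)
        _, history = sparse.ksvd_learn(
            Y, n_atoms=10, train_sparsity=3, n_iterations=15, seed=1, return_history=True
        )
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_atoms_unit_norm(self, rng):
        Y = rng.standard_normal((50, 16))
        D = sparse.ksvd_learn(Y, n_atoms=12, train_sparsity=4, n_iterations=5, seed=0)
        assert np.allclose(np.linalg.norm(D, axis=0), 1.0, atol=1e-12)

    def test_reproducible(self, rng):
        Y = rng.standard_normal((50, 16))
        D1 = sparse.ksvd_learn(Y, n_atoms=8, n_iterations=5, seed=9)
        D2 = sparse.ksvd_learn(Y, n_atoms=8, n_iterations=5, seed=9)
        assert np.array_equal(D1, D2)

    def test_too_few_vectors_raises(self, rng):
        with pytest.raises(sparse.SparseError):
            sparse.ksvd_learn(rng.standard_normal((5, 8)), n_atoms=10)


class TestConcatenation:
    def make_dict(self, rng, dim, n):
        D = rng.standard_normal((dim, n))
        return D / np.linalg.norm(D, axis=0)

    def test_three_class_90_atoms(self, rng):
        dicts = [self.make_dict(rng, 12, 30) for _ in range(3)]
        joint = sparse.concat_dictionaries(dicts)
        assert joint.n_atoms == 90
        assert joint.class_ranges == [(0, 30), (30, 60), (60, 90)]

    def test_single_class_identity(self, rng):
        D = self.make_dict(rng, 10, 5)
        joint = sparse.concat_dictionaries([D])
        assert np.array_equal(joint.atoms, D)

    def test_ranges_partition(self, rng):
        dicts = [self.make_dict(rng, 8, n) for n in (3, 5, 2)]
        joint = sparse.concat_dictionaries(dicts)
        covered = [i for lo, hi in joint.class_ranges for i in range(lo, hi)]
        assert covered == list(range(joint.n_atoms))

    def test_row_mismatch_raises(self, rng):
        with pytest.raises(sparse.SparseError):
            sparse.concat_dictionaries([self.make_dict(rng, 8, 3), self.make_dict(rng, 9, 3)])


class TestPooling:
    def test_single_segment_identity(self, rng):
        codes = rng.standard_normal((1, 7))
        assert np.array_equal(sparse.pool_histogram(codes), codes[0])

    def test_additivity(self, rng):
        a = rng.standard_normal((4, 9))
        b = rng.standard_normal((3, 9))
        together = sparse.pool_histogram(np.concatenate([a, b]))
        assert np.allclose(together, sparse.pool_histogram(a) + sparse.pool_histogram(b))

    def test_permutation_invariance(self, rng):
        codes = rng.standard_normal((6, 11))
        assert np.allclose(
            sparse.pool_histogram(codes), sparse.pool_histogram(codes[rng.permutation(6)])
        )

    def test_signed_vs_absolute(self):
        codes = np.array([[1.0, -1.0], [-1.0, -1.0]])
        assert np.array_equal(sparse.pool_histogram(codes), [0.0, -2.0])
        assert np.array_equal(sparse.pool_histogram(codes, absolute=True), [2.0, 2.0])

    def test_empty_raises(self):
        with pytest.raises(sparse.SparseError):
            sparse.pool_histogram(np.empty((0, 4)))


@pytest.fixture(scope="module")
def sr_setup(small_features):
    Xtr, ytr, Xte, yte, _ = small_features
    model = sparse.train_sr(Xtr, ytr, head="lda", atoms_per_class=10, n_iterations=10, seed=0)
    return Xtr, ytr, Xte, yte, model


class TestSRPipeline:
    def test_histogram_length_90_for_three_classes(self, small_features):
        Xtr, ytr, *_ = small_features
        model = sparse.train_sr(Xtr, ytr, head="lda", atoms_per_class=30, n_iterations=1, seed=0)
        hist = sparse.compute_histograms(Xtr[:2], model.dictionary)
        assert hist.shape == (2, 90)

    def test_reproducible_training_and_prediction(self, sr_setup, small_features):
        Xtr, ytr, Xte, _, model = sr_setup
        again = sparse.train_sr(Xtr, ytr, head="lda", atoms_per_class=10, n_iterations=10, seed=0)
        assert np.array_equal(model.dictionary.atoms, again.dictionary.atoms)
        assert np.array_equal(sparse.predict_sr(model, Xte), sparse.predict_sr(again, Xte))

    def test_end_to_end_kappa(self, sr_setup):
        _, _, Xte, yte, model = sr_setup
        kappa = kappa_from_labels(yte, sparse.predict_sr(model, Xte), 3)
        assert kappa >= 0.6

    def test_heads_share_identical_histograms(self, small_features):
        Xtr, ytr, *_ = small_features
        lda_model = sparse.train_sr(Xtr, ytr, head="lda", atoms_per_class=10, n_iterations=5, seed=4)
        svc_model = sparse.train_sr(Xtr, ytr, head="svc", atoms_per_class=10, n_iterations=5, seed=4)
        h1 = sparse.compute_histograms(Xtr, lda_model.dictionary)
        h2 = sparse.compute_histograms(Xtr, svc_model.dictionary)
        assert h1.tobytes() == h2.tobytes()

    def test_single_class_raises(self, small_features):
        Xtr, *_ = small_features
        with pytest.raises(sparse.SparseError):
            sparse.train_sr(Xtr, np.zeros(len(Xtr), dtype=int), head="lda")
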