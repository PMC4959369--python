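import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mraselect import moo
from mraselect.moo import (
    CostEvaluator,
    Encoding,
    Individual,
    ParetoArchive,
    crowding_distance,
    decode_genome,
    fast_nondominated_sort,
    polynomial_mutation,
    run_nsga2,
    sbx_crossover,
    select_operating_point,
)


def brute_force_ranks(costs):
    """Independent O(n^2) dominance peel."""
    costs = np.asarray(costs, dtype=float).copy()
    costs[np.isnan(costs).any(axis=1)] = np.inf
    n = len(costs)
    ranks = np.full(n, -1)
    alive = list(range(n))
    front = 0
    while alive:
        nondom = []
        for i in alive:
            dominated = False
            for j in alive:
                if j != i and np.all(costs[j] <= costs[i]) and np.any(costs[j] < costs[i]):
                    dominated = True
                    break
            if not dominated:
                nondom.append(i)
        for i in nondom:
            ranks[i] = front
        alive = [i for i in alive if i not in nondom]
        front += 1
    return ranks


class TestEncoding:
    def test_essex_genome_lengths(self):
        assert Encoding("OPT1", 20, 15, 6).genome_length == 3600
        assert Encoding("OPT2", 20, 15, 6).genome_length == 240
        enc3 = Encoding("OPT3", 20, 15, 6)
        assert enc3.segment_block == 180
        assert enc3.genome_length == 20 * 180

    def test_full_and_empty_masks(self):
        enc = Encoding("OPT1", 2, 3, 2)
        assert decode_genome(np.full(24, 0.9), enc).all()
        assert not decode_genome(np.full(24, 0.1), enc).any()

    def test_opt3_mask_shape(self):
        enc = Encoding("OPT3", 4, 3, 2)
        mask = decode_genome(np.random.default_rng(0).random(enc.genome_length), enc)
        assert mask.shape == (4, 12)

    def test_length_mismatch_raises(self):
        with pytest.raises(moo.EncodingError):
            decode_genome(np.zeros(10), Encoding("OPT2", 20, 15, 6))

    def test_cardinality_cap(self):
        enc = Encoding("OPT1", 2, 3, 2, max_active=3)
        genome = np.linspace(0.51, 0.99, 24)
        mask = decode_genome(genome, enc)
        assert mask.sum() == 3
        assert mask[-3:].all()  # the three largest genes survive


class TestNondominatedSort:
    def test_single_individual(self):
        assert fast_nondominated_sort(np.array([[1.0, 2.0]])).tolist() == [0]

    def test_three_point_example(self):
        ranks = fast_nondominated_sort(np.array([[1, 2], [2, 1], [2, 2]], dtype=float))
        assert ranks.tolist() == [0, 0, 1]

    def test_duplicates_same_rank(self):
        ranks = fast_nondominated_sort(np.array([[1, 1], [1, 1], [2, 2]], dtype=float))
        assert ranks[0] == ranks[1] == 0 and ranks[2] == 1

    def test_nan_dominated(self):
        ranks = fast_nondominated_sort(np.array([[1, 1], [np.nan, 0.5]]))
        assert ranks[0] == 0 and ranks[1] == 1

    def test_agrees_with_brute_force_on_200_random_populations(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(1, 51)
            costs = np.round(rng.random((n, 2)), 2)  # rounding induces ties
            assert np.array_equal(fast_nondominated_sort(costs), brute_force_ranks(costs))


class TestCrowdingDistance:
    def test_two_member_front(self):
        assert np.all(np.isinf(crowding_distance(np.array([[0, 1], [1, 0]], dtype=float))))

    def test_middle_member_distance(self):
        dists = crowding_distance(np.array([[0, 1], [0.5, 0.5], [1, 0]]))
        assert np.isinf(dists[0]) and np.isinf(dists[2])
        assert np.isclose(dists[1], 2.0)

    def test_identical_costs(self):
        # stable sort puts the same two members at the boundaries of both
        # objectives; everyone else has zero distance
        dists = crowding_distance(np.tile([0.3, 0.3], (5, 1)))
        assert np.isinf(dists).sum() == 2
        assert np.all(dists[~np.isinf(dists)] == 0.0)

    def test_empty_front_raises(self):
        with pytest.raises(moo.EncodingError):
            crowding_distance(np.empty((0, 2)))


class TestSBX:
    def test_identical_parents_identical_children(self, rng):
        p = rng.random(50)
        c1, c2 = sbx_crossover(p, p, pc=1.0, rng=rng)
        assert np.allclose(c1, p) and np.allclose(c2, p)

    def test_no_crossover_returns_parents(self, rng):
        a, b = rng.random(20), rng.random(20)
        c1, c2 = sbx_crossover(a, b, pc=0.0, rng=rng)
        assert np.array_equal(c1, a) and np.array_equal(c2, b)

    def test_mean_preservation_per_gene(self):
        rng = np.random.default_rng(3)
        a = np.full(10_000, 0.45)
        b = np.full(10_000, 0.55)
        c1, c2 = sbx_crossover(a, b, eta=20.0, pc=1.0, rng=rng)
        # interior parents: no clipping, so the sum identity is exact
        assert np.allclose(c1 + c2, a + b, atol=1e-12)

    def test_monte_carlo_child_mean(self):
        rng = np.random.default_rng(5)
        a = np.full(100_000, 0.3)
        b = np.full(100_000, 0.7)
        c1, c2 = sbx_crossover(a, b, eta=20.0, pc=1.0, rng=rng)
        lower = np.minimum(c1, c2)
        upper = np.maximum(c1, c2)
        assert abs(lower.mean() - 0.3) < 0.01
        assert abs(upper.mean() - 0.7) < 0.01

    def test_output_bounds(self, rng):
        for _ in range(20):
            c1, c2 = sbx_crossover(rng.random(64), rng.random(64), pc=1.0, rng=rng)
            assert c1.min() >= 0 and c1.max() <= 1 and c2.min() >= 0 and c2.max() <= 1

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(moo.EncodingError):
            sbx_crossover(np.zeros(3), np.zeros(4), rng=rng)


class TestPolynomialMutation:
    def test_pm_zero_unchanged(self, rng):
        g = rng.random(30)
        assert np.array_equal(polynomial_mutation(g, pm=0.0, rng=rng), g)

    def test_bounds(self, rng):
        for _ in range(50):
            out = polynomial_mutation(rng.random(16), pm=1.0, rng=rng)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_monte_carlo_mean_symmetric(self):
        rng = np.random.default_rng(11)
        # length-1 genome: per-gene rate 1/n = 1, so every draw mutates
        values = [polynomial_mutation(np.array([0.5]), eta=20.0, pm=1.0, rng=rng)[0] for _ in range(20_000)]
        assert abs(np.mean(values) - 0.5) < 0.01


class ToyProblem:
    """Continuous two-objective toy: f1 = mean(g), f2 = mean(1-g)."""

    n_genes = 8

    def evaluate(self, genome):
        m = float(np.mean(genome))
        return m, 1.0 - m


class TestNSGA2:
    def test_invalid_sizes(self):
        with pytest.raises(moo.EncodingError):
            run_nsga2(ToyProblem(), pop_size=5, generations=3)
        with pytest.raises(moo.EncodingError):
            run_nsga2(ToyProblem(), pop_size=8, generations=0)

    def test_archive_mutually_nondominated(self):
        archive, _ = run_nsga2(ToyProblem(), pop_size=12, generations=5, seed=0)
        costs = archive.costs
        for i in range(len(costs)):
            for j in range(len(costs)):
                if i != j:
                    assert not (np.all(costs[j] <= costs[i]) and np.any(costs[j] < costs[i]))

    def test_reproducible(self):
        a1, h1 = run_nsga2(ToyProblem(), pop_size=12, generations=5, seed=3)
        a2, h2 = run_nsga2(ToyProblem(), pop_size=12, generations=5, seed=3)
        assert h1 == h2
        assert all(np.array_equal(x.genome, y.genome) for x, y in zip(a1.individuals, a2.individuals))

    def test_history_length_and_default_shape(self):
        _, history = run_nsga2(ToyProblem(), pop_size=8, generations=4, seed=1)
        assert len(history) == 5  # initial population + one entry per generation
        assert set(history[0]) == {"generation", "min_c1", "min_c2", "archive_size"}

    def test_elitism_min_costs_non_increasing(self):
        _, history = run_nsga2(ToyProblem(), pop_size=16, generations=20, seed=7)
        c1 = [h["min_c1"] for h in history]
        c2 = [h["min_c2"] for h in history]
        assert all(a >= b - 1e-12 for a, b in zip(c1, c1[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(c2, c2[1:]))


class TestOperatingPoint:
    def archive_from(self, cost_list):
        inds = [
            Individual(genome=np.full(2, 0.1 * i), costs=tuple(c), rank=0)
            for i, c in enumerate(cost_list)
        ]
        return ParetoArchive(individuals=inds)

    def test_singleton(self):
        archive = self.archive_from([(0.4, 0.6)])
        for rule in ("min_c1", "min_c2", "knee"):
            assert select_operating_point(archive, rule).costs == (0.4, 0.6)

    def test_min_rules(self):
        archive = self.archive_from([(0.1, 0.9), (0.9, 0.1)])
        assert select_operating_point(archive, "min_c1").costs == (0.1, 0.9)
        assert select_operating_point(archive, "min_c2").costs == (0.9, 0.1)

    def test_knee(self):
        archive = self.archive_from([(0.0, 1.0), (0.2, 0.2), (1.0, 0.0)])
        assert select_operating_point(archive, "knee").costs == (0.2, 0.2)

    def test_empty_raises(self):
        with pytest.raises(moo.EncodingError):
            select_operating_point(ParetoArchive(individuals=[]), "min_c1")

    def test_unknown_rule_raises(self):
        with pytest.raises(moo.EncodingError):
            select_operating_point(self.archive_from([(0, 1)]), "median")


class TestCostEvaluator:
    def test_empty_mask_penalty(self, small_features):
        Xtr, ytr, *_ = small_features
        enc = Encoding("OPT1", 6, 4, 4)
        ev = CostEvaluator(Xtr, ytr, enc, cv_seed=0)
        assert ev.evaluate_mask(np.zeros(enc.genome_length, dtype=bool)) == (2.0, 1.0)

    def test_ground_truth_mask_low_c1(self, small_features, small_config, small_mra):
        from mraselect.synthetic import ground_truth_mask

        Xtr, ytr, *_ = small_features
        gt = ground_truth_mask(small_config, small_mra).ravel()
        enc = Encoding("OPT1", 6, 4, 4)
        c1, c2 = CostEvaluator(Xtr, ytr, enc, cv_seed=0).evaluate_mask(gt)
        assert c1 <= 0.05

    def test_pure_noise_chance_level_c2(self, rng):
        features = rng.standard_normal((90, 2, 6, 4, 4))
        labels = np.repeat(np.arange(3), 30)
        enc = Encoding("OPT1", 6, 4, 4)
        ev = CostEvaluator(features, labels, enc, cv_seed=1)
        mask = np.zeros(enc.genome_length, dtype=bool)
        mask[rng.choice(enc.genome_length, 8, replace=False)] = True
        _, c2 = ev.evaluate_mask(mask)
        assert abs(c2 - 2.0 / 3.0) <= 0.1

    def test_cache_counts_unique_masks(self, small_features):
        Xtr, ytr, *_ = small_features
        enc = Encoding("OPT1", 6, 4, 4)
        ev = CostEvaluator(Xtr, ytr, enc, cv_seed=0)
        genome = np.random.default_rng(0).random(enc.genome_length)
        first = ev.evaluate_genome(genome)
        count = ev.n_evaluations
        assert ev.evaluate_genome(genome) == first
        assert ev.n_evaluations == count

    def test_opt2_fast_path_matches_direct_route(self, small_features):
        from mraselect.classifiers import build_ensemble, predict_ensemble
        from mraselect.evaluation import kappa_from_labels, kfold_splits

        Xtr, ytr, *_ = small_features
        enc = Encoding("OPT2", 6, 4, 4)
        ev = CostEvaluator(Xtr, ytr, enc, cv_seed=5)
        rng = np.random.default_rng(1)
        for _ in range(2):
            mask = rng.random(enc.genome_length) > 0.5
            fast = ev.evaluate_mask(mask)
            model = build_ensemble(Xtr, ytr, "OPT2", mask)
            c1 = 1.0 - kappa_from_labels(ytr, predict_ensemble(model, Xtr), 3)
            losses = []
            for tr_idx, va_idx in kfold_splits(ytr, 10, 5):
                fold = build_ensemble(Xtr[tr_idx], ytr[tr_idx], "OPT2", mask)
                losses.append(np.mean(predict_ensemble(fold, Xtr[va_idx]) != ytr[va_idx]))
            assert np.allclose(fast, (c1, float(np.mean(losses))))

    @settings(max_examples=10, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_costs_within_contract_bounds(self, seed):
        rng = np.random.default_rng(seed)
        features = rng.standard_normal((30, 2, 3, 2, 2))
        labels = np.arange(30) % 3
        enc = Encoding("OPT1", 3, 2, 2)
        ev = CostEvaluator(features, labels, enc, cv_seed=0)
        c1, c2 = ev.evaluate_genome(rng.random(enc.genome_length))
        assert 0.0 <= c1 <= 2.0 and 0.0 <= c2 <= 1.0
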