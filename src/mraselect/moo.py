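"""NSGA-II wrapper feature selection over three classifier-structure encodings.

Genomes are real vectors in [0,1]^n thresholded at 0.5 into binary masks:

* ``OPT1`` — n = 2*S*E*L; the mask selects input features of one LDA.
* ``OPT2`` — n = 2*S*L; the mask selects voting members of the full LDA bank.
* ``OPT3`` — n = S * 2*E*L; each length-2*E*L block selects the inputs of the
  corresponding per-segment LDA (empty blocks drop that member).

Two costs are minimized per individual: C1 = 1 - kappa on the training set
after a full fit, and C2 = mean held-out misclassification rate over a
stratified tenfold cross-validation of the training set.  Degenerate masks
receive penalty costs (2.0, 1.0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classifiers import (
    ClassifierError,
    build_ensemble,
    fit_lda,
    majority_vote,
    predict_ensemble,
    predict_lda,
)
from .evaluation import kappa_from_labels, kfold_splits
from .mra import MRAConfig, flatten_features

__all__ = [
    "Encoding",
    "Individual",
    "ParetoArchive",
    "CostEvaluator",
    "decode_genome",
    "evaluate_costs",
    "fast_nondominated_sort",
    "crowding_distance",
    "sbx_crossover",
    "polynomial_mutation",
    "binary_tournament",
    "run_nsga2",
    "select_operating_point",
    "EncodingError",
]

logger = logging.getLogger(__name__)

PENALTY_COSTS = (2.0, 1.0)


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class Encoding:
    """Genome layout for one selection approach."""

    tag: str  # OPT1 | OPT2 | OPT3
    n_segments: int
    n_electrodes: int
    n_levels: int
    threshold: float = 0.5
    max_active: int | None = None  # cardinality cap on the decoded mask

    def __post_init__(self) -> None:
        object.__setattr__(self, "tag", self.tag.upper())
        if self.tag not in ("OPT1", "OPT2", "OPT3"):
            raise EncodingError(f"unknown encoding tag {self.tag!r}")
        if not 0.0 < self.threshold < 1.0:
            raise EncodingError("threshold must be in (0, 1)")
        if self.max_active is not None and self.max_active < 1:
            raise EncodingError("max_active must be >= 1 when given")

    @classmethod
    def from_mra(cls, tag: str, config: MRAConfig, threshold: float = 0.5) -> "Encoding":
        return cls(tag, config.n_segments, config.n_electrodes, config.n_levels, threshold)

    @property
    def segment_block(self) -> int:
        """Selectable inputs per OPT3 member: 2*E*L."""
        return 2 * self.n_electrodes * self.n_levels

    @property
    def genome_length(self) -> int:
        S, E, L = self.n_segments, self.n_electrodes, self.n_levels
        if self.tag == "OPT1":
            return 2 * S * E * L
        if self.tag == "OPT2":
            return 2 * S * L
        return S * self.segment_block


def decode_genome(genome: np.ndarray, encoding: Encoding) -> np.ndarray:
    """Threshold a real genome into the encoding's binary mask.

    Bit i is active iff gene_i > threshold.  When the encoding carries a
    cardinality cap and more genes exceed the threshold, only the
    ``max_active`` largest genes stay active.  OPT3 masks are reshaped into
    (S, 2*E*L) per-member rows.
    """
    genome = np.asarray(genome, dtype=float)
    if genome.shape != (encoding.genome_length,):
        raise EncodingError(
            f"genome length {genome.size} != {encoding.genome_length} for {encoding.tag}"
        )
    mask = genome > encoding.threshold
    cap = encoding.max_active
    if cap is not None and mask.sum() > cap:
        keep = np.argsort(genome, kind="stable")[-cap:]
        mask = np.zeros_like(mask)
        mask[keep] = True
    if encoding.tag == "OPT3":
        return mask.reshape(encoding.n_segments, encoding.segment_block)
    return mask


class CostEvaluator:
    """Wrapper cost evaluation with caching.

    For OPT2 the member LDAs do not depend on the mask, so member predictions
    (full-fit training predictions and per-fold validation predictions) are
    precomputed once; any mask evaluation is then a pure voting aggregation.
    The fast path is verified against the direct ensemble route in the tests.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        encoding: Encoding,
        cv_seed: int = 0,
        n_folds: int = 10,
        shrinkage: "float | str" = "auto",
    ) -> None:
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        self.encoding = encoding
        self.cv_seed = cv_seed
        self.n_folds = n_folds
        self.shrinkage = shrinkage
        self.n_classes = int(np.unique(self.labels).size)
        self.flat = flatten_features(self.features)
        self._cache: dict[bytes, tuple[float, float]] = {}
        self._splits = kfold_splits(self.labels, n_folds, cv_seed)
        self._opt2_votes = None
        self.n_evaluations = 0

    # -- OPT2 fast path -----------------------------------------------------
    def _precompute_opt2(self):
        n = self.features.shape[0]
        S, L = self.encoding.n_segments, self.encoding.n_levels
        n_members = 2 * S * L
        full = build_ensemble(self.features, self.labels, "OPT0", shrinkage=self.shrinkage)
        train_labels = np.empty((n_members, n), dtype=int)
        train_scores = np.empty((n_members, n, self.n_classes))
        cv_labels = np.empty((n_members, n), dtype=int)
        cv_scores = np.empty((n_members, n, self.n_classes))
        for m, (spec, lda) in enumerate(full.members):
            from .classifiers import _member_matrix

            X = _member_matrix(self.features, spec)
            pred, sc = predict_lda(lda, X)
            train_labels[m], train_scores[m] = pred, sc
        for train_idx, val_idx in self._splits:
            fold = build_ensemble(
                self.features[train_idx], self.labels[train_idx], "OPT0", shrinkage=self.shrinkage
            )
            for m, (spec, lda) in enumerate(fold.members):
                from .classifiers import _member_matrix

                Xv = _member_matrix(self.features[val_idx], spec)
                pred, sc = predict_lda(lda, Xv)
                cv_labels[m, val_idx], cv_scores[m, val_idx] = pred, sc
        self._opt2_votes = (train_labels, train_scores, cv_labels, cv_scores)

    def _costs_opt2(self, mask: np.ndarray) -> tuple[float, float]:
        if self._opt2_votes is None:
            self._precompute_opt2()
        train_labels, train_scores, cv_labels, cv_scores = self._opt2_votes
        active = np.flatnonzero(mask)
        pred_train = majority_vote(
            train_labels[active], train_scores[active], self.n_classes
        )
        c1 = 1.0 - kappa_from_labels(self.labels, pred_train, self.n_classes)
        losses = []
        for _, val_idx in self._splits:
            pred_val = majority_vote(
                cv_labels[active][:, val_idx],
                cv_scores[active][:, val_idx],
                self.n_classes,
            )
            losses.append(float(np.mean(pred_val != self.labels[val_idx])))
        return c1, float(np.mean(losses))

    # -- generic (OPT1/OPT3) route ------------------------------------------
    def _fit_predict(self, mask, X_train, y_train, X_eval):
        if self.encoding.tag == "OPT1":
            cols = np.flatnonzero(mask)
            model = fit_lda(X_train[:, cols], y_train, self.shrinkage)
            return predict_lda(model, X_eval[:, cols])[0]
        # OPT3: X_* are feature tensors
        model = build_ensemble(X_train, y_train, "OPT3", mask, self.shrinkage)
        return predict_ensemble(model, X_eval)

    def _costs_generic(self, mask: np.ndarray) -> tuple[float, float]:
        if self.encoding.tag == "OPT1":
            X = self.flat
        else:
            X = self.features
        pred = self._fit_predict(mask, X, self.labels, X)
        c1 = 1.0 - kappa_from_labels(self.labels, pred, self.n_classes)
        losses = []
        for train_idx, val_idx in self._splits:
            pred_val = self._fit_predict(mask, X[train_idx], self.labels[train_idx], X[val_idx])
            losses.append(float(np.mean(pred_val != self.labels[val_idx])))
        return c1, float(np.mean(losses))

    def __call__(self, genome: np.ndarray) -> tuple[float, float]:
        return self.evaluate_genome(genome)

    def evaluate_genome(self, genome: np.ndarray) -> tuple[float, float]:
        return self.evaluate_mask(decode_genome(genome, self.encoding))

    def evaluate_mask(self, mask: np.ndarray) -> tuple[float, float]:
        key = np.packbits(np.asarray(mask, dtype=bool).ravel()).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if not np.any(mask):
            costs = PENALTY_COSTS
        else:
            try:
                if self.encoding.tag == "OPT2":
                    costs = self._costs_opt2(np.asarray(mask, dtype=bool).ravel())
                else:
                    costs = self._costs_generic(mask)
            except ClassifierError as exc:  # degenerate training → penalty
                logger.warning("penalizing mask after training failure: %s", exc)
                costs = PENALTY_COSTS
        self._cache[key] = costs
        self.n_evaluations += 1
        return costs

    @property
    def n_genes(self) -> int:
        return self.encoding.genome_length

    def evaluate(self, genome: np.ndarray) -> tuple[float, float]:
        return self.evaluate_genome(genome)


def evaluate_costs(
    mask: np.ndarray,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    encoding: Encoding,
    cv_seed: int = 0,
    **kwargs,
) -> tuple[float, float]:
    """One-shot (C1, C2) evaluation of a decoded mask (no shared cache)."""
    return CostEvaluator(train_features, train_labels, encoding, cv_seed, **kwargs).evaluate_mask(mask)


# ---------------------------------------------------------------------------
# NSGA-II machinery
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    genome: np.ndarray
    costs: tuple[float, float]
    rank: int = 0
    crowding: float = 0.0


@dataclass
class ParetoArchive:
    """Rank-0 individuals of the final population (plus the full population)."""

    individuals: list[Individual]
    provenance: dict = field(default_factory=dict)
    population: list[Individual] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def costs(self) -> np.ndarray:
        return np.array([ind.costs for ind in self.individuals])

    @property
    def population_costs(self) -> np.ndarray:
        members = self.population or self.individuals
        return np.array([ind.costs for ind in members])


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def fast_nondominated_sort(cost_pairs: np.ndarray) -> np.ndarray:
    """Front index (0 = non-dominated) per individual, minimizing both costs.

    NaN costs are treated as +inf (dominated by every finite point).
    """
    costs = np.asarray(cost_pairs, dtype=float)
    if costs.ndim != 2 or costs.shape[0] < 1:
        raise EncodingError("need a non-empty (n, m) cost matrix")
    bad = np.isnan(costs).any(axis=1)
    costs = costs.copy()
    costs[bad] = np.inf  # NaN anywhere -> dominated by every finite point
    n = costs.shape[0]
    # a dominates b: all(a <= b) and any(a < b), vectorized pairwise
    le = np.all(costs[:, None, :] <= costs[None, :, :], axis=2)
    lt = np.any(costs[:, None, :] < costs[None, :, :], axis=2)
    dominates = le & lt  # [i, j] = i dominates j
    n_dominators = dominates.sum(axis=0)
    ranks = np.full(n, -1, dtype=int)
    current = np.flatnonzero(n_dominators == 0)
    front = 0
    remaining = n
    counts = n_dominators.copy()
    while current.size:
        ranks[current] = front
        remaining -= current.size
        counts[current] = -1
        for i in current:
            counts[dominates[i]] -= 1
        current = np.flatnonzero(counts == 0)
        front += 1
    return ranks


def crowding_distance(front_costs: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front (boundaries get +inf)."""
    costs = np.asarray(front_costs, dtype=float)
    if costs.ndim != 2 or costs.shape[0] < 1:
        raise EncodingError("empty front")
    n, m = costs.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(costs[:, j], kind="stable")
        lo, hi = costs[order[0], j], costs[order[-1], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        span = hi - lo
        if span <= 0:
            continue
        gaps = (costs[order[2:], j] - costs[order[:-2], j]) / span
        dist[order[1:-1]] += gaps
    return dist


def sbx_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    eta: float = 20.0,
    pc: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover on [0,1]^n genomes.

    With probability ``pc`` the pair is recombined: each gene undergoes SBX
    with probability 0.5 (else it is copied), drawing a spread factor beta
    from the eta-parameterized SBX density, and the two contracted values are
    assigned to the children in random order (the per-gene swap that makes
    SBX recombine parental patterns).  The children's pre-clip sum equals the
    parents' sum per gene.  Without crossover the parents are returned
    unchanged (copies).
    """
    rng = np.random.default_rng() if rng is None else rng
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise EncodingError("parent genome length mismatch")
    if rng.random() >= pc:
        return a.copy(), b.copy()
    u = rng.random(a.shape)
    beta = np.where(
        u < 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (0.5 / (1.0 - u)) ** (1.0 / (eta + 1.0)),
    )
    crossed = rng.random(a.shape) < 0.5
    beta = np.where(crossed, beta, 1.0)
    c1 = 0.5 * ((1.0 + beta) * a + (1.0 - beta) * b)
    c2 = 0.5 * ((1.0 - beta) * a + (1.0 + beta) * b)
    swap = rng.random(a.shape) < 0.5
    c1_out = np.where(swap, c2, c1)
    c2_out = np.where(swap, c1, c2)
    return np.clip(c1_out, 0.0, 1.0), np.clip(c2_out, 0.0, 1.0)


def polynomial_mutation(
    genome: np.ndarray,
    eta: float = 20.0,
    pm: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Polynomial mutation: with probability ``pm`` the individual is mutated,
    perturbing each gene with per-gene rate 1/n; output clipped to [0,1]."""
    rng = np.random.default_rng() if rng is None else rng
    genome = np.asarray(genome, dtype=float).copy()
    if rng.random() >= pm:
        return genome
    n = genome.size
    hit = rng.random(n) < (1.0 / n)
    if not hit.any():
        return genome
    u = rng.random(int(hit.sum()))
    delta = np.where(
        u < 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0,
        1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0)),
    )
    genome[hit] = np.clip(genome[hit] + delta, 0.0, 1.0)
    return genome


def binary_tournament(pop: list[Individual], rng: np.random.Generator) -> Individual:
    """Pick the (rank, crowding)-better of two random individuals."""
    i, j = rng.integers(len(pop)), rng.integers(len(pop))
    a, b = pop[i], pop[j]
    if (a.rank, -a.crowding) <= (b.rank, -b.crowding):
        return a
    return b


def _assign_rank_crowding(pop: list[Individual]) -> None:
    costs = np.array([ind.costs for ind in pop])
    ranks = fast_nondominated_sort(costs)
    for ind, r in zip(pop, ranks):
        ind.rank = int(r)
    for r in range(ranks.max() + 1):
        members = [i for i, ind in enumerate(pop) if ind.rank == r]
        dists = crowding_distance(costs[members])
        for i, d in zip(members, dists):
            pop[i].crowding = float(d)


def run_nsga2(
    problem,
    pop_size: int = 50,
    generations: int = 50,
    seed: int = 0,
    eta_crossover: float = 20.0,
    eta_mutation: float = 20.0,
    pc: float = 0.5,
    pm: float = 0.5,
) -> tuple[ParetoArchive, list[dict]]:
    """Standard NSGA-II minimization of ``problem.evaluate(genome) -> (C1, C2)``.

    ``problem`` exposes ``n_genes`` and ``evaluate``.  Returns the rank-0 set
    of the final population and a per-generation history of best costs.
    """
    if pop_size < 4 or pop_size % 2:
        raise EncodingError("pop_size must be an even number >= 4")
    if generations < 1:
        raise EncodingError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    n = problem.n_genes

    pop = [
        Individual(genome=g, costs=tuple(problem.evaluate(g)))
        for g in rng.random((pop_size, n))
    ]
    _assign_rank_crowding(pop)
    history: list[dict] = []

    def log_generation(generation: int) -> None:
        costs = np.array([ind.costs for ind in pop])
        history.append(
            {
                "generation": generation,
                "min_c1": float(costs[:, 0].min()),
                "min_c2": float(costs[:, 1].min()),
                "archive_size": int(sum(1 for ind in pop if ind.rank == 0)),
            }
        )

    log_generation(0)
    for gen in range(1, generations + 1):
        offspring: list[Individual] = []
        while len(offspring) < pop_size:
            pa = binary_tournament(pop, rng)
            pb = binary_tournament(pop, rng)
            ca, cb = sbx_crossover(pa.genome, pb.genome, eta_crossover, pc, rng)
            for child in (ca, cb):
                child = polynomial_mutation(child, eta_mutation, pm, rng)
                offspring.append(
                    Individual(genome=child, costs=tuple(problem.evaluate(child)))
                )
        combined = pop + offspring[:pop_size]
        costs = np.array([ind.costs for ind in combined])
        ranks = fast_nondominated_sort(costs)
        for ind, r in zip(combined, ranks):
            ind.rank = int(r)
        survivors: list[Individual] = []
        for r in range(ranks.max() + 1):
            members = [ind for ind in combined if ind.rank == r]
            dists = crowding_distance(np.array([ind.costs for ind in members]))
            for ind, d in zip(members, dists):
                ind.crowding = float(d)
            if len(survivors) + len(members) <= pop_size:
                survivors.extend(members)
            else:
                order = np.argsort([-ind.crowding for ind in members], kind="stable")
                survivors.extend(members[i] for i in order[: pop_size - len(survivors)])
                break
        pop = survivors
        _assign_rank_crowding(pop)
        log_generation(gen)

    archive = ParetoArchive(
        individuals=[ind for ind in pop if ind.rank == 0],
        population=list(pop),
        provenance={
            "seed": seed,
            "pop_size": pop_size,
            "generations": generations,
            "encoding": getattr(getattr(problem, "encoding", None), "tag", None),
        },
    )
    return archive, history


def select_operating_point(archive: ParetoArchive, rule: str = "min_c1") -> Individual:
    """Pick one archive member: lexicographic min on C1 or C2, or the knee.

    The knee maximizes perpendicular distance to the segment joining the
    archive's extreme cost points.  Ties break on genome lexicographic order.
    """
    if not archive.individuals:
        raise EncodingError("empty archive")
    inds = archive.individuals
    costs = archive.costs

    def lex_key(ind: Individual):
        return tuple(ind.genome)

    if rule == "min_c1":
        best = min(inds, key=lambda ind: (ind.costs[0], ind.costs[1], lex_key(ind)))
    elif rule == "min_c2":
        best = min(inds, key=lambda ind: (ind.costs[1], ind.costs[0], lex_key(ind)))
    elif rule == "knee":
        lo = costs[np.lexsort((costs[:, 1], costs[:, 0]))[0]]
        hi = costs[np.lexsort((costs[:, 0], costs[:, 1]))[0]]
        direction = hi - lo
        norm = np.hypot(*direction)
        if norm == 0:
            return min(inds, key=lex_key)
        rel = np.asarray(costs) - lo
        dists = np.abs(rel[:, 0] * direction[1] - rel[:, 1] * direction[0]) / norm
        best_d = dists.max()
        cands = [ind for ind, d in zip(inds, dists) if d == best_d]
        best = min(cands, key=lex_key)
    else:
        raise EncodingError(f"unknown selection rule {rule!r}")
    return best
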