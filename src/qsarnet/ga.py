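"""Genetic-algorithm wrapper for descriptor-subset selection.

A chromosome is a bit vector over descriptor columns (1 = selected). Fitness
is the mean stratified k-fold cross-validated accuracy of a classifier
trained on the selected columns, minus a parsimony penalty
``penalty_lambda × (selected / total)``. Search uses tournament selection,
uniform crossover, per-bit mutation and elitism; with at least one elite the
best-fitness trace is non-decreasing.

The inner CV folds are re-seeded identically on every fitness call, so
fitness is a pure function of the chromosome within a run and results are
reproducible from the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, PropertyLabels, train_classifier


@dataclass
class Chromosome:
    bits: np.ndarray
    fitness: float | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def selected_names(self, names: list[str]) -> list[str]:
        return [n for n, b in zip(names, self.bits) if b]


@dataclass
class GAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.01
    tournament_size: int = 3
    elitism: int = 1
    init_inclusion_prob: float = 0.1
    penalty_lambda: float = 0.01
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_prob", "mutation_prob", "init_inclusion_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be smaller than population_size")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


@dataclass
class GARun:
    best_chromosome: Chromosome
    fitness_trace: list[float]
    selected_names: list[str]
    config: GAConfig

    @property
    def best_fitness(self) -> float:
        return float(self.best_chromosome.fitness)


def _cv_accuracy(
    X: np.ndarray, y: PropertyLabels, spec: ClassifierSpec, folds: int, seed: int
) -> float:
    y01 = y.y
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y01):
        train_classes = [y.classes[i] for i in train_idx]
        if min(train_classes.count("+"), train_classes.count("-")) < 2:
            majority = max(("-", "+"), key=train_classes.count)
            correct += sum(y.classes[i] == majority for i in test_idx)
            continue
        y_tr = PropertyLabels(
            [y.compound_ids[i] for i in train_idx], y.property, train_classes
        )
        model = train_classifier(X[train_idx], y_tr, spec)
        pred = model.predict(X[test_idx])
        correct += sum(p == y.classes[i] for p, i in zip(pred, test_idx))
    return correct / len(y)


def fitness_of(
    chrom: Chromosome,
    X: np.ndarray,
    y: PropertyLabels,
    spec: ClassifierSpec,
    cfg: GAConfig,
) -> float:
    """CV-accuracy fitness with parsimony penalty; all-zero chromosome → 0."""
    if chrom.n_selected == 0:
        chrom.fitness = 0.0
        chrom.valid = False
        return 0.0
    X = np.asarray(X, dtype=float)
    acc = _cv_accuracy(X[:, chrom.bits], y, spec, cfg.cv_folds, cfg.seed)
    fit = acc - cfg.penalty_lambda * chrom.n_selected / chrom.bits.size
    chrom.fitness = fit
    chrom.valid = True
    return fit


def _tournament(rng: np.random.Generator, pop: list[Chromosome], size: int) -> Chromosome:
    idx = rng.integers(0, len(pop), size=size)
    return max((pop[i] for i in idx), key=lambda c: c.fitness)


def run_ga(
    X,
    y: PropertyLabels,
    spec: ClassifierSpec,
    cfg: GAConfig,
    feature_names: list[str] | None = None,
) -> GARun:
    """Evolve descriptor subsets for ``cfg.generations`` generations.

    The trace has one entry per evaluated generation (initial population
    included), so ``generations=0`` returns the best of the seeded initial
    population with a trace of length 1.
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 descriptors to search over")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]

    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}

    def evaluate(c: Chromosome) -> None:
        key = np.packbits(c.bits).tobytes()
        if key in cache:
            c.fitness = cache[key]
            c.valid = c.n_selected > 0
        else:
            cache[key] = fitness_of(c, X, y, spec, cfg)

    population: list[Chromosome] = []
    for _ in range(cfg.population_size):
        bits = rng.random(p) < cfg.init_inclusion_prob
        if not bits.any():
            bits[rng.integers(0, p)] = True
        population.append(Chromosome(bits))
    for c in population:
        evaluate(c)

    def best_of(pop: list[Chromosome]) -> Chromosome:
        return max(pop, key=lambda c: c.fitness)

    trace = [best_of(population).fitness]
    for _ in range(cfg.generations):
        nxt: list[Chromosome] = []
        elites = sorted(population, key=lambda c: c.fitness, reverse=True)[: cfg.elitism]
        nxt.extend(Chromosome(e.bits.copy(), e.fitness, e.valid) for e in elites)
        while len(nxt) < cfg.population_size:
            p1 = _tournament(rng, population, cfg.tournament_size)
            p2 = _tournament(rng, population, cfg.tournament_size)
            if rng.random() < cfg.crossover_prob:
                mask = rng.random(p) < 0.5
                child_bits = np.where(mask, p1.bits, p2.bits)
            else:
                child_bits = p1.bits.copy()
            flip = rng.random(p) < cfg.mutation_prob
            child_bits = child_bits ^ flip
            nxt.append(Chromosome(child_bits))
        population = nxt
        for c in population:
            if c.fitness is None:
                evaluate(c)
        trace.append(best_of(population).fitness)

    best = best_of(population)
    return GARun(
        best_chromosome=best,
        fitness_trace=[float(t) for t in trace],
        selected_names=best.selected_names(feature_names),
        config=cfg,
    )


def exhaustive_best_fitness(
    X, y: PropertyLabels, spec: ClassifierSpec, cfg: GAConfig
) -> tuple[float, np.ndarray]:
    """Enumerate every non-empty descriptor subset (small p only).

    Reference optimiser for validating the GA search; cost is 2^p − 1
    fitness evaluations.
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    p = X.shape[1]
    if p > 20:
        raise ValueError("exhaustive enumeration limited to p <= 20")
    best_fit, best_bits = -np.inf, None
    for mask in range(1, 2**p):
        bits = np.array([(mask >> j) & 1 for j in range(p)], dtype=bool)
        fit = fitness_of(Chromosome(bits), X, y, spec, cfg)
        if fit > best_fit:
            best_fit, best_bits = fit, bits
    return float(best_fit), best_bits
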