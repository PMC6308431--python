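"""Genetic-algorithm search over ANN architecture chromosomes.

Each individual is a 9-gene :class:`~blastograde.grading.Architecture`.
A generation applies tournament selection (size 3), uniform crossover,
per-gene mutation (redraw from the gene's domain), migration (a fraction
of the population replaced by fresh random architectures) and elitism.
Fitness is the accuracy of the trained network on the held-out test (or
validation) split; evaluations are memoized per (architecture, dataset,
seed) so elites are never retrained.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grading import (Architecture, MAX_NEURONS, TRAIN_FUNCTIONS,
                      TRANSFER_FUNCTIONS, accuracy, split_dataset, train_ann)

_GENE_DOMAINS: tuple = (
    ("int", 1, MAX_NEURONS),        # n_hidden1
    ("int", 1, MAX_NEURONS),        # n_hidden2
    ("int", 1, MAX_NEURONS),        # n_hidden3
    ("enum", TRANSFER_FUNCTIONS),   # tf_hidden1
    ("enum", TRANSFER_FUNCTIONS),   # tf_hidden2
    ("enum", TRANSFER_FUNCTIONS),   # tf_hidden3
    ("enum", TRANSFER_FUNCTIONS),   # tf_output
    ("enum", TRAIN_FUNCTIONS),      # train_fn
    ("enum", (1, 2, 3)),            # n_hidden_layers
)


class ConfigError(ValueError):
    pass


@dataclass
class GAConfig:
    population_size: int = 100
    n_generations: int = 20
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    migration_rate: float = 0.05
    elitism_count: int = 2
    fitness_metric: str = "test_accuracy"
    seed: int = 0
    max_epochs: int = 150
    patience: int = 20

    def __post_init__(self) -> None:
        for r in (self.crossover_rate, self.mutation_rate, self.migration_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"rate {r} outside [0, 1]")
        if self.elitism_count >= self.population_size:
            raise ConfigError("elitism_count must be < population_size")
        if self.fitness_metric not in ("test_accuracy", "validation_accuracy"):
            raise ConfigError(f"unknown fitness metric {self.fitness_metric!r}")


@dataclass
class GAResult:
    best: Architecture
    best_fitness: float
    per_generation: list[dict] = field(default_factory=list)
    evaluated_count: int = 0
    ranked: list[tuple[Architecture, float]] = field(default_factory=list)

    def top(self, k: int) -> list[tuple[Architecture, float]]:
        """The k best distinct architectures over the whole run."""
        return self.ranked[:k]


def _draw_gene(domain, rng: np.random.Generator):
    if domain[0] == "int":
        return int(rng.integers(domain[1], domain[2] + 1))
    return domain[1][int(rng.integers(len(domain[1])))]


def random_architecture(seed_or_rng) -> Architecture:
    """A uniformly random chromosome (deterministic for an int seed)."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return Architecture.from_genes([_draw_gene(d, rng) for d in _GENE_DOMAINS])


def _dataset_hash(features: np.ndarray, labels: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.asarray(features, dtype=np.float64)).tobytes())
    h.update(np.ascontiguousarray(np.asarray(labels, dtype=np.int64)).tobytes())
    return h.hexdigest()


class FitnessEvaluator:
    """Trains an architecture on the stratified 70/15/15 split and scores it."""

    def __init__(self, features: np.ndarray, labels: np.ndarray,
                 metric: str = "test_accuracy", seed: int = 0,
                 max_epochs: int = 150, patience: int = 20):
        self.features = np.asarray(features, dtype=np.float64)
        self.labels = np.asarray(labels)
        self.metric = metric
        self.seed = seed
        self.max_epochs = max_epochs
        self.patience = patience
        self.split = split_dataset(self.features, self.labels, seed=seed)
        self._hash = _dataset_hash(self.features, self.labels)
        self._cache: dict[tuple, float] = {}
        self.evaluated_count = 0

    def __call__(self, arch: Architecture) -> float:
        key = (arch.genes, self._hash, self.seed)
        if key in self._cache:
            return self._cache[key]
        train, val, test = self.split
        try:
            ann = train_ann(train, val, arch, seed=self.seed,
                            max_epochs=self.max_epochs, patience=self.patience)
            holdout = test if self.metric == "test_accuracy" else val
            fit = accuracy(ann, holdout[0], holdout[1])
        except Exception:  # divergence counts as fitness 0
            fit = 0.0
        self._cache[key] = fit
        self.evaluated_count += 1
        return fit

    def train_best(self, arch: Architecture, seed: Optional[int] = None):
        train, val, _ = self.split
        return train_ann(train, val, arch, seed=self.seed if seed is None else seed,
                         max_epochs=self.max_epochs, patience=self.patience)


def _crossover(a: Architecture, b: Architecture, rng: np.random.Generator) -> Architecture:
    mask = rng.random(9) < 0.5
    genes = [ga if m else gb for ga, gb, m in zip(a.genes, b.genes, mask)]
    return Architecture.from_genes(genes)


def _mutate(arch: Architecture, rate: float, rng: np.random.Generator) -> Architecture:
    genes = list(arch.genes)
    for k, domain in enumerate(_GENE_DOMAINS):
        if rng.random() < rate:
            genes[k] = _draw_gene(domain, rng)
    return Architecture.from_genes(genes)


def evolve(config: GAConfig, features: np.ndarray, labels: np.ndarray,
           evaluator: Optional[FitnessEvaluator] = None) -> GAResult:
    """Run the generational GA and return the fittest architecture.

    With ``elitism_count >= 1`` the best-fitness trace is non-decreasing.
    Reproducible bit-for-bit from ``config.seed`` and the dataset.
    """
    if config.n_generations < 1:
        raise ConfigError("n_generations must be >= 1")
    rng = np.random.default_rng(config.seed)
    if evaluator is None:
        evaluator = FitnessEvaluator(features, labels, metric=config.fitness_metric,
                                     seed=config.seed, max_epochs=config.max_epochs,
                                     patience=config.patience)
    pop = [random_architecture(rng) for _ in range(config.population_size)]
    trace: list[dict] = []
    all_scores: dict[tuple, tuple[Architecture, float]] = {}

    for gen in range(config.n_generations):
        fits = np.array([evaluator(a) for a in pop])
        for a, f in zip(pop, fits):
            all_scores[a.genes] = (a, float(f))
        order = np.argsort(-fits, kind="stable")
        trace.append({"generation": gen,
                      "best_fitness": float(fits[order[0]]),
                      "mean_fitness": float(fits.mean())})
        if gen == config.n_generations - 1:
            break
        elites = [pop[i] for i in order[:config.elitism_count]]
        n_migrants = int(round(config.migration_rate * config.population_size))
        n_children = config.population_size - len(elites) - n_migrants

        def tournament() -> Architecture:
            idx = rng.integers(0, len(pop), size=3)
            return pop[int(idx[np.argmax(fits[idx])])]

        children = []
        for _ in range(n_children):
            p1, p2 = tournament(), tournament()
            child = _crossover(p1, p2, rng) if rng.random() < config.crossover_rate else p1
            children.append(_mutate(child, config.mutation_rate, rng))
        migrants = [random_architecture(rng) for _ in range(n_migrants)]
        pop = elites + children + migrants

    ranked = sorted(all_scores.values(), key=lambda t: -t[1])
    best, best_fit = ranked[0]
    return GAResult(best=best, best_fitness=best_fit, per_generation=trace,
                    evaluated_count=evaluator.evaluated_count, ranked=ranked)
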