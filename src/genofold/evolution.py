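"""The genetic-folding life cycle.

A population of random kernel expressions (encoded as linear chromosomes)
is evolved by fitness-proportionate (roulette-wheel) selection and
symbol-only point mutation -- there is no crossover; mutation alone drives
variation.  Fitness is the mean stratified k-fold cross-validated accuracy
of a precomputed-kernel SVM trained on the candidate kernel's repaired Gram
matrix.  One elite individual is copied unchanged each generation, so the
best fitness trajectory is non-decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from . import kernel_lang as kl
from .data import Dataset
from .evaluation import stratified_kfold
from .kernel_lang import (
    GFChromosome,
    Gene,
    GramMatrix,
    KernelExpression,
    decode,
    encode,
    gram,
    gram_unit_scale,
    normalize_gram,
    random_expression,
    repair_gram,
)

__all__ = [
    "EvolutionConfig",
    "FitnessRecord",
    "GenerationStats",
    "EvolutionResult",
    "fitness",
    "roulette_select",
    "mutate",
    "subtree_mutate",
    "evolve",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the evolutionary search.

    Defaults follow the standard experimental settings for this strategy:
    population 50, 20 generations, per-gene mutation rate 0.5, 5-fold
    fitness CV.  ``repair`` is the Gram repair applied before SVM training
    (``clip`` zeroes negative eigenvalues; ``symmetrize`` only averages
    with the transpose).  ``subtree_mutation`` optionally regenerates a
    random subtree in addition to symbol mutation; off by default since
    symbol-only mutation is the canonical variation operator here.
    """

    population_size: int = 50
    max_generations: int = 20
    mutation_rate: float = 0.5
    max_depth: int = 4
    operators: tuple[str, ...] = kl.OPERATORS
    terminals: tuple[str, ...] = kl.TERMINALS
    elitism: int = 1
    svm_C: float = 1.0
    cv_folds: int = 5
    seed: int = 0
    repair: str = "clip"
    class_weight: Optional[str] = None
    cosine_normalize: bool = False
    early_stop: Optional[int] = None
    subtree_mutation: bool = False
    subtree_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.elitism < 0 or self.elitism > self.population_size:
            raise ValueError("elitism must lie in [0, population_size]")
        if self.repair not in ("clip", "symmetrize"):
            raise ValueError(f"unknown repair mode {self.repair!r}")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitnessRecord:
    chromosome: GFChromosome
    fitness: float
    complexity: int


@dataclass
class GenerationStats:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_complexity: int


@dataclass
class EvolutionResult:
    best: FitnessRecord
    history: list[GenerationStats]
    generations_run: int

    @property
    def best_expression(self) -> KernelExpression:
        return decode(self.best.chromosome)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame([asdict(h) for h in self.history])


def fitness(chrom: GFChromosome, dataset: Dataset, cfg: EvolutionConfig) -> float:
    """Cross-validated SVM accuracy of a candidate kernel, in [0, 1].

    Invalid kernels -- non-finite Gram entries or a (near-)constant Gram --
    score 0 by contract rather than being silently patched.
    """
    y = dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("fitness needs both classes present")
    expr = decode(chrom)
    G = gram(expr, dataset.X)
    if not G.valid:
        return 0.0
    K = (G.values + G.values.T) / 2.0
    if np.ptp(K) < 1e-12:
        return 0.0
    if cfg.cosine_normalize:
        Gn = normalize_gram(GramMatrix(K))
        if not Gn.valid:
            return 0.0
        K = Gn.values
    else:
        K = K / gram_unit_scale(K)
    folds = stratified_kfold(y, cfg.cv_folds, seed=cfg.seed)
    accs = []
    for tr, te in folds:
        Ktr = repair_gram(GramMatrix(K[np.ix_(tr, tr)]), cfg.repair).values
        svc = SVC(
            C=cfg.svm_C,
            kernel="precomputed",
            class_weight=cfg.class_weight,
            max_iter=1_000_000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svc.fit(Ktr, y[tr])
        pred = svc.predict(K[np.ix_(te, tr)])
        accs.append(float(np.mean(pred == y[te])))
    return float(np.mean(accs))


def roulette_select(population: Sequence[FitnessRecord], rng) -> GFChromosome:
    """Fitness-proportionate parent selection; uniform when all fitness is 0."""
    if not population:
        raise ValueError("cannot select from an empty population")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    f = np.array([max(r.fitness, 0.0) for r in population], dtype=float)
    total = f.sum()
    p = f / total if total > 0 else np.full(len(f), 1.0 / len(f))
    idx = int(rng.choice(len(population), p=p))
    return population[idx].chromosome


def mutate(
    chrom: GFChromosome,
    rate: float,
    rng,
    operators: Sequence[str] = kl.OPERATORS,
    terminals: Sequence[str] = kl.TERMINALS,
) -> GFChromosome:
    """Symbol-only point mutation: links never change, so validity is preserved.

    Independently per gene with probability ``rate``, an operator symbol is
    replaced by a uniformly drawn *different* operator and a terminal by a
    different terminal.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    operators = tuple(operators)
    terminals = tuple(terminals)
    genes = []
    for g in chrom.genes:
        sym = g.symbol
        if rng.random() < rate:
            pool = tuple(
                s for s in (terminals if g.is_terminal else operators) if s != sym
            )
            if pool:
                sym = pool[rng.integers(len(pool))]
        genes.append(Gene(g.position, sym, g.link))
    return GFChromosome(tuple(genes))


def subtree_mutate(
    chrom: GFChromosome,
    rng,
    max_depth: int = 4,
    operators: Sequence[str] = kl.OPERATORS,
    terminals: Sequence[str] = kl.TERMINALS,
) -> GFChromosome:
    """Structural mutation: replace a uniformly chosen node's subtree."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    expr = decode(chrom)
    nodes: list[tuple[KernelExpression, int]] = []

    def collect(node: KernelExpression, depth: int) -> None:
        nodes.append((node, depth))
        for c in node.children:
            collect(c, depth + 1)

    collect(expr, 0)
    target, depth = nodes[rng.integers(len(nodes))]
    replacement = random_expression(
        max(max_depth - depth, 0), operators, terminals, rng
    )

    def rebuild(node: KernelExpression) -> KernelExpression:
        if node is target:
            return replacement
        if node.is_leaf:
            return node
        return KernelExpression(node.symbol, tuple(rebuild(c) for c in node.children))

    return encode(rebuild(expr))


def evolve(dataset: Dataset, cfg: Optional[EvolutionConfig] = None) -> EvolutionResult:
    """Run the full life cycle and return the best kernel found.

    Fully reproducible for a fixed seed: initialization, selection and
    mutation all draw from one seeded generator, and fitness is
    deterministic given the dataset.  Ties in fitness break toward lower
    complexity, then earlier discovery.
    """
    cfg = cfg if cfg is not None else EvolutionConfig()
    rng = np.random.default_rng(cfg.seed)
    cache: dict[str, float] = {}

    def make_record(ch: GFChromosome) -> FitnessRecord:
        key = ch.to_text()
        if key not in cache:
            cache[key] = fitness(ch, dataset, cfg)
        return FitnessRecord(ch, cache[key], decode(ch).complexity)

    records = [
        make_record(
            encode(random_expression(cfg.max_depth, cfg.operators, cfg.terminals, rng))
        )
        for _ in range(cfg.population_size)
    ]

    history: list[GenerationStats] = []
    best_overall: Optional[FitnessRecord] = None
    stall = 0
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        ranked = sorted(
            range(len(records)),
            key=lambda i: (-records[i].fitness, records[i].complexity, i),
        )
        best = records[ranked[0]]
        history.append(
            GenerationStats(
                gen,
                best.fitness,
                float(np.mean([r.fitness for r in records])),
                best.complexity,
            )
        )
        if best_overall is None or (best.fitness, -best.complexity) > (
            best_overall.fitness,
            -best_overall.complexity,
        ):
            if best_overall is not None and best.fitness > best_overall.fitness + 1e-12:
                stall = 0
            best_overall = best
        else:
            stall += 1
        if gen == cfg.max_generations:
            break
        if cfg.early_stop is not None and stall >= cfg.early_stop:
            break
        elites = [records[i] for i in ranked[: cfg.elitism]]
        children = []
        for _ in range(cfg.population_size - len(elites)):
            child = mutate(
                roulette_select(records, rng),
                cfg.mutation_rate,
                rng,
                cfg.operators,
                cfg.terminals,
            )
            if cfg.subtree_mutation and rng.random() < cfg.subtree_rate:
                child = subtree_mutate(
                    child, rng, cfg.max_depth, cfg.operators, cfg.terminals
                )
            children.append(child)
        records = elites + [make_record(c) for c in children]

    assert best_overall is not None
    return EvolutionResult(best=best_overall, history=history, generations_run=gen)
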