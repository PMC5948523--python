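"""Generational grammatical-evolution loop with fitness sharing.

Selection runs on the similarity-adjusted fitness ``fa`` while elites and the
hall of fame are ranked by the nominal fitness ``fn``.  Crossover is forced
into the effective (actually decoded) region of both parents, and mutation
touches every non-elite individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .grammar import (
    Chromosome,
    DerivationResult,
    GrammarDef,
    TopologySpec,
    decode,
    phenotype_to_text,
    random_chromosome,
)

__all__ = [
    "EvolutionConfig",
    "Individual",
    "HallOfFame",
    "GenerationStats",
    "similarity",
    "adjust_fitness",
    "tournament_select",
    "crossover",
    "mutate",
    "update_hall_of_fame",
    "evolve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvolutionConfig:
    population_size: int = 50
    max_generations: int = 100
    stall_generations: int = 30
    tournament_size: int = 3
    crossover_rate: float = 0.7
    mutation_rate: float = 0.015
    elite_size: int = 1
    codon_size: int = 256
    chromosome_capacity: int = 100
    hall_of_fame_size: int = 20
    seed: int = 0
    memoize_fitness: bool = True
    consume_single: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 1 <= self.tournament_size <= self.population_size:
            raise ValueError("tournament_size must be in [1, population_size]")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0 <= self.elite_size < self.population_size:
            raise ValueError("elite_size must be in [0, population_size)")


@dataclass
class Individual:
    chromosome: Chromosome
    derivation: DerivationResult
    nominal_fitness: float | None = None   # fn
    adjusted_fitness: float | None = None  # fa

    @property
    def phenotype(self) -> TopologySpec | None:
        return self.derivation.phenotype

    @property
    def effective_length(self) -> int:
        """Codons actually consumed; whole chromosome if incomplete."""
        if self.derivation.complete:
            return self.derivation.codons_used
        return len(self.chromosome)


def similarity(a: Individual, b: Individual) -> float:
    """Fraction of positionally aligned hyperparameter slots with identical
    values; 0 when the conv or dense layer counts differ."""
    sa, sb = a.phenotype, b.phenotype
    if sa is None or sb is None:
        raise ValueError("similarity requires complete derivations")
    if sa.n_conv != sb.n_conv or sa.n_dense != sb.n_dense:
        return 0.0
    slots_a, slots_b = sa.slots(), sb.slots()
    matches = sum(x == y for x, y in zip(slots_a, slots_b))
    return matches / len(slots_a)


def adjust_fitness(population: Sequence[Individual]) -> None:
    """Set ``fa(i) = fn(i) * (1 - sum_{j != i} sim(i, j) / (|P| - 1))``.

    Individuals with incomplete derivations count as dissimilar to everyone.
    With a single-member population ``fa := fn``.
    """
    n = len(population)
    if n == 1:
        population[0].adjusted_fitness = population[0].nominal_fitness
        return
    sims = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if population[i].phenotype is None or population[j].phenotype is None:
                s = 0.0
            else:
                s = similarity(population[i], population[j])
            sims[i, j] = sims[j, i] = s
    penalties = sims.sum(axis=1) / (n - 1)
    for ind, penalty in zip(population, penalties):
        if ind.nominal_fitness is None:
            raise ValueError("adjust_fitness requires evaluated individuals")
        ind.adjusted_fitness = ind.nominal_fitness * (1.0 - penalty)


def _argmax_random_tie(values: Sequence[float], rng: np.random.Generator) -> int:
    arr = np.asarray(values, dtype=float)
    best = arr.max()
    candidates = np.flatnonzero(arr == best)
    return int(rng.choice(candidates))


def tournament_select(
    population: Sequence[Individual],
    tournament_size: int,
    rng: np.random.Generator,
    *,
    fitness_key: Callable[[Individual], float] | None = None,
) -> Individual:
    """Best-of-``tournament_size`` selection, drawn with replacement; ties
    broken uniformly at random."""
    if not population:
        raise ValueError("population is empty")
    key = fitness_key or (lambda ind: ind.adjusted_fitness)
    idx = rng.integers(0, len(population), size=tournament_size)
    contenders = [population[i] for i in idx]
    winner = _argmax_random_tie([key(c) for c in contenders], rng)
    return contenders[winner]


def crossover(
    p1: Individual,
    p2: Individual,
    crossover_rate: float,
    rng: np.random.Generator,
) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover restricted to the effective codon region.

    The cut point is drawn uniformly from ``[1, min(used) - 1]`` so the
    exchange always alters decoded material.  With probability
    ``1 - crossover_rate`` (or when no valid cut point exists) copies of the
    parents are returned.
    """
    c1, c2 = p1.chromosome, p2.chromosome
    limit = min(p1.effective_length, p2.effective_length)
    if rng.random() >= crossover_rate or limit < 2:
        return c1, c2
    cut = int(rng.integers(1, limit))
    child1 = replace(c1, codons=c1.codons[:cut] + c2.codons[cut:])
    child2 = replace(c2, codons=c2.codons[:cut] + c1.codons[cut:])
    return child1, child2


def mutate(
    chromosome: Chromosome,
    mutation_rate: float,
    rng: np.random.Generator,
) -> Chromosome:
    """Integer-flipping mutation: each codon is independently replaced with
    probability ``mutation_rate`` by a uniform draw from ``[0, codon_size)``."""
    n = len(chromosome)
    if n == 0 or mutation_rate == 0.0:
        return chromosome
    hits = rng.random(n) < mutation_rate
    if not hits.any():
        return chromosome
    codons = np.array(chromosome.codons)
    codons[hits] = rng.integers(0, chromosome.codon_size, size=int(hits.sum()))
    return replace(chromosome, codons=tuple(int(c) for c in codons))


@dataclass
class HallOfFameEntry:
    phenotype: TopologySpec
    chromosome: Chromosome
    nominal_fitness: float


@dataclass
class HallOfFame:
    max_size: int = 20
    entries: list[HallOfFameEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def update_hall_of_fame(hof: HallOfFame, ind: Individual) -> HallOfFame:
    """Insert an evaluated individual, keeping entries sorted by ``fn``
    descending, deduplicated by phenotype, and capped at ``max_size``."""
    if ind.phenotype is None or ind.nominal_fitness is None:
        return hof
    for i, entry in enumerate(hof.entries):
        if entry.phenotype == ind.phenotype:
            if ind.nominal_fitness > entry.nominal_fitness:
                hof.entries[i] = HallOfFameEntry(
                    ind.phenotype, ind.chromosome, ind.nominal_fitness
                )
                hof.entries.sort(key=lambda e: -e.nominal_fitness)
            return hof
    if len(hof.entries) >= hof.max_size:
        if ind.nominal_fitness <= hof.entries[-1].nominal_fitness:
            return hof
    hof.entries.append(
        HallOfFameEntry(ind.phenotype, ind.chromosome, ind.nominal_fitness)
    )
    hof.entries.sort(key=lambda e: -e.nominal_fitness)
    del hof.entries[hof.max_size:]
    return hof


@dataclass(frozen=True)
class GenerationStats:
    generation: int
    best_nominal: float
    mean_nominal: float
    best_phenotype_text: str


def evolve(
    config: EvolutionConfig,
    fitness_fn: Callable[[TopologySpec], float],
    grammar: GrammarDef,
    rng: np.random.Generator | None = None,
) -> tuple[HallOfFame, list[GenerationStats]]:
    """Run the full loop and return the hall of fame plus per-generation
    history.

    Each generation: evaluate nominal fitness (incomplete derivations and
    raising fitness functions score 0), apply the similarity penalty, copy
    ``elite_size`` elites chosen by nominal fitness, and fill the rest by
    tournament selection on adjusted fitness followed by effective crossover
    and mutation.  Stops after ``max_generations`` or ``stall_generations``
    without improvement of the best nominal fitness.  Fitness is memoized by
    phenotype text unless ``memoize_fitness`` is off.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cache: dict[str, float] = {}

    def make_individual(chromosome: Chromosome) -> Individual:
        derivation = decode(chromosome, grammar, consume_single=config.consume_single)
        return Individual(chromosome=chromosome, derivation=derivation)

    def evaluate(ind: Individual) -> None:
        if ind.phenotype is None:
            ind.nominal_fitness = 0.0
            return
        key = phenotype_to_text(ind.phenotype)
        if config.memoize_fitness and key in cache:
            ind.nominal_fitness = cache[key]
            return
        try:
            fn = float(fitness_fn(ind.phenotype))
        except Exception:
            logger.exception("fitness function failed for %s; scoring 0", key)
            fn = 0.0
        ind.nominal_fitness = fn
        if config.memoize_fitness:
            cache[key] = fn

    population = [
        make_individual(
            random_chromosome(config.codon_size, config.chromosome_capacity, rng)
        )
        for _ in range(config.population_size)
    ]

    hof = HallOfFame(max_size=config.hall_of_fame_size)
    history: list[GenerationStats] = []
    best_so_far = -np.inf
    stall = 0

    for generation in range(config.max_generations):
        for ind in population:
            evaluate(ind)
        adjust_fitness(population)
        for ind in population:
            update_hall_of_fame(hof, ind)

        fns = [ind.nominal_fitness for ind in population]
        best_idx = _argmax_random_tie(fns, rng)
        best = population[best_idx]
        history.append(
            GenerationStats(
                generation=generation,
                best_nominal=best.nominal_fitness,
                mean_nominal=float(np.mean(fns)),
                best_phenotype_text=(
                    phenotype_to_text(best.phenotype) if best.phenotype else ""
                ),
            )
        )
        logger.info(
            "generation %d: best fn=%.4f mean fn=%.4f",
            generation, best.nominal_fitness, history[-1].mean_nominal,
        )

        if best.nominal_fitness > best_so_far:
            best_so_far = best.nominal_fitness
            stall = 0
        else:
            stall += 1
            if stall >= config.stall_generations:
                break
        if generation == config.max_generations - 1:
            break

        # elites by nominal fitness, random tie-breaks
        order = sorted(
            range(len(population)),
            key=lambda i: (-population[i].nominal_fitness, rng.random()),
        )
        next_pop = [population[i] for i in order[: config.elite_size]]
        while len(next_pop) < config.population_size:
            p1 = tournament_select(population, config.tournament_size, rng)
            p2 = tournament_select(population, config.tournament_size, rng)
            child1, child2 = crossover(p1, p2, config.crossover_rate, rng)
            for child in (child1, child2):
                if len(next_pop) >= config.population_size:
                    break
                mutated = mutate(child, config.mutation_rate, rng)
                next_pop.append(make_individual(mutated))
        population = next_pop

    return hof, history
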