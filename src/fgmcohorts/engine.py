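"""Wright-Fisher generation cycle with genotype-class bookkeeping.

One generation = fitness-weighted multinomial resampling of the N
offspring (selection + drift in one draw), followed by Poisson mutational
input in the newborns.  The population is stored as genotype *classes* —
distinct sets of segregating mutations with a shared phenotype — so the
per-generation cost scales with the number of distinct genotypes, not
with N.  A naive per-individual engine (``reference_step``) implements
the identical model without aggregation and serves as a distributional
oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    ModelParams,
    initial_phenotype,
    log_fitness,
    sample_mutation,
)
from .results import MeanFitnessRow, SimulationResult
from .tracker import (
    MutationRegistry,
    census,
    detect_fixation_and_loss,
    make_fixation_event,
    prune_fixed,
    record_trajectories,
)

__all__ = [
    "GenotypeClass",
    "Population",
    "init_population",
    "selection_drift_step",
    "mutation_step",
    "advance_generation",
    "run_simulation",
    "Individual",
    "init_individuals",
    "reference_step",
]


@dataclass
class GenotypeClass:
    """A distinct genotype: its segregating mutations, phenotype and count.

    ``mutation_ids`` excludes the fixed background; ``logw`` caches the
    log-fitness of ``phenotype``.
    """

    class_id: int
    mutation_ids: frozenset[int]
    phenotype: np.ndarray
    logw: float
    count: int


@dataclass
class Population:
    """All genotype classes at one census, plus the fixed background."""

    generation: int
    classes: list[GenotypeClass]
    fixed_ids: set[int]
    params: ModelParams
    next_class_id: int = 1

    @property
    def size(self) -> int:
        return sum(c.count for c in self.classes)

    def mean_fitness(self) -> float:
        tot = 0.0
        for c in self.classes:
            tot += c.count * np.exp(c.logw)
        return tot / self.params.N

    def max_fitness(self) -> float:
        return float(np.exp(max(c.logw for c in self.classes)))

    def new_class_id(self) -> int:
        i = self.next_class_id
        self.next_class_id += 1
        return i

    def dedupe_classes(self) -> None:
        """Merge classes that share the same mutation set (summed counts)."""
        by_set: dict[frozenset[int], GenotypeClass] = {}
        for c in self.classes:
            prev = by_set.get(c.mutation_ids)
            if prev is None:
                by_set[c.mutation_ids] = c
            else:
                prev.count += c.count
        if len(by_set) != len(self.classes):
            self.classes = list(by_set.values())


def init_population(params: ModelParams, rng: np.random.Generator) -> Population:
    """Monomorphic founding population at fitness w0."""
    z = initial_phenotype(params, rng)
    founder = GenotypeClass(
        class_id=0,
        mutation_ids=frozenset(),
        phenotype=z,
        logw=log_fitness(z),
        count=params.N,
    )
    return Population(generation=0, classes=[founder], fixed_ids=set(), params=params)


def selection_drift_step(pop: Population, rng: np.random.Generator) -> Population:
    """Resample class counts by one fitness-weighted multinomial draw.

    Offspring-class probabilities are proportional to ``count * w``; the
    exponentials are max-shifted so far-from-optimum genotypes cannot
    underflow to an all-zero weight vector.  Classes drawn to count 0 are
    dropped.
    """
    classes = pop.classes
    if len(classes) == 1:
        return pop  # degenerate multinomial: the single class keeps all N slots
    logw = np.array([c.logw for c in classes])
    counts = np.array([c.count for c in classes], dtype=float)
    w = np.exp(logw - logw.max())
    p = counts * w
    p /= p.sum()
    new_counts = rng.multinomial(pop.params.N, p)
    survivors = []
    for c, k in zip(classes, new_counts):
        if k > 0:
            c.count = int(k)
            survivors.append(c)
    pop.classes = survivors
    return pop


def mutation_step(
    pop: Population, rng: np.random.Generator, registry: MutationRegistry
) -> Population:
    """Poisson mutational input into the newborn generation.

    The total number of new mutations is one Poisson(N*U) draw; each is
    assigned to a uniformly random individual (so an individual can pick
    up two or more in one generation), which is distributionally identical
    to independent Poisson(U) draws per individual.  Every hit individual
    is split out of its class into a new single-individual class with the
    mutation(s) applied; the mutation's selection coefficient against its
    immediate parent genotype is recorded at origin.
    """
    params = pop.params
    M = rng.poisson(params.N * params.U)
    if M == 0:
        return pop
    targets = rng.integers(0, params.N, size=M)
    # Map individual slots onto classes via the cumulative counts at entry.
    cum = np.cumsum([c.count for c in pop.classes])
    class_pos = np.searchsorted(cum, targets, side="right")
    hits: dict[int, list[int]] = {}
    for t, cp in zip(targets.tolist(), class_pos.tolist()):
        hits.setdefault(t, []).append(cp)
    new_classes: list[GenotypeClass] = []
    for _, positions in hits.items():
        parent = pop.classes[positions[0]]
        parent.count -= 1
        z = parent.phenotype.copy()
        ids = set(parent.mutation_ids)
        logw_parent = parent.logw
        for _ in positions:
            mut = sample_mutation(params, rng, registry.next_id(), pop.generation)
            idx = list(mut.trait_indices)
            z[idx] += mut.deltas
            logw_child = -float(z @ z)
            registry.add(mut, s_at_origin=float(np.exp(logw_child - logw_parent) - 1.0))
            logw_parent = logw_child
            ids.add(mut.id)
        new_classes.append(
            GenotypeClass(
                class_id=pop.new_class_id(),
                mutation_ids=frozenset(ids),
                phenotype=z,
                logw=logw_parent,
                count=1,
            )
        )
    pop.classes = [c for c in pop.classes if c.count > 0] + new_classes
    return pop


def advance_generation(
    pop: Population, rng: np.random.Generator, registry: MutationRegistry
) -> Population:
    """One full Wright-Fisher generation: resample, then mutate newborns."""
    selection_drift_step(pop, rng)
    mutation_step(pop, rng, registry)
    pop.generation += 1
    return pop


def _mean_fitness_row(pop: Population, registry: MutationRegistry) -> MeanFitnessRow:
    return MeanFitnessRow(
        generation=pop.generation,
        mean_w=pop.mean_fitness(),
        max_w=pop.max_fitness(),
        n_segregating=len(registry.active),
    )


def run_simulation(
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
    *,
    stop_after_fixations: Optional[int] = None,
) -> SimulationResult:
    """Drive one replicate from the founding census to the horizon.

    Each generation is advanced, censused, checked for fixations and
    losses, pruned, and recorded.  ``stop_after_fixations=k`` ends the run
    (as complete) right after the k-th fixation event — handy when only
    the first fixation is of interest.  An interrupt mid-run returns the
    partial result flagged ``complete=False``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pop = init_population(params, rng)
    registry = MutationRegistry()
    result = SimulationResult(params=params, replicate_seed=params.seed, registry=registry)
    result.mean_fitness.append(_mean_fitness_row(pop, registry))
    stop_reason = "horizon"
    try:
        for _ in range(params.generations):
            advance_generation(pop, rng, registry)
            gen = pop.generation
            counts = census(pop, registry)
            newly_fixed, newly_lost = detect_fixation_and_loss(
                counts, params.N, registry, gen
            )
            event = make_fixation_event(gen, newly_fixed)
            if event is not None:
                result.fixation_events.append(event)
                prune_fixed(pop, newly_fixed)
            result.trajectories.extend(
                record_trajectories(
                    counts,
                    params.N,
                    gen,
                    params.record_every,
                    force=event is not None,
                    lost_ids=newly_lost,
                )
            )
            if event is not None or gen % params.record_every == 0:
                result.mean_fitness.append(_mean_fitness_row(pop, registry))
            if (
                stop_after_fixations is not None
                and len(result.fixation_events) >= stop_after_fixations
            ):
                stop_reason = "fixations"
                break
    except KeyboardInterrupt:
        result.complete = False
        stop_reason = "interrupted"
    result.final_generation = pop.generation
    result.stop_reason = stop_reason
    if not result.mean_fitness or result.mean_fitness[-1].generation != pop.generation:
        result.mean_fitness.append(_mean_fitness_row(pop, registry))
    return result


# --------------------------------------------------------------------------
# Naive per-individual reference engine (test oracle).
# --------------------------------------------------------------------------


@dataclass
class Individual:
    """One individual in the naive engine: phenotype plus mutation set."""

    phenotype: np.ndarray
    mutation_ids: frozenset[int]
    logw: float


def init_individuals(params: ModelParams, rng: np.random.Generator) -> list[Individual]:
    z = initial_phenotype(params, rng)
    lw = log_fitness(z)
    return [Individual(z.copy(), frozenset(), lw) for _ in range(params.N)]


def reference_step(
    individuals: list[Individual],
    params: ModelParams,
    rng: np.random.Generator,
    registry: Optional[MutationRegistry] = None,
    generation: int = 0,
) -> list[Individual]:
    """One Wright-Fisher generation without class aggregation.

    Each offspring draws its parent with probability proportional to the
    parent's fitness, then receives an independent Poisson(U) number of
    new mutations.  Distributionally identical to one pass of
    :func:`selection_drift_step` + :func:`mutation_step`.
    """
    if len(individuals) != params.N:
        raise ValueError(f"expected exactly N={params.N} individuals")
    if registry is None:
        registry = MutationRegistry()
    logw = np.array([ind.logw for ind in individuals])
    w = np.exp(logw - logw.max())
    p = w / w.sum()
    parents = rng.choice(params.N, size=params.N, p=p)
    n_muts = rng.poisson(params.U, size=params.N)
    offspring: list[Individual] = []
    for par, k in zip(parents, n_muts):
        parent = individuals[par]
        if k == 0:
            offspring.append(Individual(parent.phenotype, parent.mutation_ids, parent.logw))
            continue
        z = parent.phenotype.copy()
        ids = set(parent.mutation_ids)
        lw = parent.logw
        for _ in range(int(k)):
            mut = sample_mutation(params, rng, registry.next_id(), generation)
            idx = list(mut.trait_indices)
            z[idx] += mut.deltas
            new_lw = -float(z @ z)
            registry.add(mut, s_at_origin=float(np.exp(new_lw - lw) - 1.0))
            lw = new_lw
            ids.add(mut.id)
        offspring.append(Individual(z, frozenset(ids), lw))
    return offspring
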