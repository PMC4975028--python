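"""Lineage bookkeeping: census, fixation/loss detection, cohort events.

Every de novo mutation is tracked from origin until it either reaches
carrier count ``N`` (fixation) or carrier count 0 (loss).  Mutations whose
first census at frequency 1 falls on the same generation form a *cohort*;
the cohort size is the quantity summarised downstream.  Fixed mutations
are pruned out of the segregating class sets into a fixed background —
the phenotypes already include their effect, so pruning changes nothing
but the bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .core import Mutation

__all__ = [
    "MutationRegistry",
    "RegistryEntry",
    "FixationEvent",
    "TrajectoryRecord",
    "census",
    "detect_fixation_and_loss",
    "make_fixation_event",
    "prune_fixed",
    "record_trajectories",
]

SEGREGATING = "segregating"
FIXED = "fixed"
LOST = "lost"


@dataclass
class RegistryEntry:
    """Fate record for a single mutation (no back mutation: one-way)."""

    mutation: Mutation
    status: str = SEGREGATING
    fixation_generation: Optional[int] = None
    loss_generation: Optional[int] = None
    s_at_origin: float = 0.0


@dataclass(frozen=True)
class FixationEvent:
    """One census at which >= 1 mutation first reached frequency 1."""

    generation: int
    mutation_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.mutation_ids:
            raise ValueError("a fixation event needs at least one mutation")

    @property
    def cohort_size(self) -> int:
        return len(self.mutation_ids)


@dataclass(frozen=True)
class TrajectoryRecord:
    generation: int
    mutation_id: int
    frequency: float


class MutationRegistry:
    """Map id -> fate of every mutation created during a run.

    Statuses move only segregating -> fixed or segregating -> lost.
    """

    def __init__(self) -> None:
        self.entries: dict[int, RegistryEntry] = {}
        self.active: set[int] = set()
        self._next_id = 0

    def next_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def add(self, mutation: Mutation, s_at_origin: float) -> None:
        if mutation.id in self.entries:
            raise ValueError(f"mutation id {mutation.id} already registered")
        self.entries[mutation.id] = RegistryEntry(mutation, s_at_origin=s_at_origin)
        self.active.add(mutation.id)

    def mark_fixed(self, ids: Iterable[int], generation: int) -> None:
        for i in ids:
            e = self.entries[i]
            if e.status != SEGREGATING:
                raise ValueError(f"mutation {i} is {e.status}; cannot fix")
            e.status = FIXED
            e.fixation_generation = generation
            self.active.discard(i)

    def mark_lost(self, ids: Iterable[int], generation: int) -> None:
        for i in ids:
            e = self.entries[i]
            if e.status != SEGREGATING:
                raise ValueError(f"mutation {i} is {e.status}; cannot lose")
            e.status = LOST
            e.loss_generation = generation
            self.active.discard(i)

    def status_counts(self) -> dict[str, int]:
        out = {SEGREGATING: 0, FIXED: 0, LOST: 0}
        for e in self.entries.values():
            out[e.status] += 1
        return out

    def __len__(self) -> int:
        return len(self.entries)


def census(pop, registry: MutationRegistry | None = None) -> dict[int, int]:
    """Carrier count of every segregating mutation at this instant.

    A mutation's count is the summed count of every genotype class whose
    set contains it.  With a registry, segregating ids absent from all
    classes are reported explicitly with count 0 (they are about to be
    declared lost).
    """
    counts: dict[int, int] = {}
    if registry is not None:
        counts = dict.fromkeys(registry.active, 0)
    get = counts.get
    for cls in pop.classes:
        c = cls.count
        for mid in cls.mutation_ids:
            counts[mid] = get(mid, 0) + c
    return counts


def detect_fixation_and_loss(
    counts: Mapping[int, int],
    N: int,
    registry: MutationRegistry,
    generation: int,
) -> tuple[set[int], set[int]]:
    """Split the current census into newly fixed and newly lost mutations.

    Fixation is carrier count exactly ``N``; loss is count 0.  Registry
    statuses and fate generations are updated in place.
    """
    newly_fixed: set[int] = set()
    newly_lost: set[int] = set()
    for mid in registry.active:
        c = counts.get(mid, 0)
        if c > N:
            raise RuntimeError(f"mutation {mid} has count {c} > N={N}")
        if c == N:
            newly_fixed.add(mid)
        elif c == 0:
            newly_lost.add(mid)
    registry.mark_fixed(newly_fixed, generation)
    registry.mark_lost(newly_lost, generation)
    return newly_fixed, newly_lost


def make_fixation_event(generation: int, newly_fixed: set[int]) -> FixationEvent | None:
    """Group this census's co-fixing mutations into one cohort event."""
    if not newly_fixed:
        return None
    return FixationEvent(generation=generation, mutation_ids=frozenset(newly_fixed))


def prune_fixed(pop, newly_fixed: set[int]):
    """Move fixed mutations from the class sets into the fixed background.

    Every individual carries a fixed mutation, so removing its id from
    each class leaves phenotypes (and hence fitness) untouched.  Classes
    whose sets collide after shrinkage are merged with summed counts.
    """
    if not newly_fixed:
        return pop
    for cls in pop.classes:
        if not newly_fixed <= cls.mutation_ids:
            missing = newly_fixed - cls.mutation_ids
            raise RuntimeError(f"cannot prune non-fixed mutation(s) {sorted(missing)}")
    for cls in pop.classes:
        cls.mutation_ids = cls.mutation_ids - newly_fixed
    pop.fixed_ids |= newly_fixed
    pop.dedupe_classes()
    return pop


def record_trajectories(
    counts: Mapping[int, int],
    N: int,
    generation: int,
    cadence: int,
    *,
    force: bool = False,
    lost_ids: Iterable[int] = (),
) -> list[TrajectoryRecord]:
    """Frequency records for this census, honouring the recording cadence.

    Emits (generation, id, count/N) for every carried mutation when the
    generation falls on the cadence or ``force`` is set (used so fixation
    censuses always appear in outputs).  ``lost_ids`` get an explicit final
    0.0 record regardless of cadence, so losses are never silent.
    """
    if cadence < 1:
        raise ValueError(f"cadence must be >= 1, got {cadence!r}")
    records: list[TrajectoryRecord] = []
    if force or generation % cadence == 0:
        for mid, c in counts.items():
            if c > 0:
                records.append(TrajectoryRecord(generation, mid, c / N))
    for mid in lost_ids:
        records.append(TrajectoryRecord(generation, mid, 0.0))
    return records
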