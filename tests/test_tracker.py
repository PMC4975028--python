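"""Lineage census, fixation/loss detection, cohorts and pruning."""

import numpy as np
import pytest

from fgmcohorts import (
    FixationEvent,
    GenotypeClass,
    ModelParams,
    Mutation,
    MutationRegistry,
    Population,
    census,
    detect_fixation_and_loss,
    make_fixation_event,
    prune_fixed,
    record_trajectories,
    run_simulation,
)


def build_pop(class_specs, params):
    """class_specs: list of (mutation id set, count)."""
    classes = [
        GenotypeClass(i, frozenset(ids), np.zeros(params.n), 0.0, count)
        for i, (ids, count) in enumerate(class_specs)
    ]
    return Population(generation=0, classes=classes, fixed_ids=set(),
                      params=params, next_class_id=len(classes))


def registry_with(ids):
    reg = MutationRegistry()
    for i in ids:
        reg._next_id = i
        reg.add(Mutation(i, 0, (0,), (0.0,)), s_at_origin=0.0)
    return reg


@pytest.fixture
def params():
    return ModelParams(n=2, m=1, sigma2=0.001, U=0.0, N=7, generations=1)


def test_census_sums_over_classes(params):
    pop = build_pop([({1}, 3), ({1, 2}, 4)], params)
    reg = registry_with([1, 2, 9])
    counts = census(pop, reg)
    assert counts == {1: 7, 2: 4, 9: 0}


def test_census_monomorphic(params):
    pop = build_pop([({7}, 7)], params)
    assert census(pop)[7] == params.N
    assert census(build_pop([(set(), 7)], params)) == {}


def test_detect_fixation_and_loss_updates_registry(params):
    pop = build_pop([({1}, 3), ({1, 2}, 4)], params)
    reg = registry_with([1, 2, 9])
    fixed, lost = detect_fixation_and_loss(census(pop, reg), params.N, reg, 42)
    assert fixed == {1} and lost == {9}
    assert reg.entries[1].status == "fixed"
    assert reg.entries[1].fixation_generation == 42
    assert reg.entries[9].status == "lost" and reg.entries[9].loss_generation == 42
    assert reg.entries[2].status == "segregating"
    assert reg.active == {2}


def test_count_n_minus_one_still_segregating(params):
    pop = build_pop([({1}, 6), (set(), 1)], params)
    reg = registry_with([1])
    fixed, lost = detect_fixation_and_loss(census(pop, reg), params.N, reg, 1)
    assert fixed == set() and lost == set()


def test_overfull_census_is_an_error(params):
    reg = registry_with([1])
    with pytest.raises(RuntimeError):
        detect_fixation_and_loss({1: params.N + 1}, params.N, reg, 1)


def test_fate_transitions_are_one_way(params):
    reg = registry_with([1])
    reg.mark_fixed({1}, 5)
    with pytest.raises(ValueError):
        reg.mark_lost({1}, 6)
    with pytest.raises(ValueError):
        reg.mark_fixed({1}, 6)


def test_make_fixation_event():
    assert make_fixation_event(10, set()) is None
    assert make_fixation_event(10, {4}).cohort_size == 1
    ev = make_fixation_event(10, {4, 5, 6})
    assert ev.cohort_size == 3 and ev.generation == 10
    with pytest.raises(ValueError):
        FixationEvent(3, frozenset())


def test_prune_fixed_moves_ids_to_background(params):
    pop = build_pop([({1, 2}, 3), ({1, 3}, 4)], params)
    reg = registry_with([1, 2, 3])
    prune_fixed(pop, {1})
    assert pop.fixed_ids == {1}
    assert census(pop, reg) == {1: 0, 2: 3, 3: 4}
    with pytest.raises(RuntimeError):
        prune_fixed(pop, {2})  # not carried by every class


def test_prune_preserves_counts_and_merges_duplicates(params):
    pop = build_pop([({1, 2}, 3), ({1, 2}, 4)], params)
    prune_fixed(pop, {1, 2})
    assert len(pop.classes) == 1 and pop.classes[0].count == 7
    assert pop.size == params.N


def test_record_trajectories_cadence_and_events():
    counts = {1: 5, 2: 0, 3: 10}
    recs = record_trajectories(counts, 10, generation=7, cadence=10)
    assert recs == []
    recs = record_trajectories(counts, 10, generation=20, cadence=10)
    assert {(r.mutation_id, r.frequency) for r in recs} == {(1, 0.5), (3, 1.0)}
    forced = record_trajectories(counts, 10, generation=7, cadence=10,
                                 force=True, lost_ids=[2])
    got = {(r.mutation_id, r.frequency) for r in forced}
    assert got == {(1, 0.5), (3, 1.0), (2, 0.0)}
    with pytest.raises(ValueError):
        record_trajectories(counts, 10, generation=1, cadence=0)


def test_every_mutation_ends_in_exactly_one_fate(small_params):
    res = run_simulation(small_params)
    tallies = res.registry.status_counts()
    assert sum(tallies.values()) == len(res.registry)
    gens = [e.generation for e in res.fixation_events]
    assert gens == sorted(set(gens))  # strictly increasing
    seen = set()
    for e in res.fixation_events:
        assert not (e.mutation_ids & seen)  # a mutation fixes at most once
        seen |= e.mutation_ids


def test_first_fixation_matches_trajectory_scan():
    """The earliest fixation event agrees with a brute-force scan of the
    full (cadence-1) trajectory table for the first frequency-1 census."""
    p = ModelParams.from_mean_effect(
        E_S=-0.02, m=2, n=2, U=0.01, N=300, w0=0.5,
        generations=2000, record_every=1, seed=5,
    )
    res = run_simulation(p, stop_after_fixations=1)
    assert res.fixation_events, "expected a fixation within the horizon"
    first = res.fixation_events[0]
    at_one = [r for r in res.trajectories if r.frequency == 1.0]
    gen = min(r.generation for r in at_one)
    ids = {r.mutation_id for r in at_one if r.generation == gen}
    assert gen == first.generation
    assert ids == set(first.mutation_ids)
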