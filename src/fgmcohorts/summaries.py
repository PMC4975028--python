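"""Replicate-level statistics: cohort-size distributions, fitness series,
segregating counts, and the observation-noise post-processor.

These are the quantities typically plotted from forward simulations of
adaptive walks: the size of the mutation cohort fixed at the first
fixation event across replicates, cohort sizes along the whole walk, the
mean-fitness trajectory, and mutation-frequency trajectories with
optional Gaussian "sequencing-like" noise added purely at output time.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .results import SimulationResult
from .tracker import TrajectoryRecord

__all__ = [
    "first_fixation_cohort_size",
    "cohort_size_distribution",
    "cohorts_along_walk",
    "mean_fitness_series",
    "segregating_count_series",
    "add_observation_noise",
]


def _check_same_params(results: Sequence[SimulationResult]) -> None:
    if not results:
        raise ValueError("need at least one simulation result")
    ref = results[0].params
    for r in results[1:]:
        a = {k: v for k, v in vars(ref).items() if k != "seed"}
        b = {k: v for k, v in vars(r.params).items() if k != "seed"}
        if a != b:
            raise ValueError(
                "results were produced under different parameters; "
                "aggregate replicates of one parameter set at a time"
            )


def first_fixation_cohort_size(result: SimulationResult) -> Optional[int]:
    """Cohort size of the earliest fixation event; None if nothing fixed."""
    if not result.fixation_events:
        return None
    return result.fixation_events[0].cohort_size


def cohort_size_distribution(
    results: Sequence[SimulationResult],
) -> tuple[dict[int, float], int]:
    """Empirical distribution of first-fixation cohort sizes over replicates.

    Returns ``(histogram, n_no_fixation)``: the histogram is normalised
    over the replicates that had at least one fixation; replicates without
    any fixation within their horizon are counted separately, never
    silently dropped.
    """
    _check_same_params(results)
    sizes = [first_fixation_cohort_size(r) for r in results]
    none_count = sum(1 for s in sizes if s is None)
    observed = [s for s in sizes if s is not None]
    if not observed:
        return {}, none_count
    hist: dict[int, float] = {}
    for s in observed:
        hist[s] = hist.get(s, 0) + 1
    total = len(observed)
    return {k: v / total for k, v in sorted(hist.items())}, none_count


def cohorts_along_walk(result: SimulationResult) -> list[tuple[int, int]]:
    """Chronological (generation, cohort size) for every fixation event."""
    return [(e.generation, e.cohort_size) for e in result.fixation_events]


def mean_fitness_series(results: Sequence[SimulationResult]) -> pd.DataFrame:
    """Across-replicate mean fitness on the common recorded generation grid.

    Columns: generation, mean_w (pointwise average across replicates),
    se_w (across-replicate standard error; 0 for a single replicate),
    n_replicates.  Generations recorded in only some replicates (event
    censuses) are restricted to the grid common to all.
    """
    _check_same_params(results)
    per_rep = []
    for r in results:
        s = pd.Series(
            {row.generation: row.mean_w for row in r.mean_fitness}, name="mean_w"
        )
        per_rep.append(s[~s.index.duplicated(keep="last")])
    common = per_rep[0].index
    for s in per_rep[1:]:
        common = common.intersection(s.index)
    common = common.sort_values()
    mat = np.vstack([s.loc[common].to_numpy() for s in per_rep])
    k = len(results)
    se = mat.std(axis=0, ddof=1) / np.sqrt(k) if k > 1 else np.zeros(mat.shape[1])
    return pd.DataFrame(
        {
            "generation": common.to_numpy(),
            "mean_w": mat.mean(axis=0),
            "se_w": se,
            "n_replicates": k,
        }
    )


def segregating_count_series(result: SimulationResult) -> list[tuple[int, int]]:
    """(generation, number of distinct segregating mutations) at each record."""
    return [(row.generation, row.n_segregating) for row in result.mean_fitness]


def add_observation_noise(
    trajectories: Iterable[TrajectoryRecord],
    variance: float,
    rng: np.random.Generator,
) -> list[TrajectoryRecord]:
    """Perturb recorded frequencies by iid Normal(0, variance), clipped to [0, 1].

    Mimics measurement error of experimentally assayed allele frequencies;
    applied only to the output table, never fed back into the simulation.
    The input records are left untouched.
    """
    if variance < 0:
        raise ValueError(f"noise variance must be >= 0, got {variance!r}")
    records = list(trajectories)
    if variance == 0 or not records:
        return list(records)
    sd = float(np.sqrt(variance))
    noise = rng.normal(0.0, sd, size=len(records))
    out = []
    for rec, eps in zip(records, noise):
        f = min(1.0, max(0.0, rec.frequency + eps))
        out.append(TrajectoryRecord(rec.generation, rec.mutation_id, f))
    return out
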