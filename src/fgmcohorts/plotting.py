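"""Figure helpers: mean-fitness dynamics, cohort-size histograms, cohort
sizes along the walk, and mutation-frequency trajectories."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_mean_fitness(series: pd.DataFrame, ax: Optional[plt.Axes] = None, *, band: bool = True):
    """Mean-fitness trajectory with an optional across-replicate SE band."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series["generation"], series["mean_w"], lw=1.5)
    if band and (series["se_w"] > 0).any():
        ax.fill_between(
            series["generation"],
            series["mean_w"] - series["se_w"],
            series["mean_w"] + series["se_w"],
            alpha=0.3,
        )
    ax.set_xlabel("generation")
    ax.set_ylabel("mean fitness")
    return ax


def plot_cohort_histogram(hist: dict[int, float], none_count: int = 0, ax=None):
    """First-fixation cohort-size distribution across replicates."""
    if ax is None:
        _, ax = plt.subplots()
    sizes = sorted(hist)
    ax.bar(sizes, [hist[s] for s in sizes], width=0.8)
    ax.set_xlabel("cohort size at first fixation")
    ax.set_ylabel("probability")
    if none_count:
        ax.set_title(f"{none_count} replicate(s) without fixation excluded")
    return ax


def plot_cohorts_along_walk(events: Sequence[tuple[int, int]], ax=None):
    """Scatter of (generation, cohort size) for every fixation event."""
    if ax is None:
        _, ax = plt.subplots()
    if events:
        gens, sizes = zip(*events)
        ax.scatter(gens, sizes, s=12, alpha=0.7)
    ax.set_xlabel("generation of fixation")
    ax.set_ylabel("cohort size")
    return ax


def plot_trajectories(table: pd.DataFrame, ax=None, max_mutations: Optional[int] = None):
    """Frequency trajectory of each mutation (one line per mutation id)."""
    if ax is None:
        _, ax = plt.subplots()
    ids = table["mutation_id"].unique()
    if max_mutations is not None:
        ids = ids[:max_mutations]
    for mid in ids:
        sub = table[table["mutation_id"] == mid]
        ax.plot(sub["generation"], sub["frequency"], lw=0.8, alpha=0.8)
    ax.set_xlabel("generation")
    ax.set_ylabel("mutation frequency")
    ax.set_ylim(-0.02, 1.02)
    return ax
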