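"""Per-run result container shared by the engine and the summary layer."""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ModelParams
from .tracker import FixationEvent, MutationRegistry, TrajectoryRecord

__all__ = ["MeanFitnessRow", "SimulationResult"]


@dataclass(frozen=True)
class MeanFitnessRow:
    generation: int
    mean_w: float
    max_w: float
    n_segregating: int


@dataclass
class SimulationResult:
    """Everything one replicate produced.

    ``mean_fitness`` always covers generation 0 and the last simulated
    generation; ``trajectories`` follows the configured cadence (with
    fixation censuses forced in); ``fixation_events`` is chronological;
    ``registry`` holds origin, fate and effect of every mutation created.
    ``complete`` is False only for runs that were interrupted (a run that
    stopped at a requested early-stopping condition is complete).
    """

    params: ModelParams
    replicate_seed: int
    mean_fitness: list[MeanFitnessRow] = field(default_factory=list)
    trajectories: list[TrajectoryRecord] = field(default_factory=list)
    fixation_events: list[FixationEvent] = field(default_factory=list)
    registry: MutationRegistry = field(default_factory=MutationRegistry)
    final_generation: int = 0
    complete: bool = True
    stop_reason: str = "horizon"
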