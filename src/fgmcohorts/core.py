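"""Elementary operations of Fisher's geometric model (FGM).

An individual is a point ``z = (z_1, ..., z_n)`` in an ``n``-dimensional
trait space with the optimum at the origin.  Fitness is Gaussian in the
distance to the optimum,

    w(z) = exp(-sum_i z_i**2),

so ``w = 1`` exactly at the optimum and decays with the squared norm.
A de novo mutation alters ``m`` of the ``n`` traits (partial pleiotropy;
``m = n`` is full pleiotropy), the affected traits drawn uniformly
without replacement and each perturbed additively by an independent
Normal(0, sigma^2) deviate.  For a parent sitting at the optimum the mean
selection coefficient of a random mutation is

    E(S) = (1 + 2*sigma^2)**(-m/2) - 1  ~=  -m * sigma^2

to first order in ``sigma^2``; configurations may be specified through
either ``sigma2`` or the mean effect ``E(S)`` (with ``sigma2 = |E(S)|/m``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "ModelParams",
    "Mutation",
    "fitness",
    "log_fitness",
    "initial_phenotype",
    "sample_mutation",
    "apply_mutation",
    "selection_coefficient",
    "expected_mean_effect",
    "exact_mean_fitness_factor",
]

Placement = Literal["axis", "random_direction"]


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of a single simulation run.

    Parameters
    ----------
    n : int
        Phenotypic complexity — number of traits under selection.
    m : int
        Pleiotropy — number of traits a single mutation alters (1 <= m <= n).
    sigma2 : float
        Per-trait variance of mutational effects.
    U : float
        Genomic mutation rate per individual per generation.
    N : int
        Population size (fixed; Wright-Fisher).
    w0 : float
        Initial fitness of the (monomorphic) founding population, in (0, 1].
    generations : int
        Number of generations to simulate.
    record_every : int
        Cadence (in generations) of trajectory and mean-fitness recording.
    seed : int
        Replicate RNG seed.
    placement : {"axis", "random_direction"}
        Where the founder sits on the shell of fitness ``w0``.  The default
        "random_direction" picks a uniformly random direction — the generic
        position in trait space.  "axis" puts the whole displacement on the
        first trait; under full pleiotropy (m = n) the two are equivalent by
        isotropy, but under partial pleiotropy the axis position is a special
        geometry in which only mutations hitting that one trait (probability
        m/n each) can be strongly selected.
    """

    n: int
    m: int
    sigma2: float
    U: float
    N: int
    w0: float = 0.5
    generations: int = 1000
    record_every: int = 1
    seed: int = 0
    placement: Placement = "random_direction"

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        if not (isinstance(self.m, (int, np.integer)) and 1 <= self.m <= self.n):
            raise ValueError(f"m must satisfy 1 <= m <= n={self.n}, got {self.m!r}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2!r}")
        if self.U < 0:
            raise ValueError(f"U must be >= 0, got {self.U!r}")
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be a positive integer, got {self.N!r}")
        if not (0 < self.w0 <= 1):
            raise ValueError(f"w0 must lie in (0, 1], got {self.w0!r}")
        if self.generations < 0:
            raise ValueError(f"generations must be >= 0, got {self.generations!r}")
        if self.record_every < 1:
            raise ValueError(f"record_every must be >= 1, got {self.record_every!r}")
        if self.placement not in ("axis", "random_direction"):
            raise ValueError(f"unknown placement {self.placement!r}")

    @classmethod
    def from_mean_effect(cls, *, E_S: float, m: int, **kwargs) -> "ModelParams":
        """Build parameters from a mean mutational effect ``E(S)``.

        Uses the first-order relation ``E(S) = -m * sigma2`` exactly, i.e.
        ``sigma2 = |E(S)| / m``.
        """
        return cls(m=m, sigma2=abs(E_S) / m, **kwargs)

    @property
    def mean_effect(self) -> float:
        """First-order mean selection coefficient ``-m * sigma2``."""
        return expected_mean_effect(self.m, self.sigma2)

    def with_seed(self, seed: int) -> "ModelParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class Mutation:
    """A unique mutational lineage: which traits it hit and by how much.

    ``trait_indices`` are 0-based and distinct; ``deltas`` are the additive
    per-trait phenotypic changes.  Records are immutable; identity within a
    run is by ``id``.
    """

    id: int
    origin_generation: int
    trait_indices: tuple[int, ...]
    deltas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.trait_indices) != len(self.deltas):
            raise ValueError("trait_indices and deltas must have equal length")
        if len(set(self.trait_indices)) != len(self.trait_indices):
            raise ValueError("trait_indices must be distinct")


def _check_phenotype(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim != 1:
        raise ValueError(f"phenotype must be a 1-d vector, got shape {z.shape}")
    if not np.all(np.isfinite(z)):
        raise ValueError("phenotype has non-finite entries")
    return z


def fitness(z: np.ndarray) -> float:
    """Gaussian fitness ``exp(-sum z_i^2)`` of a phenotype.

    Equals 1 exactly at the optimum (the origin) and is strictly
    decreasing in the squared distance to it.
    """
    z = _check_phenotype(z)
    return math.exp(-float(z @ z))


def log_fitness(z: np.ndarray) -> float:
    """Log-fitness ``-sum z_i^2`` (numerically safe far from the optimum)."""
    z = _check_phenotype(z)
    return -float(z @ z)


def initial_phenotype(params: ModelParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Founding phenotype at fitness exactly ``w0``.

    ``placement="axis"`` puts the founder at distance ``d = sqrt(ln(1/w0))``
    along the first trait axis; ``"random_direction"`` picks a uniform
    direction on the sphere of the same radius (consumes ``rng``).  Fitness
    depends on the distance only, so the two choices are statistically
    equivalent for every isotropic summary.
    """
    d = math.sqrt(math.log(1.0 / params.w0))
    z = np.zeros(params.n)
    if params.w0 == 1.0 or d == 0.0:
        return z
    if params.placement == "axis":
        z[0] = d
        return z
    if rng is None:
        raise ValueError("random_direction placement requires an rng")
    v = rng.standard_normal(params.n)
    norm = np.linalg.norm(v)
    while norm == 0.0:  # essentially impossible; guards the division
        v = rng.standard_normal(params.n)
        norm = np.linalg.norm(v)
    return v * (d / norm)


def sample_mutation(
    params: ModelParams,
    rng: np.random.Generator,
    mutation_id: int,
    generation: int,
) -> Mutation:
    """Draw one de novo mutation under partial pleiotropy.

    ``m`` distinct trait indices uniform without replacement from
    ``{0, ..., n-1}``; per-trait deltas iid Normal(0, sigma2).
    """
    if params.m == params.n:
        idx = np.arange(params.n)
    else:
        idx = rng.choice(params.n, size=params.m, replace=False)
    deltas = rng.normal(0.0, math.sqrt(params.sigma2), size=params.m)
    return Mutation(
        id=mutation_id,
        origin_generation=generation,
        trait_indices=tuple(int(i) for i in idx),
        deltas=tuple(float(d) for d in deltas),
    )


def apply_mutation(z: np.ndarray, mut: Mutation) -> np.ndarray:
    """Return a new phenotype with the mutation's deltas added to its traits."""
    z = np.asarray(z, dtype=float)
    if max(mut.trait_indices, default=-1) >= z.shape[0]:
        raise IndexError(
            f"mutation touches trait {max(mut.trait_indices)} but phenotype has "
            f"{z.shape[0]} traits"
        )
    out = z.copy()
    out[list(mut.trait_indices)] += mut.deltas
    return out


def selection_coefficient(w_parent: float, w_offspring: float) -> float:
    """Relative fitness change ``w_offspring / w_parent - 1``."""
    if w_parent <= 0:
        raise ValueError(f"parent fitness must be > 0, got {w_parent!r}")
    return w_offspring / w_parent - 1.0


def expected_mean_effect(m: int, sigma2: float) -> float:
    """First-order mean selection coefficient ``-m * sigma2``.

    This is the mean effect of a random mutation applied to a parent at the
    optimum, to first order in ``sigma2``; see
    :func:`exact_mean_fitness_factor` for the exact multiplicative factor.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m!r}")
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2!r}")
    return -m * sigma2


def monte_carlo_mean_effect(
    params: ModelParams,
    n_draws: int,
    rng: np.random.Generator,
    chunk: int = 200_000,
) -> tuple[float, float]:
    """Monte-Carlo mean selection coefficient at the optimum, with its SE.

    Each draw is a random mutation applied to an optimum-resident parent
    (fitness 1): the offspring fitness is ``exp(-sum_j delta_j^2)`` over
    its ``m`` iid Normal(0, sigma2) deltas — which traits are hit does not
    enter at the optimum, so the estimate vectorises over deltas.  Returns
    ``(mean, standard_error)``; the mean converges to
    ``(1 + 2*sigma2)**(-m/2) - 1 ~= -m*sigma2``.
    """
    sd = math.sqrt(params.sigma2)
    total = 0.0
    total_sq = 0.0
    done = 0
    while done < n_draws:
        k = min(chunk, n_draws - done)
        deltas = rng.normal(0.0, sd, size=(k, params.m))
        s = np.exp(-np.einsum("ij,ij->i", deltas, deltas)) - 1.0
        total += float(s.sum())
        total_sq += float((s * s).sum())
        done += k
    mean = total / n_draws
    var = total_sq / n_draws - mean * mean
    return mean, math.sqrt(max(var, 0.0) / n_draws)


def exact_mean_fitness_factor(m: int, sigma2: float) -> float:
    """Exact mean multiplicative fitness factor at the optimum.

    With the parent at the optimum, an offspring's fitness is
    ``exp(-sum_{j=1}^m delta_j^2)`` with iid Normal(0, sigma2) deltas, whose
    expectation is the moment generating function of a scaled chi-square:
    ``(1 + 2*sigma2)**(-m/2)``.  Subtracting 1 gives the exact mean
    selection coefficient; ``-m*sigma2`` is its first-order expansion.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m!r}")
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2!r}")
    return (1.0 + 2.0 * sigma2) ** (-m / 2.0)
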