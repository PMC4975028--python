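"""Run configuration, replicate orchestration and table serialization.

Configs are plain-text YAML/JSON key-value files (CLI flags override
them).  Exactly one of ``sigma2`` or ``E_S`` must be given; with ``E_S``
the per-trait variance is derived as ``sigma2 = |E_S| / m``.  Replicate
``r`` runs on the child seed ``spawn(master_seed, r)`` — a fixed,
documented function of the master seed and the replicate index — so
adding replicates never perturbs earlier ones and reruns are
byte-identical.  All tables are TSV with dot decimals and floats at 17
significant digits for exact round-trips.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ModelParams
from .engine import run_simulation
from .results import SimulationResult
from .summaries import add_observation_noise

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "child_seed",
    "run_replicates",
    "write_tables",
    "TABLE_COLUMNS",
]

log = logging.getLogger("fgmcohorts")

_PARAM_KEYS = {
    "n", "m", "sigma2", "E_S", "U", "N", "w0", "generations",
    "record_every", "seed", "placement",
}
_RUN_KEYS = {"replicates", "out_dir", "noise_variance", "emit", "stop_after_fixations"}
_FLOAT_FMT = "%.17g"

TABLE_COLUMNS = {
    "mean_fitness": ["replicate", "generation", "mean_w", "max_w", "n_segregating"],
    "trajectories": ["replicate", "generation", "mutation_id", "frequency"],
    "trajectories_noisy": ["replicate", "generation", "mutation_id", "frequency"],
    "fixations": ["replicate", "generation", "cohort_id", "cohort_size", "mutation_id"],
    "mutations": [
        "replicate", "mutation_id", "origin_generation", "fate", "fate_generation",
        "trait_indices", "deltas", "s_at_origin",
    ],
}


class ConfigError(ValueError):
    """Invalid or contradictory run configuration."""


@dataclass
class RunConfig:
    """A validated multi-replicate run: model parameters plus orchestration."""

    params: ModelParams
    replicates: int = 1
    out_dir: Path = Path("fgm_out")
    noise_variance: float = 0.02
    emit: tuple[str, ...] = tuple(TABLE_COLUMNS)
    stop_after_fixations: Optional[int] = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates!r}")
        if self.noise_variance < 0:
            raise ConfigError(
                f"noise_variance must be >= 0, got {self.noise_variance!r}"
            )
        unknown = set(self.emit) - set(TABLE_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown emit table(s): {sorted(unknown)}")


def load_config(path: Optional[str | Path] = None, **overrides: Any) -> RunConfig:
    """Read a YAML/JSON config file and/or keyword overrides into a RunConfig.

    Overrides win over file values.  All violations are collected and
    reported together.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a key-value mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})

    problems: list[str] = []
    unknown = set(raw) - _PARAM_KEYS - _RUN_KEYS
    if unknown:
        problems.append(f"unknown key(s): {sorted(unknown)}")
    has_sigma2 = raw.get("sigma2") is not None
    has_es = raw.get("E_S") is not None
    if has_sigma2 and has_es:
        problems.append("give either sigma2 or E_S, not both")
    if not has_sigma2 and not has_es:
        problems.append("one of sigma2 or E_S is required")
    for key in ("n", "m", "U", "N"):
        if raw.get(key) is None:
            problems.append(f"missing required key: {key}")
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))

    pkw = {k: raw[k] for k in _PARAM_KEYS & set(raw) if k not in ("sigma2", "E_S")}
    try:
        if has_es:
            params = ModelParams.from_mean_effect(E_S=float(raw["E_S"]), **pkw)
        else:
            params = ModelParams(sigma2=float(raw["sigma2"]), **pkw)
    except ValueError as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc

    rkw: dict[str, Any] = {k: raw[k] for k in _RUN_KEYS & set(raw)}
    if "out_dir" in rkw:
        rkw["out_dir"] = Path(rkw["out_dir"])
    if "emit" in rkw:
        rkw["emit"] = tuple(rkw["emit"])
    return RunConfig(params=params, **rkw)


def child_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed: ``SeedSequence(master, spawn_key=(r,))``."""
    return np.random.SeedSequence(master_seed, spawn_key=(replicate,))


def run_replicates(
    config: RunConfig,
) -> tuple[list[SimulationResult], dict[str, Any]]:
    """Run every replicate on its child seed and assemble the manifest."""
    t0 = time.time()
    results: list[SimulationResult] = []
    failures: dict[int, str] = {}
    for r in range(config.replicates):
        rng = np.random.default_rng(child_seed(config.params.seed, r))
        try:
            res = run_simulation(
                config.params.with_seed(config.params.seed),
                rng,
                stop_after_fixations=config.stop_after_fixations,
            )
        except Exception as exc:  # keep completed replicates on partial failure
            failures[r] = f"{type(exc).__name__}: {exc}"
            log.error("replicate %d failed: %s", r, failures[r])
            continue
        res.replicate_seed = r
        results.append(res)
        log.info(
            "replicate %d: %d generations, %d fixation events, %d mutations",
            r, res.final_generation, len(res.fixation_events), len(res.registry),
        )
    manifest = {
        "package_version": __version__,
        "params": asdict(config.params),
        "replicates": config.replicates,
        "seed_scheme": "numpy SeedSequence(master_seed, spawn_key=(replicate,))",
        "master_seed": config.params.seed,
        "noise_variance": config.noise_variance,
        "stop_after_fixations": config.stop_after_fixations,
        "failures": failures,
        "wall_time_s": round(time.time() - t0, 3),
    }
    return results, manifest


def _frames(results: Sequence[SimulationResult], config: RunConfig) -> dict[str, pd.DataFrame]:
    mean_rows, traj_rows, fix_rows, mut_rows, noisy_rows = [], [], [], [], []
    for res in results:
        r = res.replicate_seed
        for row in res.mean_fitness:
            mean_rows.append((r, row.generation, row.mean_w, row.max_w, row.n_segregating))
        for rec in res.trajectories:
            traj_rows.append((r, rec.generation, rec.mutation_id, rec.frequency))
        for cid, ev in enumerate(res.fixation_events):
            for mid in sorted(ev.mutation_ids):
                fix_rows.append((r, ev.generation, cid, ev.cohort_size, mid))
        for mid in sorted(res.registry.entries):
            e = res.registry.entries[mid]
            fate_gen = e.fixation_generation if e.status == "fixed" else e.loss_generation
            mut_rows.append(
                (
                    r, mid, e.mutation.origin_generation, e.status,
                    -1 if fate_gen is None else fate_gen,
                    ";".join(str(i) for i in e.mutation.trait_indices),
                    ";".join(_FLOAT_FMT % d for d in e.mutation.deltas),
                    e.s_at_origin,
                )
            )
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(config.params.seed, spawn_key=(res.replicate_seed, 1))
        )
        for rec in add_observation_noise(res.trajectories, config.noise_variance, noise_rng):
            noisy_rows.append((r, rec.generation, rec.mutation_id, rec.frequency))
    data = {
        "mean_fitness": mean_rows,
        "trajectories": traj_rows,
        "trajectories_noisy": noisy_rows,
        "fixations": fix_rows,
        "mutations": mut_rows,
    }
    return {
        name: pd.DataFrame(rows, columns=TABLE_COLUMNS[name])
        for name, rows in data.items()
    }


def write_tables(
    results: Sequence[SimulationResult],
    config: RunConfig,
    manifest: Optional[dict[str, Any]] = None,
) -> dict[str, Path]:
    """Serialize result tables as TSV under ``config.out_dir``.

    Fixed column orders; one row per cohort member in ``fixations.tsv``;
    within-cell lists semicolon-joined.  Returns the written paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = _frames(results, config)
    written: dict[str, Path] = {}
    for name in config.emit:
        path = out / f"{name}.tsv"
        frames[name].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written[name] = path
    if manifest is not None:
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        written["manifest"] = path
    return written


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_tables` (exact round-trip)."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
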