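"""Per-generation simulation loop, replicates, and factorial sweeps.

Event order within a generation (fixed): herbivore attacks are resolved
first, plant fitness and reproduction use the realized damage (tolerance
is inducible within the same generation), then herbivores reproduce from
their feeding outcomes, and the new state is recorded.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import init_population
from .herbivory import resolve_attacks
from .params import Params, rng_for_replicate, validate_params
from .reproduction import next_herbivore_generation, next_plant_generation

logger = logging.getLogger(__name__)

RECORD_COLUMNS = (
    "generation", "freq_resistance", "freq_tolerance", "freq_selfing",
    "freq_antiresistance", "selfer_fraction", "mean_heterozygosity",
    "mean_load", "n_plants", "n_herbivores", "mean_fitness_factor",
    "attack_rate",
)

COMPLETED = "completed"
PLANT_EXTINCTION = "plant_extinction"
HERBIVORE_EXTINCTION = "herbivore_extinction_continued"


@dataclasses.dataclass
class RunResult:
    """A finished simulation: parameter echo, per-generation records, status."""

    params: Params
    replicate: int
    records: pd.DataFrame
    status: str
    extinction_generation: int | None = None

    @property
    def seed(self) -> int:
        return self.params.seed


def _record(gen, plants, herbs, mean_f, attack_rate):
    return (
        gen,
        plants.allele_frequency("resistance"),
        plants.allele_frequency("tolerance"),
        plants.allele_frequency("selfing"),
        herbs.allele_frequency(),
        float(plants.selfer_tag.mean()),
        float(plants.heterozygosity().mean()),
        float(plants.detrimental_counts().mean()),
        plants.size,
        herbs.size,
        mean_f,
        attack_rate,
    )


def run_simulation(p: Params, rng: np.random.Generator,
                   replicate: int = 0) -> RunResult:
    """Run one replicate for ``p.generations`` generations (or to extinction)."""
    validate_params(p)
    plants, herbs = init_population(p, rng)
    rows = [_record(0, plants, herbs, float("nan"), float("nan"))]
    status = COMPLETED
    ext_gen: int | None = None

    for gen in range(1, p.generations + 1):
        outcome = resolve_attacks(plants, herbs, rng)
        step = next_plant_generation(plants, outcome.damage, p, rng)
        if step.population is None:
            status = PLANT_EXTINCTION
            ext_gen = gen
            break
        herbs = next_herbivore_generation(herbs, outcome.fed, p, rng)
        plants = step.population
        rows.append(_record(gen, plants, herbs, step.mean_fitness,
                            outcome.attack_rate))
        if gen % 1000 == 0:
            logger.info("replicate %d: generation %d (plants=%d, herbivores=%d)",
                        replicate, gen, plants.size, herbs.size)

    if status == COMPLETED and herbs.size == 0:
        status = HERBIVORE_EXTINCTION
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    logger.info("replicate %d finished: %s", replicate, status)
    return RunResult(p, replicate, records, status, ext_gen)


def run_replicate(p: Params, replicate: int,
                  cell: int | None = None) -> RunResult:
    """Run one replicate with its stream derived from (seed, [cell,] replicate)."""
    return run_simulation(p, rng_for_replicate(p, replicate, cell), replicate)


def run_replicates(p: Params, replicates: int | None = None) -> list[RunResult]:
    """Run ``p.replicates`` (or ``replicates``) independent replicates."""
    n = p.replicates if replicates is None else replicates
    return [run_replicate(p, r) for r in range(n)]


def sweep_cells(grid: Mapping[str, Sequence]) -> list[dict]:
    """Cartesian product of a parameter grid, as per-cell override dicts."""
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def run_sweep(p: Params, grid: Mapping[str, Sequence], reps: int | None = None,
              out_dir: str | Path | None = None,
              resume: bool = True) -> Iterable[tuple[int, Params, int, object]]:
    """Run a factorial sweep: Cartesian grid x replicates, streamed lazily.

    Yields ``(cell_index, cell_params, replicate, result)`` where result is
    a ``RunResult`` or, when ``out_dir`` is given, the path of the written
    per-run CSV.  With ``out_dir`` and ``resume=True``, cells whose output
    file already exists are skipped, so an interrupted sweep completes only
    the missing runs when re-invoked.
    """
    from .summaries import write_run_csv  # deferred: avoids an import cycle

    reps = p.replicates if reps is None else reps
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for cell_index, overrides in enumerate(sweep_cells(grid)):
        cell_params = validate_params(dataclasses.replace(p, **overrides))
        for rep in range(reps):
            path = (out / f"cell{cell_index:04d}_rep{rep}.csv"
                    if out is not None else None)
            if path is not None and resume and path.exists():
                yield cell_index, cell_params, rep, path
                continue
            result = run_replicate(cell_params, rep, cell=cell_index)
            if path is not None:
                try:
                    write_run_csv(result, path)
                except OSError as exc:
                    logger.error("cell %d rep %d: write failed (%s); skipped",
                                 cell_index, rep, exc)
                    continue
                yield cell_index, cell_params, rep, path
            else:
                yield cell_index, cell_params, rep, result
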