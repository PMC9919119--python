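"""Next-generation construction for plants and herbivores.

Plants are hermaphroditic and may self-fertilize.  Each plant mothers a
Poisson number of seeds with mean w0 * F (its realized fitness); every
seed is selfed with the mother's individual selfing probability, otherwise
it outcrosses with a pollen parent drawn uniformly from the population
(pollen production is not fitness-weighted).  Offspring are built gamete by
gamete (segregation -> mutation -> fusion); seeds homozygous for a
detrimental allele die at birth; the viable seed pool is subsampled
uniformly to the carrying capacity.

Herbivores are dioecious: each female produces Poisson offspring scaled by
her fitness factor, sires are drawn among males weighted by theirs, and
offspring sex is equiprobable.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import genetics
from .fitness import fitness_factor, realize_seeds
from .genetics import (HerbivorePopulation, PlantPopulation, empty_herbivores,
                       fuse_herbivores, fuse_plants, make_herbivore_gametes,
                       make_plant_gametes, mutate_gametes)
from .herbivory import herbivore_fitness_factor
from .params import Params


def selfing_probability(pop: PlantPopulation, mode: str) -> np.ndarray:
    """Per-plant probability that an ovule is self-fertilized.

    heritable: proportional to the selfing-allele dosage (count / 4);
    non_heritable: all-or-nothing by the maternal selfer tag;
    none: always outcrossing.
    """
    if mode == "heritable":
        return pop.investment("selfing")
    if mode == "non_heritable":
        return pop.selfer_tag.astype(float)
    if mode == "none":
        return np.zeros(pop.size)
    raise ValueError(f"unknown selfing mode: {mode!r}")


# The viable seed pool is subsampled uniformly to K_plants, so only a capped
# uniform subsample of seed slots (SEED_POOL_FACTOR * K_plants) is ever
# constructed: subsampling slots before the lethality cull commutes with
# subsampling survivors after it.  When lethality is so high that the capped
# pool cannot fill the capacity, the full pool is constructed instead.
SEED_POOL_FACTOR = 4


@dataclasses.dataclass
class PlantStepResult:
    """One plant generation turnover; ``population`` is None on extinction."""

    population: PlantPopulation | None
    mean_fitness: float
    n_seeds: int
    n_selfed: int
    n_viable: int


def next_plant_generation(pop: PlantPopulation, damage: np.ndarray, p: Params,
                          rng: np.random.Generator) -> PlantStepResult:
    """Produce the next plant generation from realized damage.

    Returns an extinction result (population None) when fewer than two
    viable seeds exist.
    """
    factor = fitness_factor(p, pop.investment("resistance"),
                            pop.investment("tolerance"), damage,
                            pop.heterozygosity(), pop.detrimental_counts(),
                            pop.lethal())
    seeds = realize_seeds(p, factor, rng)
    total = int(seeds.sum())
    mean_f = float(factor.mean())
    if total < 2:
        return PlantStepResult(None, mean_f, total, 0, 0)

    mothers = np.repeat(np.arange(pop.size), seeds)
    p_self = selfing_probability(pop, p.selfing_mode)
    selfed = rng.random(total) < p_self[mothers]

    if p.selfing_mode == "non_heritable" and not p.selfers_donate_pollen:
        donors = np.flatnonzero(~pop.selfer_tag)
        if donors.size == 0:
            donors = np.arange(pop.size)
        fathers = donors[rng.integers(0, donors.size, size=total)]
    else:
        fathers = rng.integers(0, pop.size, size=total)
    fathers[selfed] = mothers[selfed]

    cap = SEED_POOL_FACTOR * p.K_plants
    slots = rng.permutation(total)[:cap] if total > cap else np.arange(total)
    built = _build_seeds(pop, mothers[slots], fathers[slots], p, rng)
    if built.size < p.K_plants and total > cap:
        built = _build_seeds(pop, mothers, fathers, p, rng)  # rare: heavy lethality
    n_viable = built.size
    if n_viable < 2:
        return PlantStepResult(None, mean_f, total, int(selfed.sum()), n_viable)
    if n_viable > p.K_plants:
        built = built.subset(rng.permutation(n_viable)[:p.K_plants])
    return PlantStepResult(built, mean_f, total, int(selfed.sum()), n_viable)


def _build_seeds(pop: PlantPopulation, mothers: np.ndarray, fathers: np.ndarray,
                 p: Params, rng: np.random.Generator) -> PlantPopulation:
    """Construct viable offspring for the given seed-slot parent pairs."""
    gm = mutate_gametes(make_plant_gametes(pop, mothers, rng), p.mu, rng)
    gf = mutate_gametes(make_plant_gametes(pop, fathers, rng), p.mu, rng)
    # cull detrimental-homozygous seeds at birth (equivalent to adult F = 0)
    idx = np.flatnonzero(~(gm.load_det & gf.load_det).any(axis=1))
    return fuse_plants(
        genetics.PlantGametes(gm.eff[idx], gm.load_cls[idx], gm.load_det[idx]),
        genetics.PlantGametes(gf.eff[idx], gf.load_cls[idx], gf.load_det[idx]),
        selfer_tag=pop.selfer_tag[mothers[idx]],
    )


def next_herbivore_generation(pop: HerbivorePopulation, fed: np.ndarray,
                              p: Params,
                              rng: np.random.Generator) -> HerbivorePopulation:
    """Produce the next herbivore generation from this generation's feeding.

    An empty result records herbivore extinction (subsequent generations
    simply see zero damage); it is a state, not an error.
    """
    if pop.size == 0:
        return empty_herbivores()
    factor = herbivore_fitness_factor(p, pop.investment(), fed)
    females = np.flatnonzero(pop.female)
    males = np.flatnonzero(~pop.female)
    if females.size == 0 or males.size == 0:
        return empty_herbivores()
    male_w = factor[males]
    if male_w.sum() <= 0.0:
        return empty_herbivores()

    counts = rng.poisson(p.herbivore_base_fecundity * factor[females])
    total = int(counts.sum())
    if total == 0:
        return empty_herbivores()
    mothers = np.repeat(females, counts)
    fathers = males[rng.choice(males.size, size=total, p=male_w / male_w.sum())]

    gm = make_herbivore_gametes(pop, mothers, rng)
    gf = make_herbivore_gametes(pop, fathers, rng)
    female = rng.random(total) < 0.5
    offspring = fuse_herbivores(gm, gf, female)
    if total > p.K_herbivores:
        keep = rng.permutation(total)[:p.K_herbivores]
        offspring = offspring.subset(keep)
    return offspring
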