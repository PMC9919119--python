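"""Gene-for-gene plant-herbivore encounters and herbivore fitness.

The interaction follows the gene-for-gene rules: a plant gene is *armed*
when it carries at least one resistance allele, which gives full
protection; a herbivore carrying at least one anti-resistance allele at
the matching gene *disarms* it.  An attack succeeds iff no armed plant
gene remains un-disarmed.  Damage is binary: a plant is damaged (d = 1)
iff at least one herbivore fed on it this generation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .genetics import HerbivorePopulation, PlantPopulation, RESISTANCE
from .params import Params


class PlantExtinctionError(RuntimeError):
    """Raised when attacks are resolved against an empty plant population."""


@dataclasses.dataclass
class AttackOutcome:
    """Per-herbivore targets and feeding success; per-plant binary damage."""

    targets: np.ndarray  # (m,) int: plant index attacked by each herbivore
    fed: np.ndarray      # (m,) bool: attack success of each herbivore
    damage: np.ndarray   # (n,) bool: plant was fed upon by >= 1 herbivore

    @property
    def attack_rate(self) -> float:
        """Fraction of attacks that succeeded (NaN without herbivores)."""
        return float(self.fed.mean()) if self.fed.size else float("nan")


def attack_success(plant_res: np.ndarray, herb_anti: np.ndarray) -> np.ndarray:
    """Gene-for-gene outcome for paired (..., 2) resistance/anti-resistance counts.

    Plants without resistance alleles are fully susceptible; one resistance
    allele at an uncountered gene gives full protection; one anti-resistance
    allele suffices to inactivate the matching plant gene.
    """
    plant_res = np.asarray(plant_res)
    herb_anti = np.asarray(herb_anti)
    if plant_res.shape[-1] != 2 or herb_anti.shape[-1] != 2:
        raise ValueError("expected two genes per genotype")
    if (plant_res < 0).any() or (plant_res > 2).any() \
            or (herb_anti < 0).any() or (herb_anti > 2).any():
        raise ValueError("allele counts must lie in {0, 1, 2}")
    armed = plant_res >= 1
    disarmed = herb_anti >= 1
    return ~(armed & ~disarmed).any(axis=-1)


def resolve_attacks(plants: PlantPopulation, herbivores: HerbivorePopulation,
                    rng: np.random.Generator) -> AttackOutcome:
    """Each herbivore attacks one plant per generation, chosen uniformly.

    Targets are drawn with replacement (several herbivores may land on the
    same plant; damage saturates at d = 1).
    """
    n = plants.size
    if n == 0:
        raise PlantExtinctionError("cannot resolve attacks: no plants left")
    m = herbivores.size
    if m == 0:
        return AttackOutcome(np.zeros(0, dtype=np.int64),
                             np.zeros(0, dtype=bool),
                             np.zeros(n, dtype=bool))
    targets = rng.integers(0, n, size=m)
    fed = attack_success(plants.eff[targets, RESISTANCE, :], herbivores.anti)
    damage = np.zeros(n, dtype=bool)
    damage[targets[fed]] = True
    return AttackOutcome(targets, fed, damage)


def herbivore_fitness_factor(p: Params, a, fed) -> np.ndarray:
    """Herbivore fitness factor: anti-resistance cost x failed-feeding cost.

    F_h = (1 - c_a * a**l) * (1 - herbivore_failure_cost * (1 - fed)),
    floored at zero.  A failed attack costs a configurable fitness
    proportion rather than being lethal.
    """
    a = np.asarray(a, dtype=float)
    fed = np.asarray(fed, dtype=float)
    cost = np.maximum(1.0 - p.c_a * a ** p.l, 0.0)
    failure = np.maximum(1.0 - p.herbivore_failure_cost * (1.0 - fed), 0.0)
    return cost * failure
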