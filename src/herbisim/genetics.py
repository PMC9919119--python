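"""Diploid genotypes, gametes, mutation, and derived genetic quantities.

Populations are stored struct-of-arrays (one numpy array per genetic
component, first axis = individuals) so the per-generation inner loops are
fully vectorized.  A "population" of size 1 is the per-individual case.

Each plant carries three *effect* traits (resistance, tolerance, selfing)
and each herbivore one (anti-resistance).  Every effect is controlled by two
unlinked diallelic genes; a genotype stores the effect-allele count in
{0, 1, 2} per gene, and the individual's investment in the trait is the
carried fraction of the four possible effect alleles.

Plants additionally carry a load genome of ``n_genome_genes`` unlinked genes
with two allele slots each.  An allele has a neutral class (A/B, providing
standing heterozygosity) and a detrimental flag (recessive-lethal mutation).
Individual heterozygosity ``h_i`` is the fraction of load genes whose two
alleles differ in composite state; ``u_i`` is the total number of
detrimental alleles; an individual is lethal iff some gene carries the
detrimental flag on both alleles.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .params import Params

PLANT_EFFECTS = ("resistance", "tolerance", "selfing")
RESISTANCE, TOLERANCE, SELFING = 0, 1, 2


def _effect_index(effect: str) -> int:
    try:
        return PLANT_EFFECTS.index(effect)
    except ValueError:
        raise KeyError(f"unknown effect: {effect!r}") from None


@dataclasses.dataclass
class PlantPopulation:
    """A plant population (or a single plant when ``size == 1``)."""

    eff: np.ndarray        # (n, 3, 2) int8: effect-allele count per gene
    load_cls: np.ndarray   # (n, G, 2) uint8: neutral class of each allele
    load_det: np.ndarray   # (n, G, 2) bool: detrimental flag of each allele
    selfer_tag: np.ndarray  # (n,) bool: non-heritable selfer status

    @property
    def size(self) -> int:
        return self.eff.shape[0]

    def investment(self, effect: str) -> np.ndarray:
        """Per-individual investment: carried effect alleles / 4, in steps of 0.25."""
        e = _effect_index(effect)
        return self.eff[:, e, :].sum(axis=1) / 4.0

    def heterozygosity(self) -> np.ndarray:
        """h_i: fraction of load genes whose two alleles differ in (class, flag)."""
        diff = (self.load_cls[:, :, 0] != self.load_cls[:, :, 1]) \
            | (self.load_det[:, :, 0] != self.load_det[:, :, 1])
        return diff.mean(axis=1)

    def detrimental_counts(self) -> np.ndarray:
        """u_i: total detrimental alleles over both slots of every load gene."""
        return self.load_det.sum(axis=(1, 2))

    def lethal(self) -> np.ndarray:
        """True iff some load gene carries the detrimental flag homozygously."""
        return self.load_det.all(axis=2).any(axis=1)

    def allele_frequency(self, effect: str) -> float:
        """Population frequency of the effect allele over all 4 slots per plant."""
        e = _effect_index(effect)
        return float(self.eff[:, e, :].sum()) / (4.0 * self.size)

    def subset(self, idx: np.ndarray) -> "PlantPopulation":
        return PlantPopulation(self.eff[idx], self.load_cls[idx],
                               self.load_det[idx], self.selfer_tag[idx])


@dataclasses.dataclass
class HerbivorePopulation:
    """A dioecious herbivore population; sex is fixed at birth."""

    anti: np.ndarray    # (n, 2) int8: anti-resistance allele count per gene
    female: np.ndarray  # (n,) bool

    @property
    def size(self) -> int:
        return self.anti.shape[0]

    def investment(self) -> np.ndarray:
        return self.anti.sum(axis=1) / 4.0

    def allele_frequency(self) -> float:
        if self.size == 0:
            return float("nan")
        return float(self.anti.sum()) / (4.0 * self.size)

    def subset(self, idx: np.ndarray) -> "HerbivorePopulation":
        return HerbivorePopulation(self.anti[idx], self.female[idx])


def empty_herbivores() -> HerbivorePopulation:
    return HerbivorePopulation(np.zeros((0, 2), dtype=np.int8),
                               np.zeros(0, dtype=bool))


@dataclasses.dataclass
class PlantGametes:
    """Haploid plant gametes: one allele per effect gene and per load gene."""

    eff: np.ndarray       # (m, 3, 2) int8 in {0, 1}
    load_cls: np.ndarray  # (m, G) uint8
    load_det: np.ndarray  # (m, G) bool


@dataclasses.dataclass
class HerbivoreGametes:
    anti: np.ndarray  # (m, 2) int8 in {0, 1}


def _transmit(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # Mendelian transmission from an allele count: homozygotes are
    # deterministic, heterozygotes pass the effect allele with p = 1/2.
    bits = rng.integers(0, 2, size=counts.shape, dtype=np.int8)
    return np.where(counts == 1, bits, counts >> 1).astype(np.int8)


def make_plant_gametes(pop: PlantPopulation, parents: np.ndarray,
                       rng: np.random.Generator) -> PlantGametes:
    """One gamete per entry of ``parents`` (indices into ``pop``).

    Every gene segregates independently (unlinked, free recombination);
    each load gene transmits one of its two alleles as a unit, so the
    neutral class and detrimental flag travel together.
    """
    eff = _transmit(pop.eff[parents], rng)
    n_genes = pop.load_cls.shape[1]
    choice = rng.integers(0, 2, size=(len(parents), n_genes))
    # one flat gather per array: (parent, gene, chosen allele slot)
    flat = (np.asarray(parents)[:, None] * n_genes
            + np.arange(n_genes)[None, :]) * 2 + choice
    cls = np.ascontiguousarray(pop.load_cls).reshape(-1)[flat]
    det = np.ascontiguousarray(pop.load_det).reshape(-1)[flat]
    return PlantGametes(eff, cls, det)


def make_herbivore_gametes(pop: HerbivorePopulation, parents: np.ndarray,
                           rng: np.random.Generator) -> HerbivoreGametes:
    return HerbivoreGametes(_transmit(pop.anti[parents], rng))


def mutate_gametes(gam: PlantGametes, mu: float,
                   rng: np.random.Generator) -> PlantGametes:
    """Each load-gene allele independently becomes detrimental with prob ``mu``.

    Idempotent on already-detrimental alleles; effect genes never mutate
    (lost effect alleles can only persist cryptically in heterozygotes).
    """
    if mu <= 0.0:
        return gam
    hits = rng.random(gam.load_det.shape) < mu
    return PlantGametes(gam.eff, gam.load_cls, gam.load_det | hits)


def fuse_plants(maternal: PlantGametes, paternal: PlantGametes,
                selfer_tag: np.ndarray | None = None) -> PlantPopulation:
    """Fuse gamete pairs into diploid offspring (derived quantities on demand)."""
    eff = (maternal.eff + paternal.eff).astype(np.int8)
    cls = np.stack([maternal.load_cls, paternal.load_cls], axis=2)
    det = np.stack([maternal.load_det, paternal.load_det], axis=2)
    if selfer_tag is None:
        selfer_tag = np.zeros(eff.shape[0], dtype=bool)
    return PlantPopulation(eff, cls, det, np.asarray(selfer_tag, dtype=bool))


def fuse_herbivores(maternal: HerbivoreGametes, paternal: HerbivoreGametes,
                    female: np.ndarray) -> HerbivorePopulation:
    anti = (maternal.anti + paternal.anti).astype(np.int8)
    return HerbivorePopulation(anti, np.asarray(female, dtype=bool))


def _draw_counts(rng: np.random.Generator, n: int, n_genes: int,
                 freq: float) -> np.ndarray:
    alleles = rng.random((n, n_genes, 2)) < freq
    return alleles.sum(axis=2).astype(np.int8)


def init_population(p: Params, rng: np.random.Generator
                    ) -> tuple[PlantPopulation, HerbivorePopulation]:
    """Found both populations from the configured initial allele frequencies.

    Effect alleles are drawn independently per slot; load-genome neutral
    classes are drawn at ``init_genome_het`` (giving expected h_i = 2pq);
    the load genome starts free of detrimental alleles; herbivore sexes
    alternate to an even split; selfer tags are drawn only under
    non-heritable selfing.
    """
    n, g = p.K_plants, p.n_genome_genes
    freqs = (p.init_freq_resistance, p.init_freq_tolerance, p.init_freq_selfing)
    eff = np.stack([_draw_counts(rng, n, 2, f) for f in freqs], axis=1)
    load_cls = (rng.random((n, g, 2)) < p.init_genome_het).astype(np.uint8)
    load_det = np.zeros((n, g, 2), dtype=bool)
    if p.selfing_mode == "non_heritable":
        selfer_tag = rng.random(n) < p.init_selfer_fraction
    else:
        selfer_tag = np.zeros(n, dtype=bool)
    plants = PlantPopulation(eff, load_cls, load_det, selfer_tag)

    m = p.K_herbivores
    anti = _draw_counts(rng, m, 2, p.init_freq_antiresistance)
    female = np.arange(m) % 2 == 0
    return plants, HerbivorePopulation(anti, female)
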