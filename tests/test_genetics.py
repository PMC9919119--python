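"""Genotypes, segregation, mutation, and derived genetic quantities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herbisim.genetics import (fuse_plants, init_population,
                               make_plant_gametes, mutate_gametes)
from herbisim.params import default_params

from conftest import make_plants

GENE_COUNTS = st.tuples(st.integers(0, 2), st.integers(0, 2))


@pytest.mark.parametrize("counts, expected", [
    ((0, 0), 0.0),
    ((1, 0), 0.25),   # minimum non-zero investment: a single retained allele
    ((1, 1), 0.5),
    ((2, 1), 0.75),
    ((2, 2), 1.0),
])
def test_investment_is_carried_allele_fraction(counts, expected):
    pop = make_plants(res=counts)
    assert pop.investment("resistance")[0] == expected


def test_investment_unknown_effect():
    with pytest.raises(KeyError):
        make_plants().investment("vigor")


@given(GENE_COUNTS)
def test_investment_invariant_under_gene_order(counts):
    forward = make_plants(res=counts).investment("resistance")[0]
    swapped = make_plants(res=counts[::-1]).investment("resistance")[0]
    assert forward == swapped


class TestHeterozygosity:
    def test_identical_allele_pairs_give_zero(self):
        assert make_plants().heterozygosity()[0] == 0.0

    def test_half_heterozygous(self):
        cls = np.zeros((100, 2), dtype=np.uint8)
        cls[:50, 1] = 1
        assert make_plants(load_cls=cls).heterozygosity()[0] == 0.5

    def test_all_heterozygous(self):
        cls = np.zeros((100, 2), dtype=np.uint8)
        cls[:, 1] = 1
        assert make_plants(load_cls=cls).heterozygosity()[0] == 1.0

    def test_detrimental_flag_differences_count(self):
        # composite state: same neutral class but one detrimental allele
        det = np.zeros((100, 2), dtype=bool)
        det[0, 0] = True
        assert make_plants(load_det=det).heterozygosity()[0] == 0.01


class TestDetrimentalCounts:
    def test_clean_genome(self):
        pop = make_plants()
        assert pop.detrimental_counts()[0] == 0
        assert not pop.lethal()[0]

    def test_homozygous_detrimental_is_lethal(self):
        det = np.zeros((100, 2), dtype=bool)
        det[3] = True
        pop = make_plants(load_det=det)
        assert pop.detrimental_counts()[0] == 2
        assert pop.lethal()[0]

    def test_heterozygous_detrimentals_are_not_lethal(self):
        det = np.zeros((100, 2), dtype=bool)
        det[:10, 0] = True
        pop = make_plants(load_det=det)
        assert pop.detrimental_counts()[0] == 10
        assert not pop.lethal()[0]


class TestGametes:
    def test_homozygous_parent_transmits_its_haplotype(self, rng):
        cls = np.ones((100, 2), dtype=np.uint8)
        pop = make_plants(res=(2, 0), tol=(2, 2), load_cls=cls)
        gam = make_plant_gametes(pop, np.zeros(10, dtype=int), rng)
        assert np.array_equal(gam.eff[:, 0, :], np.tile([1, 0], (10, 1)))
        assert np.array_equal(gam.eff[:, 1, :], np.ones((10, 2)))
        assert (gam.load_cls == 1).all()
        assert not gam.load_det.any()

    def test_heterozygous_transmission_is_mendelian(self, rng):
        pop = make_plants(res=(1, 0))
        n = 10_000
        gam = make_plant_gametes(pop, np.zeros(n, dtype=int), rng)
        frac = gam.eff[:, 0, 0].mean()
        sigma = 0.5 / np.sqrt(n)
        assert abs(frac - 0.5) < 3 * sigma

    def test_same_rng_state_gives_identical_gametes(self):
        pop = make_plants(res=(1, 1), tol=(1, 0))
        idx = np.zeros(50, dtype=int)
        g1 = make_plant_gametes(pop, idx, np.random.default_rng(3))
        g2 = make_plant_gametes(pop, idx, np.random.default_rng(3))
        assert np.array_equal(g1.eff, g2.eff)
        assert np.array_equal(g1.load_cls, g2.load_cls)


class TestMutation:
    def test_mu_zero_is_identity(self, rng):
        pop = make_plants()
        gam = make_plant_gametes(pop, np.zeros(5, dtype=int), rng)
        assert mutate_gametes(gam, 0.0, rng) is gam

    def test_mu_one_floods_the_genome(self, rng):
        pop = make_plants()
        gam = make_plant_gametes(pop, np.zeros(5, dtype=int), rng)
        assert mutate_gametes(gam, 1.0, rng).load_det.all()

    def test_default_rate_poisson_count(self, rng):
        # 10^5 gamete-alleles at mu = 0.00245: expect ~245 +- 3 sigma
        pop = make_plants(n=1, n_genes=100)
        gam = make_plant_gametes(pop, np.zeros(1000, dtype=int), rng)
        gains = mutate_gametes(gam, 0.00245, rng).load_det.sum()
        assert abs(gains - 245) < 3 * np.sqrt(245)

    def test_idempotent_on_detrimental_alleles(self, rng):
        det = np.ones((100, 2), dtype=bool)
        det[50:] = False
        pop = make_plants(load_det=det)
        gam = make_plant_gametes(pop, np.zeros(5, dtype=int), rng)
        before = gam.load_det.copy()
        after = mutate_gametes(gam, 0.5, rng).load_det
        assert (after | before == after).all()  # only gains, never losses


class TestFuse:
    def test_identical_gametes_give_zero_heterozygosity(self, rng):
        pop = make_plants()
        gam = make_plant_gametes(pop, np.zeros(3, dtype=int), rng)
        assert fuse_plants(gam, gam).heterozygosity().max() == 0.0

    def test_opposite_neutral_classes_give_full_heterozygosity(self, rng):
        a = make_plants(load_cls=np.zeros((100, 2), np.uint8))
        b = make_plants(load_cls=np.ones((100, 2), np.uint8))
        ga = make_plant_gametes(a, np.zeros(3, dtype=int), rng)
        gb = make_plant_gametes(b, np.zeros(3, dtype=int), rng)
        assert fuse_plants(ga, gb).heterozygosity().min() == 1.0

    def test_detrimental_from_both_sides_is_lethal(self, rng):
        det = np.zeros((100, 2), dtype=bool)
        det[7] = True
        pop = make_plants(load_det=det)
        gam = make_plant_gametes(pop, np.zeros(3, dtype=int), rng)
        assert fuse_plants(gam, gam).lethal().all()


class TestInitPopulation:
    def test_zero_initial_frequency(self, rng):
        p = default_params(init_freq_resistance=0.0, K_plants=50,
                           K_herbivores=10)
        plants, _ = init_population(p, rng)
        assert (plants.investment("resistance") == 0).all()

    def test_initial_frequencies_and_heterozygosity(self, rng):
        p = default_params(K_plants=10_000, K_herbivores=100)
        plants, _ = init_population(p, rng)
        sigma = np.sqrt(0.25 / (4 * p.K_plants))
        assert abs(plants.allele_frequency("resistance") - 0.5) < 3 * sigma
        # expected h_i = 2pq = 0.5 at init_genome_het = 0.5
        assert abs(plants.heterozygosity().mean() - 0.5) < 0.01
        assert plants.detrimental_counts().sum() == 0

    def test_herbivore_sexes_split_evenly(self, rng):
        p = default_params(K_plants=10, K_herbivores=100)
        _, herbs = init_population(p, rng)
        assert herbs.female.sum() == 50

    def test_selfer_tags_only_under_non_heritable_mode(self, rng):
        p = default_params(K_plants=2000, K_herbivores=10,
                           selfing_mode="non_heritable",
                           init_selfer_fraction=0.3)
        plants, _ = init_population(p, rng)
        assert abs(plants.selfer_tag.mean() - 0.3) < 0.05
        p2 = default_params(K_plants=100, K_herbivores=10)
        plants2, _ = init_population(p2, rng)
        assert not plants2.selfer_tag.any()
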