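"""Shared fixtures: deterministic micro-populations and RNGs."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from herbisim.genetics import HerbivorePopulation, PlantPopulation

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_plants(res=(0, 0), tol=(0, 0), selfing=(0, 0), n=1, n_genes=100,
                load_cls=None, load_det=None, tag=False):
    """Build a population of ``n`` identical plants from explicit genotypes."""
    eff = np.tile(np.array([res, tol, selfing], dtype=np.int8), (n, 1, 1))
    if load_cls is None:
        load_cls = np.zeros((n_genes, 2), dtype=np.uint8)
    if load_det is None:
        load_det = np.zeros((n_genes, 2), dtype=bool)
    cls = np.tile(np.asarray(load_cls, dtype=np.uint8), (n, 1, 1))
    det = np.tile(np.asarray(load_det, dtype=bool), (n, 1, 1))
    tags = np.full(n, bool(tag))
    return PlantPopulation(eff, cls, det, tags)


def make_herbivores(anti=(0, 0), n=1, female=None):
    """Build a population of ``n`` identical herbivores."""
    counts = np.tile(np.array(anti, dtype=np.int8), (n, 1))
    if female is None:
        female = np.arange(n) % 2 == 0
    else:
        female = np.full(n, bool(female))
    return HerbivorePopulation(counts, female)
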