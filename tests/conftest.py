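"""Shared fixtures: a small synthetic paralog pair, its site catalog,
and a simulated chimeric sample, all deterministic."""

from __future__ import annotations

import pytest

from parafuse import (align_gene_pair, extract_informative_sites,
                      make_toy_gene_model, make_toy_gene_pair)
from parafuse.simulate import simulate_sample


@pytest.fixture(scope="session")
def toy_pair():
    pair, events = make_toy_gene_pair(length=2000, divergence=0.06,
                                      indel_rate=0.002, seed=7)
    return pair, events


@pytest.fixture(scope="session")
def toy_alignment(toy_pair):
    pair, _ = toy_pair
    return align_gene_pair(pair)


@pytest.fixture(scope="session")
def toy_catalog(toy_alignment):
    return extract_informative_sites(toy_alignment)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_gene_model(length=2000)


@pytest.fixture(scope="session")
def chimera_sample():
    """A 2 kb chimeric sample: 60 reads, nanopore-like error rates."""
    pair, model, reads, truth = simulate_sample(
        length=2000, n_reads=60, seed=11, crossover_feature="I2")
    return pair, model, reads, truth
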