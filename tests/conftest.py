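from __future__ import annotations

import logging

import numpy as np
import pytest

from spalp.io_formats import AssociationCatalog
from spalp.similarity import DiseaseDAG

logging.getLogger("spalp").setLevel(logging.ERROR)


@pytest.fixture
def chain_dag() -> DiseaseDAG:
    """R -> P -> A."""
    return DiseaseDAG(parents={"R": set(), "P": {"R"}, "A": {"P"}})


@pytest.fixture
def diamond_dag() -> DiseaseDAG:
    """R -> P1 -> A and R -> P2 -> A."""
    return DiseaseDAG(
        parents={"R": set(), "P1": {"R"}, "P2": {"R"}, "A": {"P1", "P2"}}
    )


@pytest.fixture
def sibling_dag() -> DiseaseDAG:
    """Siblings A, B under root P."""
    return DiseaseDAG(parents={"P": set(), "A": {"P"}, "B": {"P"}})


@pytest.fixture
def small_catalog() -> AssociationCatalog:
    return AssociationCatalog(
        mirna_names=("m1", "m2", "m3"),
        disease_names=("dA", "dB"),
        positive_pairs=frozenset({(0, 0), (0, 1), (1, 0)}),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
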