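import numpy as np
import pytest

import pma
from pma.morphology import default_catalogue, instantiate_all


@pytest.fixture(scope="session")
def region():
    return pma.generate_region()


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def small_circuit(region, catalogue):
    """A small but complete 13-class circuit reused across test modules."""
    cells = pma.place_cells(region, pma.PopulationSpec(scale=0.004), seed=42)
    morphs = instantiate_all(cells, catalogue, region, seed=43)
    edges = pma.build_connectome(cells, morphs, seed=44)
    return {"region": region, "cells": cells, "morphs": morphs, "edges": edges}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
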