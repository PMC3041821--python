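import numpy as np
import pytest

from ._oracles import random_count_table  # noqa: F401  (re-exported for tests)

from frthread.lspp import build_energy_table
from frthread.scoring import ScoringWeights
from frthread.synthetic import FixtureSpec, make_backbone, make_structure_set


@pytest.fixture(scope="session")
def helix_backbone():
    return make_backbone([(-57.0, -47.0)] * 20)


@pytest.fixture(scope="session")
def strand_backbone():
    return make_backbone([(-120.0, 130.0)] * 20)


@pytest.fixture(scope="session")
def structure_set():
    """50 random segmented structures used to train fixture potentials."""
    return make_structure_set(50, seed=42)


@pytest.fixture(scope="session")
def table3(structure_set):
    return build_energy_table([s for s, _ in structure_set], "frag3")


@pytest.fixture(scope="session")
def table9(structure_set):
    return build_energy_table([s for s, _ in structure_set], "frag9")


@pytest.fixture(scope="session")
def frt5_weights():
    return ScoringWeights(w4=2.0, w5=2.0)
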