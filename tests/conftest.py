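import numpy as np
import pytest

from tsedit import (
    EditingSite,
    HexamerSet,
    LibraryRecord,
    ScoringMatrix,
    SimulationConfig,
)


@pytest.fixture
def toy_matrix():
    """2-wide matrix rewarding A at position 1 and G at position 2."""
    w = np.zeros((2, 4))
    w[0, 0] = 1.0  # A at position 1
    w[1, 2] = 1.0  # G at position 2
    return ScoringMatrix("toy", w, threshold=1.5)


@pytest.fixture
def paper_hexamers():
    return HexamerSet("four", frozenset({"GGGAGG", "TAGGTA", "TTAGGT", "CTTAGG"}))


@pytest.fixture
def plus_site():
    return EditingSite("chr1", "+", 100, "GENEX")


@pytest.fixture
def minus_site():
    return EditingSite("chr1", "-", 200)


@pytest.fixture
def small_libraries():
    return [
        LibraryRecord("L1", "brain"),
        LibraryRecord("L2", "Brain "),
        LibraryRecord("L3", "liver"),
        LibraryRecord("L4", "mixed"),
        LibraryRecord("L5", ""),
    ]


def make_config(**overrides) -> SimulationConfig:
    base = dict(
        n_tissues=2,
        libraries_per_tissue=1,
        n_sites=3,
        obs_per_site_per_library=20,
        background_rate=0.1,
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def config_factory():
    return make_config
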