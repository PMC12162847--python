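import numpy as np
import pytest

from copmap.layout import GenomeLayout, MarkerMap, arabidopsis_layout


@pytest.fixture(scope="session")
def layout():
    return arabidopsis_layout()


@pytest.fixture
def small_layout():
    """Four small chromosomes: fast simulations, still multi-chromosome."""
    return GenomeLayout(
        chromosomes=[("c1", 6_000_000), ("c2", 5_000_000),
                     ("c3", 4_000_000), ("c4", 4_500_000)],
        centromere_mid={"c1": 3_000_000, "c2": 2_500_000,
                        "c3": 2_000_000, "c4": 2_250_000},
        nrz={"c1": (2_500_000, 3_500_000)},
    )


@pytest.fixture
def one_chrom_layout():
    return GenomeLayout([("chr1", 20_000_000)])


@pytest.fixture
def dense_markers(one_chrom_layout):
    rng = np.random.default_rng(123)
    pos = np.unique(rng.integers(0, 20_000_000, size=6000))
    return MarkerMap({"chr1": pos})


def make_rng(seed=0):
    return np.random.default_rng(seed)


@pytest.fixture
def rng():
    return make_rng(0)
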