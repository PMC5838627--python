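import numpy as np
import pytest

from fretprobe import BufferConditions, build_fixture, table_oligo


@pytest.fixture(scope="session")
def buffer():
    """The assay buffer: 50 mM Na+, 2 mM Mg2+, 20 uM total strands."""
    return BufferConditions()


@pytest.fixture(scope="session")
def fixture_g():
    return build_fixture("G", seed=1)


@pytest.fixture(scope="session")
def fixture_a():
    return build_fixture("A", seed=1)


@pytest.fixture(scope="session")
def locus(fixture_g):
    return fixture_g.snp_locus()


@pytest.fixture(scope="session")
def acceptor():
    return table_oligo("OG649")


@pytest.fixture(scope="session")
def donor():
    return table_oligo("OG648")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
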