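import numpy as np
import pytest

from dmos import ldpc, tape


@pytest.fixture(scope="session")
def domains():
    return tape.default_domains()


@pytest.fixture(scope="session")
def block(domains):
    """The standard 48-register high-entropy tape block."""
    return tape.build_block(48, "high_entropy", domains=domains)


@pytest.fixture(scope="session")
def lex_block(domains):
    return tape.build_block(48, "lexicographic", domains=domains)


@pytest.fixture(scope="session")
def mini_block(domains):
    """4-register block for cheap end-to-end tests."""
    return tape.build_block(4, "high_entropy", domains=domains, block_id="mini")


@pytest.fixture(scope="session")
def default_code():
    return ldpc.build_code()


@pytest.fixture(scope="session")
def toy_code():
    """n=12 regular code, small enough for exhaustive codeword enumeration."""
    return ldpc.build_code("regular", "1/2", expansion=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
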