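import numpy as np
import pytest
from hypothesis import settings

# reproducible hypothesis runs
settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160104)


@pytest.fixture(scope="session")
def published_regexes():
    """The per-class Perl expressions of the original method, verbatim: the oracle
    for pattern construction (independent of the generator)."""
    return {
        "AAAA": r"(G{3,}).{1,7}\1.{1,7}\1.{1,7}\1|(C{3,}).{1,7}\2.{1,7}\2.{1,7}\2",
        "AABB": r"(G{3,}).{1,7}\1.{0,7}(C{3,}).{1,7}\2",
        "BBAA": r"(C{3,}).{1,7}\1.{0,7}(G{3,}).{1,7}\2",
        "ABBA": r"(G{3,}).{0,7}(C{3,}).{1,7}\2.{0,7}\1|(C{3,}).{0,7}(G{3,}).{1,7}\4.{0,7}\3",
        "ABAB": r"(G{3,}).{0,7}(C{3,}).{0,7}\1.{0,7}\2",
        "BABA": r"(C{3,}).{0,7}(G{3,}).{0,7}\1.{0,7}\2",
        "ABBB": r"(G{3,}).{0,7}(C{3,}).{1,7}\2.{1,7}\2|(G{3,}).{1,7}\3.{1,7}\3.{0,7}(C{3,})",
        "BAAA": r"(C{3,}).{0,7}(G{3,}).{1,7}\2.{1,7}\2|(C{3,}).{1,7}\3.{1,7}\3.{0,7}(G{3,})",
        "ABAA": r"(G{3,}).{0,7}(C{3,}).{0,7}\1.{1,7}\1|(C{3,}).{1,7}\3.{0,7}(G{3,}).{0,7}\3",
        "BABB": r"(C{3,}).{0,7}(G{3,}).{0,7}\1.{1,7}\1|(G{3,}).{1,7}\3.{0,7}(C{3,}).{0,7}\3",
    }


@pytest.fixture(scope="session")
def worked_example():
    """The 15-mer whose duplex contributes 12 guanines to one G4 cage."""
    return "GGGAGGGACCCACCC"
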