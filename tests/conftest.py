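import pytest

from residuefinder import CorpusConfig, generate, get_library


@pytest.fixture(scope="session")
def libraries():
    """All eight built-in libraries, compiled once per session."""
    libs = {}
    for name in ("mf", "mf_cut", "rf1", "rf1_cut", "rf2", "rf2_cut", "rf3", "rf3_cut"):
        libs[name] = get_library(name)
        libs[name].compiled  # force compilation up front
    return libs


@pytest.fixture(scope="session")
def small_corpus():
    """A small mixed corpus: all forms, all distractor classes."""
    config = CorpusConfig(n_docs=12, seed=42)
    return generate(config)


@pytest.fixture(scope="session")
def bib_corpus():
    """A corpus whose documents carry bibliography tails."""
    config = CorpusConfig(n_docs=10, seed=7, include_bibliography=True)
    return generate(config)
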