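import numpy as np
import pytest

from lexitest.instrument import build_instrument, master_key
from lexitest.simulate import (
    SyntheticVocabularyConfig,
    generate_vocabulary,
    prepare_corpus,
)


@pytest.fixture(scope="session")
def vocab_entries():
    """A 1,000-word synthetic Zipf vocabulary (fixed seed)."""
    return generate_vocabulary(SyntheticVocabularyConfig(n_words=1000, seed=11))


@pytest.fixture(scope="session")
def corpus(vocab_entries):
    """(entries, partition, chain, word set) prepared from the fixture vocab."""
    return prepare_corpus(vocab_entries)


@pytest.fixture(scope="session")
def default_instrument(corpus):
    """A default 70-item instantiation built from the fixture corpus."""
    _, partition, chain, words = corpus
    return build_instrument(partition, chain, words, seed=42)


@pytest.fixture(scope="session")
def default_key(default_instrument):
    return master_key(default_instrument)


@pytest.fixture(scope="session")
def default_weights(default_instrument):
    return {it.item_id: it.weight for it in default_instrument.items}
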