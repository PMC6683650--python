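import numpy as np
import pytest

from projcoder.corpus import Corpus, Vocabulary
from projcoder.embedding import EmbeddingTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """A 20-token, 8-dimensional random embedding table."""
    tokens = [f"tok{i}" for i in range(20)]
    vocab = Vocabulary({t: i for i, t in enumerate(tokens)}, {t: 1 for t in tokens}, 1)
    vecs = rng.normal(size=(20, 8))
    return EmbeddingTable(vocab, vecs)


@pytest.fixture
def tiny_corpus():
    docs = [
        ["acute", "pancreatitis", "with", "biliary", "obstruction"],
        ["chronic", "pancreatitis", "acute", "flare"],
        ["biliary", "obstruction", "suspected"],
        ["acute", "hepatitis", "with", "jaundice"],
    ]
    return Corpus(docs, source_id="tiny")
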