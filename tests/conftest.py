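import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctxsel.corpus_io import Corpus, TokenizedDocument

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_corpus(docs, splits=None):
    """Build a Corpus from [(doc_id, [tokens], label), ...]."""
    splits = splits or {}
    return Corpus.from_documents(
        [
            TokenizedDocument(
                doc_id=i, tokens=tuple(toks), label=lab,
                split=splits.get(i, "train"),
            )
            for i, toks, lab in docs
        ]
    )


def random_corpus(rng: np.random.Generator, max_docs=8, vocab_size=8,
                  max_len=12, n_categories=2):
    """Small random corpus for property tests."""
    vocab = [f"w{i}" for i in range(vocab_size)]
    cats = [f"c{i}" for i in range(n_categories)]
    n_docs = int(rng.integers(2, max_docs + 1))
    docs = []
    for d in range(n_docs):
        length = int(rng.integers(1, max_len + 1))
        toks = [vocab[int(i)] for i in rng.integers(0, vocab_size, length)]
        label = cats[int(rng.integers(0, n_categories))]
        docs.append((f"d{d}", toks, label))
    # ensure every category is populated
    for k, cat in enumerate(cats):
        if not any(lab == cat for _, _, lab in docs):
            docs.append((f"pad{k}", [vocab[0]], cat))
    return make_corpus(docs)


@pytest.fixture
def toy_corpus():
    """c1 = {d1: [x, y], d2: [x]}, c2 = {d3: [y]} — the hand-count fixture."""
    return make_corpus(
        [("d1", ["x", "y"], "c1"), ("d2", ["x"], "c1"), ("d3", ["y"], "c2")]
    )


@pytest.fixture
def templated_corpus():
    """Term t occurs once per c1 document inside an identical 7-token
    phrase; c2 documents do not contain t."""
    phrase = ["p", "q", "r", "t", "u", "v", "w"]
    return make_corpus(
        [
            ("d1", phrase, "c1"),
            ("d2", phrase, "c1"),
            ("d3", ["z1", "z2", "z3"], "c2"),
            ("d4", ["z4", "z5", "z6"], "c2"),
        ]
    )
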