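import numpy as np
import pytest

import driftscan as ds


@pytest.fixture
def mini_corpus():
    """Tiny two-document clinical-style corpus with entities."""
    d1 = ds.make_document(
        "d1",
        "Seen John Smith on 12/03/2021 . Plan reviewed .",
        [("PERSON", 5, 15), ("DATE", 19, 29)],
    )
    d2 = ds.make_document(
        "d2",
        "BP : 120/80\n- follow up\nSEEN by JOHN .",
    )
    return ds.Corpus("mini", [d1, d2])


@pytest.fixture
def fixture_pair():
    """A seeded (reference, drifted) fixture corpus pair."""
    ref = ds.generate_fixture_corpus(ds.DriftKnobs(seed=11), 60, name="ref")
    drift = ds.generate_fixture_corpus(
        ds.DriftKnobs(vocab_substitution_rate=0.3, seed=11), 60, name="drift"
    )
    return ref, drift


class ConstantProbScorer:
    """LM stub assigning a fixed probability to every word token."""

    name = "const"

    def __init__(self, prob: float):
        self.prob = prob

    def score(self, text):
        words = [t for t in ds.tokenize(text) if t.is_word]
        n = max(len(words), 1)
        return -n * np.log(self.prob), n


@pytest.fixture
def constant_scorer():
    return ConstantProbScorer
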