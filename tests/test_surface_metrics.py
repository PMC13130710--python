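"""Surface drift metrics: examples, oracle equivalence and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

import driftscan as ds
from driftscan.surface_metrics import (
    Distribution,
    MetricError,
    UnigramLMScorer,
    count_syllables,
    is_undefined,
    _mtld_directional,
)


def corpus_of(*texts: str, name="c") -> ds.Corpus:
    return ds.Corpus(name, [ds.make_document(f"d{i}", t) for i, t in enumerate(texts)])


# ---------------------------------------------------------------------------
# n-gram distributions and JSD
# ---------------------------------------------------------------------------

def test_unigram_counts():
    dist = ds.ngram_distribution(corpus_of("a b a"), 1)
    assert dist.as_dict() == {"a": pytest.approx(2 / 3), "b": pytest.approx(1 / 3)}


def test_bigrams_do_not_cross_sentence_boundary():
    dist = ds.ngram_distribution(corpus_of("a b. a"), 2)
    assert set(dist.support) == {("a", "b")}


def test_bigram_of_single_token_corpus_errors():
    with pytest.raises(MetricError, match="empty lexical stream"):
        ds.ngram_distribution(corpus_of("a"), 2)


def test_jsd_identity_disjoint_and_derived():
    p = Distribution(("a", "b"), np.array([0.5, 0.5]))
    q = Distribution(("a", "b"), np.array([1.0, 0.0]))
    r = Distribution(("c",), np.array([1.0]))
    assert ds.jsd(p, p) == 0.0
    assert ds.jsd(p, r) == pytest.approx(1.0)
    assert ds.jsd(p, q) == pytest.approx(0.31127812445913283)


@given(
    st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
    st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
)
@settings(max_examples=200, deadline=None)
def test_jsd_matches_scipy_and_is_symmetric_bounded(wp, wq):
    """JSD agrees with scipy's (squared) Jensen-Shannon distance on shared
    support, is symmetric, and lies in [0, 1]."""
    support = tuple(f"t{i}" for i in range(max(len(wp), len(wq))))
    pv = np.array(wp + [0.0] * (len(support) - len(wp)))
    qv = np.array(wq + [0.0] * (len(support) - len(wq)))
    pv, qv = pv / pv.sum(), qv / qv.sum()
    p = Distribution(support, pv)
    q = Distribution(support, qv)
    val = ds.jsd(p, q)
    assert val == pytest.approx(ds.jsd(q, p))
    assert -1e-12 <= val <= 1 + 1e-12
    assert val == pytest.approx(jensenshannon(pv, qv, base=2) ** 2, abs=1e-8)


def test_vocab_jaccard():
    assert ds.vocab_jaccard(corpus_of("a b c"), corpus_of("b c d")) == 0.5
    same = corpus_of("x y z")
    assert ds.vocab_jaccard(same, corpus_of("x y z", name="c2")) == 1.0
    assert ds.vocab_jaccard(corpus_of("a"), corpus_of("b")) == 0.0


def test_vocab_jaccard_shared_doc_never_decreases():
    a, b = corpus_of("a b"), corpus_of("c d")
    before = ds.vocab_jaccard(a, b)
    a2, b2 = corpus_of("a b", "shared words"), corpus_of("c d", "shared words")
    assert ds.vocab_jaccard(a2, b2) >= before


# ---------------------------------------------------------------------------
# Style summaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "texts,mean,std",
    [
        (("a b\nc d",), 2.0, 0.0),
        (("a b\nc d e f",), 3.0, 1.0),
        (("a\nb c\nd e f",), 2.0, pytest.approx(0.8164965809)),
    ],
)
def test_sentence_length_stats_population_std(texts, mean, std):
    assert ds.sentence_length_stats(corpus_of(*texts)) == (mean, std)


def test_char_category_rates():
    assert ds.char_category_rates(corpus_of("BP : 120")) == (pytest.approx(1 / 3), pytest.approx(1 / 3))
    assert ds.char_category_rates(corpus_of("only words here")) == (0.0, 0.0)
    assert ds.char_category_rates(corpus_of("12 .")) == (0.5, 0.5)


# ---------------------------------------------------------------------------
# Lexical diversity
# ---------------------------------------------------------------------------

def test_vocab_entropy():
    assert ds.vocab_entropy(corpus_of("a a a")) == 0.0
    assert ds.vocab_entropy(corpus_of("a b")) == 1.0
    assert ds.vocab_entropy(corpus_of("a a b c")) == pytest.approx(1.5)


def test_mtld_examples():
    assert ds.mtld("a b a b a b".split()) == pytest.approx(3.0)
    assert is_undefined(ds.mtld(list("abcdefghij")))
    with pytest.raises(MetricError):
        ds.mtld([])


def mtld_forward_oracle(tokens, threshold=0.72):
    """Independent step-by-step simulation of the forward pass."""
    factors = 0.0
    seen, count = set(), 0
    ttr = 1.0
    for tok in tokens:
        seen.add(tok)
        count += 1
        ttr = len(seen) / count
        if ttr < threshold:
            factors += 1
            seen, count, ttr = set(), 0, 1.0
    if count:
        factors += (1 - ttr) / (1 - threshold)
    return math.inf if factors == 0 else len(tokens) / factors


def test_mtld_forward_matches_oracle_on_random_sequences():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        length = int(rng.integers(5, 201))
        alpha = int(rng.integers(2, 51))
        seq = [f"w{int(i)}" for i in rng.integers(0, alpha, size=length)]
        expected = mtld_forward_oracle(seq)
        got = _mtld_directional(seq, 0.72)
        if math.isinf(expected):
            assert is_undefined(got)
        else:
            assert got == pytest.approx(expected, abs=1e-8)


def test_yules_k():
    assert ds.yules_k(corpus_of("a b c d")) == 0.0
    assert ds.yules_k(corpus_of("a a b")) == pytest.approx(1e4 * 2 / 9)
    n = 7
    assert ds.yules_k(corpus_of(" ".join(["x"] * n))) == pytest.approx(1e4 * (n * n - n) / (n * n))


def test_yules_k_order_invariant():
    assert ds.yules_k(corpus_of("a a b c c c")) == ds.yules_k(corpus_of("c a c b a c"))


def test_distinct_and_self_repetition():
    assert ds.distinct_n(corpus_of("a b a b"), 1) == 0.5
    assert ds.self_repetition(corpus_of("a b a b a b")) == pytest.approx(1 / 3)
    assert ds.self_repetition(corpus_of("a b c d e f g h")) == 0.0
    with pytest.raises(MetricError):
        ds.self_repetition(corpus_of("a b"))  # no 4-grams


def test_distinct_n_document_order_invariant():
    a = corpus_of("a b c", "c d e")
    b = corpus_of("c d e", "a b c")
    assert ds.distinct_n(a, 2) == ds.distinct_n(b, 2)


# ---------------------------------------------------------------------------
# Readability
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "word,syllables",
    [("cat", 1), ("the", 1), ("table", 2), ("made", 1), ("rhythm", 1), ("ab12", 1), ("idea", 2)],
)
def test_syllable_heuristic(word, syllables):
    assert count_syllables(word) == syllables


def test_flesch_kincaid_example_and_scale_invariance():
    c = corpus_of("The cat sat on the mat.")
    assert ds.flesch_kincaid(c) == pytest.approx(-1.45)
    doubled = corpus_of("The cat sat on the mat.", "The cat sat on the mat.")
    assert ds.flesch_kincaid(doubled) == pytest.approx(ds.flesch_kincaid(c))


def test_flesch_kincaid_matches_direct_formula_on_random_corpora():
    rng = np.random.default_rng(3)
    words = ["alpha", "bed", "hospital", "examine", "note", "care", "therapy"]
    for _ in range(50):
        n = int(rng.integers(4, 40))
        toks = [words[int(i)] for i in rng.integers(0, len(words), size=n)]
        text = " ".join(toks) + " ."
        c = corpus_of(text)
        syll = sum(count_syllables(w) for w in toks)
        expected = 0.39 * n + 11.8 * (syll / n) - 15.59
        assert ds.flesch_kincaid(c) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Perplexity
# ---------------------------------------------------------------------------

def test_uniform_stub_perplexity_equals_vocab_size(constant_scorer):
    vocab_size = 25
    scorer = constant_scorer(1.0 / vocab_size)
    assert ds.corpus_perplexity(corpus_of("some words in here"), scorer) == pytest.approx(vocab_size)


def test_prob_one_scorer_gives_unit_perplexity(constant_scorer):
    assert ds.corpus_perplexity(corpus_of("a b c"), constant_scorer(1.0)) == pytest.approx(1.0)


def test_two_token_stub_example():
    class Stub:
        name = "stub"

        def score(self, text):
            return -(math.log(0.5) + math.log(0.125)), 2

    # exp((ln 2 + ln 8)/2) = sqrt(16) = 4
    assert ds.corpus_perplexity(corpus_of("x y"), Stub()) == pytest.approx(4.0)


def test_unigram_scorer_is_deterministic_and_positive(fixture_pair):
    ref, _ = fixture_pair
    s1, s2 = UnigramLMScorer(ref), UnigramLMScorer(ref)
    nll, n = s1.score("patient was seen in clinic")
    assert nll > 0 and n == 5
    assert s1.score("follow up") == s2.score("follow up")


# ---------------------------------------------------------------------------
# Family aggregator
# ---------------------------------------------------------------------------

def test_surface_profile_self_is_zero(fixture_pair):
    ref, _ = fixture_pair
    prof = ds.surface_profile(ref, ref, UnigramLMScorer(ref))
    d = prof.as_dict()
    assert d.pop("vocab_jaccard") == 1.0
    assert all(v == 0.0 for v in d.values())


def test_surface_profile_symmetric(fixture_pair):
    ref, drift = fixture_pair
    a = ds.surface_profile(ref, drift).as_dict()
    b = ds.surface_profile(drift, ref).as_dict()
    for key in a:
        if a[key] is None:
            assert b[key] is None
        else:
            assert a[key] == pytest.approx(b[key]), key


def test_surface_profile_without_scorer_flags_perplexity(fixture_pair):
    ref, drift = fixture_pair
    prof = ds.surface_profile(ref, drift, scorer=None)
    assert prof.perplexity_diff is None


def test_surface_profile_drift_increases_jsd(fixture_pair):
    ref, drift = fixture_pair
    base = ds.generate_fixture_corpus(ds.DriftKnobs(seed=11), 60, name="same")
    assert ds.surface_profile(ref, drift).jsd_unigram > ds.surface_profile(ref, base).jsd_unigram
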