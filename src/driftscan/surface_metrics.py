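"""Surface-level drift metrics between two corpora.

Covers n-gram Jensen–Shannon divergence, vocabulary Jaccard overlap, style
summaries (sentence length, punctuation/digit rates), lexical diversity
(entropy, MTLD, Yule's K, Distinct-1/2, 4-gram self-repetition), readability
(Flesch–Kincaid grade) and language-model perplexity difference behind a
pluggable scorer contract.

Conventions fixed for reproducibility:

* lexical metrics operate on lowercased word tokens (punctuation-only tokens
  excluded); punctuation/digit rates use all tokens;
* bigrams do not cross sentence boundaries and carry no padding symbols;
* every pairwise ``*_diff`` is an unsigned absolute difference;
* sentence-length spread is the population standard deviation;
* MTLD is computed per document and averaged; entropy, Yule's K and
  Distinct-n are pooled over the corpus token stream.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, fields
from typing import Iterable, Protocol, Sequence

import numpy as np

from .corpus_model import Corpus, Document

MTLD_TTR_THRESHOLD = 0.72

#: Sentinel for metrics whose value is undefined on the given input
#: (e.g. MTLD on a sequence whose running TTR never drops below threshold).
UNDEFINED = float("nan")


class MetricError(ValueError):
    """Raised when a metric's preconditions are not met."""


class LMScorer(Protocol):
    """Contract for pluggable language-model fluency scorers."""

    name: str

    def score(self, text: str) -> tuple[float, int]:
        """Return (total negative log-likelihood in nats, token count)."""
        ...


def is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


# ---------------------------------------------------------------------------
# Lexical streams and distributions
# ---------------------------------------------------------------------------

def _doc_word_stream(doc: Document) -> list[str]:
    return [t.text.lower() for t in doc.tokens if t.is_word]


def _sentence_word_streams(doc: Document) -> Iterable[list[str]]:
    for s, e in doc.sentences:
        yield [t.text.lower() for t in doc.tokens[s:e] if t.is_word]


def _corpus_word_stream(corpus: Corpus) -> list[str]:
    out: list[str] = []
    for doc in corpus:
        out.extend(_doc_word_stream(doc))
    return out


@dataclass(frozen=True)
class Distribution:
    """A discrete probability distribution over tokens or n-gram tuples."""

    support: tuple
    probs: np.ndarray

    def __post_init__(self) -> None:
        if len(self.support) != len(self.probs):
            raise MetricError("support/probs length mismatch")
        if len(self.support) != len(set(self.support)):
            raise MetricError("support items not unique")
        if self.probs.size and abs(float(self.probs.sum()) - 1.0) > 1e-9:
            raise MetricError("probabilities do not sum to 1")

    @classmethod
    def from_counts(cls, counts: Counter) -> "Distribution":
        support = tuple(sorted(counts))
        total = sum(counts.values())
        probs = np.array([counts[s] / total for s in support], dtype=float)
        return cls(support, probs)

    def as_dict(self) -> dict:
        return dict(zip(self.support, self.probs))


def ngram_distribution(corpus: Corpus, n: int) -> Distribution:
    """Normalized n-gram counts over lowercased word tokens.

    Bigrams are collected within sentences only.
    """
    if n not in (1, 2):
        raise MetricError(f"n must be 1 or 2, got {n}")
    counts: Counter = Counter()
    for doc in corpus:
        for words in _sentence_word_streams(doc):
            if n == 1:
                counts.update(words)
            else:
                counts.update(zip(words, words[1:]))
    if not counts:
        raise MetricError(f"empty lexical stream for {n}-grams in corpus {corpus.name}")
    return Distribution.from_counts(counts)


def jsd(p: Distribution, q: Distribution) -> float:
    """Jensen–Shannon divergence in bits (base 2), on the union support.

    Symmetric, bounded in [0, 1]; zero iff the distributions coincide.
    """
    support = sorted(set(p.support) | set(q.support))
    pd, qd = p.as_dict(), q.as_dict()
    pv = np.array([pd.get(s, 0.0) for s in support])
    qv = np.array([qd.get(s, 0.0) for s in support])
    m = 0.5 * (pv + qv)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(pv, m) + 0.5 * kl(qv, m)


def vocab_jaccard(a: Corpus, b: Corpus) -> float:
    """|Va ∩ Vb| / |Va ∪ Vb| over lowercased word types."""
    va, vb = set(_corpus_word_stream(a)), set(_corpus_word_stream(b))
    if not va or not vb:
        raise MetricError("empty lexical stream")
    return len(va & vb) / len(va | vb)


# ---------------------------------------------------------------------------
# Style summaries
# ---------------------------------------------------------------------------

def sentence_length_stats(corpus: Corpus) -> tuple[float, float]:
    """Mean and population std of sentence length in tokens (all tokens)."""
    lengths = [e - s for doc in corpus for s, e in doc.sentences]
    if not lengths:
        raise MetricError(f"corpus {corpus.name} has no sentences")
    arr = np.array(lengths, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


def char_category_rates(corpus: Corpus) -> tuple[float, float]:
    """(punctuation-token rate, digit-containing-token rate) over all tokens."""
    tokens = [t for doc in corpus for t in doc.tokens]
    if not tokens:
        raise MetricError(f"corpus {corpus.name} has no tokens")
    punct = sum(1 for t in tokens if not t.is_word)
    digit = sum(1 for t in tokens if any(c.isdigit() for c in t.text))
    return punct / len(tokens), digit / len(tokens)


# ---------------------------------------------------------------------------
# Lexical diversity
# ---------------------------------------------------------------------------

def vocab_entropy(corpus: Corpus) -> float:
    """Shannon entropy (bits) of the pooled unigram distribution."""
    words = _corpus_word_stream(corpus)
    if not words:
        raise MetricError("empty lexical stream")
    probs = np.array(list(Counter(words).values()), dtype=float)
    probs /= probs.sum()
    return float(-np.sum(probs * np.log2(probs)))


def _mtld_directional(tokens: Sequence[str], threshold: float) -> float:
    """One directional MTLD pass (McCarthy–Jarvis forward procedure)."""
    factors = 0.0
    types: set[str] = set()
    count = 0
    ttr = 1.0
    for tok in tokens:
        count += 1
        types.add(tok)
        ttr = len(types) / count
        if ttr < threshold:
            factors += 1.0
            types.clear()
            count = 0
            ttr = 1.0
    if count > 0:
        factors += (1.0 - ttr) / (1.0 - threshold)
    if factors == 0.0:
        return UNDEFINED
    return len(tokens) / factors


def mtld(tokens: Sequence[str], ttr_threshold: float = MTLD_TTR_THRESHOLD) -> float:
    """Measure of Textual Lexical Diversity: mean of forward/backward passes.

    Returns the :data:`UNDEFINED` sentinel when either direction completes
    zero factors (running TTR never falls below the threshold).
    """
    if not tokens:
        raise MetricError("MTLD of empty sequence")
    fwd = _mtld_directional(tokens, ttr_threshold)
    bwd = _mtld_directional(list(reversed(tokens)), ttr_threshold)
    if is_undefined(fwd) or is_undefined(bwd):
        return UNDEFINED
    return 0.5 * (fwd + bwd)


def corpus_mtld(corpus: Corpus, ttr_threshold: float = MTLD_TTR_THRESHOLD) -> float:
    """Per-document MTLD averaged over documents where it is defined.

    Undefined only when no document yields a defined value.
    """
    vals = []
    any_words = False
    for doc in corpus:
        words = _doc_word_stream(doc)
        if not words:
            continue
        any_words = True
        v = mtld(words, ttr_threshold)
        if not is_undefined(v):
            vals.append(v)
    if not any_words:
        raise MetricError("empty lexical stream")
    if not vals:
        return UNDEFINED
    return float(np.mean(vals))


def yules_k(corpus: Corpus) -> float:
    """Yule's characteristic K = 1e4 · (Σ m²·V(m) − N) / N²."""
    words = _corpus_word_stream(corpus)
    if not words:
        raise MetricError("empty lexical stream")
    n = len(words)
    freq_of_freq = Counter(Counter(words).values())
    s2 = sum(m * m * vm for m, vm in freq_of_freq.items())
    return 1e4 * (s2 - n) / (n * n)


def _pooled_ngrams(corpus: Corpus, n: int) -> Counter:
    counts: Counter = Counter()
    for doc in corpus:
        words = _doc_word_stream(doc)
        counts.update(zip(*(words[i:] for i in range(n))))
    return counts


def distinct_n(corpus: Corpus, n: int) -> float:
    """Distinct-n: distinct n-grams over total n-gram occurrences, pooled
    across documents (n-grams never span document boundaries)."""
    counts = _pooled_ngrams(corpus, n)
    total = sum(counts.values())
    if total == 0:
        raise MetricError(f"no {n}-grams in corpus {corpus.name}")
    return len(counts) / total


def self_repetition(corpus: Corpus, n: int = 4) -> float:
    """Repeated n-gram occurrence fraction: 1 − Distinct-n (default 4-grams)."""
    counts = _pooled_ngrams(corpus, n)
    total = sum(counts.values())
    if total == 0:
        raise MetricError(f"no {n}-grams in corpus {corpus.name}")
    return 1.0 - len(counts) / total


# ---------------------------------------------------------------------------
# Readability
# ---------------------------------------------------------------------------

_VOWELS = set("aeiouy")


def count_syllables(word: str) -> int:
    """Heuristic syllable count: maximal vowel-letter runs (aeiouy), minus a
    trailing silent-e run unless the word ends in "le"; floored at 1."""
    w = word.lower()
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(w):
        if w[i] in _VOWELS:
            j = i
            while j < len(w) and w[j] in _VOWELS:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    count = len(runs)
    if (
        runs
        and w.endswith("e")
        and not w.endswith("le")
        and runs[-1][1] == len(w)
        and set(w[runs[-1][0] : runs[-1][1]]) == {"e"}
    ):
        count -= 1
    return max(count, 1)


def flesch_kincaid(corpus: Corpus) -> float:
    """Flesch–Kincaid grade over the pooled corpus:
    0.39·(words/sentences) + 11.8·(syllables/words) − 15.59."""
    n_sent = sum(len(doc.sentences) for doc in corpus)
    words = _corpus_word_stream(corpus)
    if n_sent == 0 or not words:
        raise MetricError("Flesch–Kincaid needs ≥1 sentence and ≥1 word")
    syll = sum(count_syllables(w) for w in words)
    return 0.39 * (len(words) / n_sent) + 11.8 * (syll / len(words)) - 15.59


# ---------------------------------------------------------------------------
# Perplexity
# ---------------------------------------------------------------------------

class UnigramLMScorer:
    """Deterministic unigram language model with add-one smoothing.

    Fitted on a reference corpus; scores text under its own (shared)
    tokenization.  Serves as the built-in :class:`LMScorer` backend; a causal
    transformer can be plugged in behind the same contract.
    """

    name = "unigram"

    def __init__(self, reference: Corpus) -> None:
        words = _corpus_word_stream(reference)
        if not words:
            raise MetricError("cannot fit unigram scorer on empty lexical stream")
        self._counts = Counter(words)
        # +1 bucket reserved for out-of-vocabulary tokens
        self._denom = len(words) + len(self._counts) + 1

    def prob(self, word: str) -> float:
        return (self._counts.get(word.lower(), 0) + 1) / self._denom

    def score(self, text: str) -> tuple[float, int]:
        from .corpus_model import tokenize

        words = [t.text.lower() for t in tokenize(text) if t.is_word]
        if not words:
            return 0.0, 1
        nll = -sum(math.log(self.prob(w)) for w in words)
        return nll, len(words)


def corpus_perplexity(corpus: Corpus, scorer: LMScorer) -> float:
    """Token-weighted corpus perplexity: exp(Σ NLL / Σ token counts)."""
    if len(corpus) == 0:
        raise MetricError("perplexity of empty corpus")
    total_nll = 0.0
    total_tokens = 0
    for doc in corpus:
        try:
            nll, n_tok = scorer.score(doc.text)
        except Exception as exc:
            raise MetricError(f"scorer failed on {doc.doc_id}: {exc}") from exc
        total_nll += nll
        total_tokens += n_tok
    return math.exp(total_nll / total_tokens)


# ---------------------------------------------------------------------------
# Family aggregator
# ---------------------------------------------------------------------------

@dataclass
class SurfaceProfile:
    """Pairwise surface drift profile; every ``*_diff`` is |train − eval|."""

    jsd_unigram: float
    jsd_bigram: float
    vocab_jaccard: float
    sent_len_mean_diff: float
    sent_len_std_diff: float
    punct_rate_diff: float
    digit_rate_diff: float
    vocab_entropy_diff: float
    mtld_diff: float
    yules_k_diff: float
    distinct1_diff: float
    distinct2_diff: float
    self_repetition_diff: float
    fk_grade_diff: float
    perplexity_diff: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def surface_profile(
    train: Corpus, eval: Corpus, scorer: LMScorer | None = None
) -> SurfaceProfile:
    """Compute the full surface drift family for a (train, eval) pair.

    ``perplexity_diff`` is ``None`` when no scorer is supplied.  MTLD can be
    the undefined sentinel (NaN) on degenerate corpora; downstream
    correlation drops such pairs.
    """

    def diff(fn, *args) -> float:
        a, b = fn(train, *args), fn(eval, *args)
        if is_undefined(a) or is_undefined(b):
            return UNDEFINED
        return abs(a - b)

    try:
        mean_a, std_a = sentence_length_stats(train)
        mean_b, std_b = sentence_length_stats(eval)
        punct_a, digit_a = char_category_rates(train)
        punct_b, digit_b = char_category_rates(eval)
        ppl_diff: float | None = None
        if scorer is not None:
            ppl_diff = abs(corpus_perplexity(train, scorer) - corpus_perplexity(eval, scorer))
        return SurfaceProfile(
            jsd_unigram=jsd(ngram_distribution(train, 1), ngram_distribution(eval, 1)),
            jsd_bigram=jsd(ngram_distribution(train, 2), ngram_distribution(eval, 2)),
            vocab_jaccard=vocab_jaccard(train, eval),
            sent_len_mean_diff=abs(mean_a - mean_b),
            sent_len_std_diff=abs(std_a - std_b),
            punct_rate_diff=abs(punct_a - punct_b),
            digit_rate_diff=abs(digit_a - digit_b),
            vocab_entropy_diff=diff(vocab_entropy),
            mtld_diff=diff(corpus_mtld),
            yules_k_diff=diff(yules_k),
            distinct1_diff=diff(distinct_n, 1),
            distinct2_diff=diff(distinct_n, 2),
            self_repetition_diff=diff(self_repetition),
            fk_grade_diff=diff(flesch_kincaid),
            perplexity_diff=ppl_diff,
        )
    except MetricError as exc:
        raise MetricError(f"surface profile ({train.name} vs {eval.name}): {exc}") from exc
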