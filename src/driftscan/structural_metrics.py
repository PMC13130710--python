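"""Layout/formatting drift indicators for clinical documentation style.

Summarizes formatting conventions that distinguish clinical notes from
narrative prose: line-break density, key–value ("BP: 120/80") sentences,
bullet or enumerated line openings, ALL-CAPS tokens, and special-character
usage.  All statistics are pooled over the corpus.

Fixed operationalizations:

* a key–value sentence has a ":" token at position 1–4 with at least one
  token following it;
* a bullet line's first non-space character is '-', '*' or '•', or a digit
  immediately followed by '.', ')' or '/';
* ALL-CAPS tokens are word tokens of length ≥ 2 whose cased characters are
  all uppercase (digits permitted), with at least one cased character;
* special characters are anything outside alphanumerics, whitespace and the
  common clinical punctuation set {. , : ; ' -}.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .corpus_model import Corpus
from .surface_metrics import MetricError

_PLAIN_PUNCT = set(".,:;'-")
_BULLET_CHARS = set("-*•")
_ENUM_FOLLOW = set(".)/")

_KEYVALUE_MAX_HEAD = 4


def _is_allcaps(text: str) -> bool:
    cased = [c for c in text if c.isalpha()]
    return len(text) >= 2 and bool(cased) and all(c.isupper() for c in cased)


def _has_special(text: str) -> bool:
    return any(
        not (c.isalnum() or c.isspace() or c in _PLAIN_PUNCT) for c in text
    )


def _is_bullet_line(line: str) -> bool:
    stripped = line.lstrip()
    if not stripped:
        return False
    first = stripped[0]
    if first in _BULLET_CHARS:
        return True
    return first.isdigit() and len(stripped) > 1 and stripped[1] in _ENUM_FOLLOW


@dataclass
class StructuralStats:
    line_break_density: float  # newlines per 100 tokens
    keyvalue_fraction: float  # fraction of sentences
    bullet_fraction: float  # fraction of raw lines
    allcaps_share: float  # fraction of word tokens
    specialchar_fraction: float  # fraction of all tokens

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def structural_stats(corpus: Corpus) -> StructuralStats:
    """Corpus-pooled structural/layout statistics."""
    n_tokens = sum(len(doc.tokens) for doc in corpus)
    if n_tokens == 0:
        raise MetricError(f"corpus {corpus.name} has no tokens")

    n_breaks = sum(doc.text.count("\n") for doc in corpus)

    n_sent = 0
    n_keyvalue = 0
    for doc in corpus:
        for s, e in doc.sentences:
            n_sent += 1
            texts = [t.text for t in doc.tokens[s:e]]
            # head of ≤4 tokens, then ":", then ≥1 payload token
            for i in range(1, min(_KEYVALUE_MAX_HEAD, len(texts) - 2) + 1):
                if texts[i] == ":":
                    n_keyvalue += 1
                    break

    lines = [line for doc in corpus for line in doc.text.split("\n")]
    n_bullet = sum(1 for line in lines if _is_bullet_line(line))

    word_tokens = [t for doc in corpus for t in doc.tokens if t.is_word]
    n_allcaps = sum(1 for t in word_tokens if _is_allcaps(t.text))

    n_special = sum(
        1 for doc in corpus for t in doc.tokens if _has_special(t.text)
    )

    return StructuralStats(
        line_break_density=100.0 * n_breaks / n_tokens,
        keyvalue_fraction=n_keyvalue / n_sent if n_sent else 0.0,
        bullet_fraction=n_bullet / len(lines) if lines else 0.0,
        allcaps_share=n_allcaps / len(word_tokens) if word_tokens else 0.0,
        specialchar_fraction=n_special / n_tokens,
    )


def structural_drift(train: Corpus, eval: Corpus) -> dict[str, float]:
    """Field-wise absolute differences of structural stats; symmetric."""
    a = structural_stats(train).as_dict()
    b = structural_stats(eval).as_dict()
    return {f"{k}_diff": abs(a[k] - b[k]) for k in a}
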