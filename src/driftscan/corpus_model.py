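"""Core corpus data model for PHI-annotated clinical text.

Documents carry their raw text, a deterministic word-level tokenization with
character offsets, sentence spans, and typed entity spans over four harmonized
PHI categories (ADDRESS, CONTACT, DATE, PERSON).  Corpora are read and written
in two plain-text carriers: CoNLL-style BIO TSV and a JSONL span format with
character offsets.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

#: The harmonized PHI label schema.
PHI_SCHEMA: tuple[str, ...] = ("ADDRESS", "CONTACT", "DATE", "PERSON")

# Maximal runs of letters/digits/apostrophes form one token; any other
# non-space character is a single token.  Underscore is deliberately excluded
# from the word class.
_TOKEN_RE = re.compile(r"(?:[^\W_]|')+|\S", re.UNICODE)

_SENT_TERMINALS = frozenset({".", "!", "?"})


class CorpusFormatError(ValueError):
    """Raised for malformed BIO/JSONL input."""


@dataclass(frozen=True)
class Token:
    """A token with half-open character offsets into the document text."""

    text: str
    start: int
    end: int

    @property
    def is_word(self) -> bool:
        """True when the token contains at least one alphanumeric character."""
        return any(c.isalnum() for c in self.text)


@dataclass(frozen=True)
class EntitySpan:
    """A typed entity over a half-open token index range."""

    label: str
    start_token: int
    end_token: int

    def __post_init__(self) -> None:
        if self.label not in PHI_SCHEMA:
            raise CorpusFormatError(f"unknown label {self.label}")
        if not 0 <= self.start_token < self.end_token:
            raise CorpusFormatError(
                f"bad span ({self.start_token},{self.end_token}) for {self.label}"
            )


@dataclass
class Document:
    doc_id: str
    text: str
    tokens: list[Token]
    sentences: list[tuple[int, int]]
    entities: list[EntitySpan] = field(default_factory=list)
    provenance: str | None = None

    def validate(self) -> None:
        n = len(self.tokens)
        for tok in self.tokens:
            if not (0 <= tok.start < tok.end <= len(self.text)):
                raise CorpusFormatError(f"{self.doc_id}: token offsets out of bounds")
            if self.text[tok.start : tok.end] != tok.text:
                raise CorpusFormatError(f"{self.doc_id}: token/text mismatch at {tok.start}")
        pos = 0
        for s, e in self.sentences:
            if s != pos or e <= s:
                raise CorpusFormatError(f"{self.doc_id}: sentences do not partition tokens")
            pos = e
        if self.sentences and pos != n:
            raise CorpusFormatError(f"{self.doc_id}: sentences do not cover all tokens")
        for ent in self.entities:
            if ent.end_token > n:
                raise CorpusFormatError(f"{self.doc_id}: entity beyond token bounds")

    def sentence_text(self, sent: tuple[int, int]) -> str:
        s, e = sent
        return self.text[self.tokens[s].start : self.tokens[e - 1].end]

    def word_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.is_word]


@dataclass
class Corpus:
    name: str
    documents: list[Document]
    schema: tuple[str, ...] = PHI_SCHEMA
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise CorpusFormatError(f"duplicate doc_ids in corpus {self.name}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)


# ---------------------------------------------------------------------------
# Tokenization and sentence segmentation
# ---------------------------------------------------------------------------

def tokenize(text: str) -> list[Token]:
    """Deterministic word-level tokenization.

    Tokens are maximal runs of letters, digits and apostrophes, or single
    non-space characters otherwise.  Offsets slice ``text`` exactly.
    """
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def split_sentences(text: str, tokens: Sequence[Token]) -> list[tuple[int, int]]:
    """Sentence boundaries after terminal punctuation tokens and at newlines.

    Returns half-open (start_token, end_token) pairs partitioning ``tokens``.
    """
    if not tokens:
        return []
    spans: list[tuple[int, int]] = []
    start = 0
    for i, tok in enumerate(tokens):
        boundary = tok.text in _SENT_TERMINALS
        if not boundary and i + 1 < len(tokens):
            gap = text[tok.end : tokens[i + 1].start]
            boundary = "\n" in gap
        if boundary:
            spans.append((start, i + 1))
            start = i + 1
    if start < len(tokens):
        spans.append((start, len(tokens)))
    return spans


def make_document(
    doc_id: str,
    text: str,
    entities: Iterable[tuple[str, int, int]] = (),
    provenance: str | None = None,
) -> Document:
    """Build a Document from raw text and character-offset entities.

    Entity character spans must coincide with token boundaries; misaligned
    spans raise :class:`CorpusFormatError` rather than being snapped.
    """
    tokens = tokenize(text)
    sentences = split_sentences(text, tokens)
    starts = {t.start: i for i, t in enumerate(tokens)}
    ends = {t.end: i + 1 for i, t in enumerate(tokens)}
    spans: list[EntitySpan] = []
    for label, s_char, e_char in entities:
        if not (0 <= s_char < e_char <= len(text)):
            raise CorpusFormatError(
                f"{doc_id}: entity chars ({s_char},{e_char}) out of bounds"
            )
        if s_char not in starts or e_char not in ends:
            raise CorpusFormatError(
                f"{doc_id}: entity span ({s_char},{e_char}) crosses a token boundary"
            )
        spans.append(EntitySpan(label, starts[s_char], ends[e_char]))
    doc = Document(doc_id, text, tokens, sentences, spans, provenance)
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# BIO tag codec
# ---------------------------------------------------------------------------

def decode_bio(tags: Sequence[str]) -> list[EntitySpan]:
    """Decode a BIO tag sequence into entity spans.

    A dangling ``I-X`` (no compatible open span) opens a new entity — the
    relaxed repair convention, applied so that evaluation is deterministic.
    """
    spans: list[EntitySpan] = []
    open_label: str | None = None
    open_start = 0
    for i, tag in enumerate(tags):
        if tag == "O":
            kind, label = "O", None
        elif tag[:2] in ("B-", "I-"):
            kind, label = tag[0], tag[2:]
        else:
            raise CorpusFormatError(f"malformed tag {tag!r}")
        if open_label is not None and (kind != "I" or label != open_label):
            spans.append(EntitySpan(open_label, open_start, i))
            open_label = None
        if kind == "B" or (kind == "I" and open_label is None):
            open_label, open_start = label, i
    if open_label is not None:
        spans.append(EntitySpan(open_label, open_start, len(tags)))
    return spans


def encode_bio(n_tokens: int, entities: Sequence[EntitySpan]) -> list[str]:
    """Inverse of :func:`decode_bio` for non-overlapping spans."""
    tags = ["O"] * n_tokens
    for ent in entities:
        tags[ent.start_token] = f"B-{ent.label}"
        for i in range(ent.start_token + 1, ent.end_token):
            tags[i] = f"I-{ent.label}"
    return tags


# ---------------------------------------------------------------------------
# CoNLL BIO TSV reader/writer
# ---------------------------------------------------------------------------

def read_conll_bio(stream: IO[str], name: str = "corpus", provenance: str = "real") -> Corpus:
    """Read a CoNLL-style ``token<TAB>tag`` stream into a Corpus.

    Blank lines break sentences; ``-DOCSTART-`` lines break documents.
    Document text is reconstructed by joining tokens with single spaces
    within a sentence and newlines between sentences.
    """
    docs: list[Document] = []
    sent_tokens: list[list[str]] = [[]]
    sent_tags: list[list[str]] = [[]]

    def flush_doc() -> None:
        sents = [(toks, tags) for toks, tags in zip(sent_tokens, sent_tags) if toks]
        sent_tokens[:] = [[]]
        sent_tags[:] = [[]]
        if not sents:
            return
        parts: list[str] = []
        tokens: list[Token] = []
        sentences: list[tuple[int, int]] = []
        tags_flat: list[str] = []
        pos = 0
        for toks, tags in sents:
            start_idx = len(tokens)
            for j, t in enumerate(toks):
                if j > 0:
                    pos += 1  # single space
                tokens.append(Token(t, pos, pos + len(t)))
                pos += len(t)
            sentences.append((start_idx, len(tokens)))
            parts.append(" ".join(toks))
            pos += 1  # newline separator
            tags_flat.extend(tags)
        text = "\n".join(parts)
        entities = decode_bio(tags_flat)
        doc = Document(f"doc{len(docs)}", text, tokens, sentences, entities)
        doc.validate()
        docs.append(doc)

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("-DOCSTART-"):
            flush_doc()
            continue
        if not line.strip():
            if sent_tokens[-1]:
                sent_tokens.append([])
                sent_tags.append([])
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CorpusFormatError(f"line {lineno}: expected token<TAB>tag, got {line!r}")
        token, tag = parts
        if tag != "O":
            if tag[:2] not in ("B-", "I-") or tag[2:] not in PHI_SCHEMA:
                label = tag[2:] if tag[:2] in ("B-", "I-") else tag
                raise CorpusFormatError(f"line {lineno}: unknown label {label}")
        sent_tokens[-1].append(token)
        sent_tags[-1].append(tag)
    flush_doc()
    return Corpus(name, docs, provenance=provenance)


def write_conll_bio(corpus: Corpus, stream: IO[str]) -> None:
    for doc in corpus:
        stream.write("-DOCSTART-\n")
        tags = encode_bio(len(doc.tokens), doc.entities)
        for s, e in doc.sentences or [(0, len(doc.tokens))]:
            for i in range(s, e):
                stream.write(f"{doc.tokens[i].text}\t{tags[i]}\n")
            stream.write("\n")


# ---------------------------------------------------------------------------
# JSONL span reader/writer
# ---------------------------------------------------------------------------

def read_jsonl_spans(stream: IO[str], name: str = "corpus", provenance: str = "real") -> Corpus:
    """Read one JSON object per line with character-offset entity spans."""
    docs: list[Document] = []
    for lineno, raw in enumerate(stream, start=1):
        if not raw.strip():
            continue
        try:
            obj = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
        ents = [
            (e["label"], e["start_char"], e["end_char"])
            for e in obj.get("entities", [])
        ]
        docs.append(
            make_document(
                obj.get("doc_id", f"doc{lineno}"),
                obj["text"],
                ents,
                provenance=obj.get("provenance"),
            )
        )
    return Corpus(name, docs, provenance=provenance)


def write_jsonl_spans(corpus: Corpus, stream: IO[str]) -> None:
    for doc in corpus:
        ents = [
            {
                "label": e.label,
                "start_char": doc.tokens[e.start_token].start,
                "end_char": doc.tokens[e.end_token - 1].end,
            }
            for e in doc.entities
        ]
        obj: dict = {"doc_id": doc.doc_id, "text": doc.text, "entities": ents}
        if doc.provenance is not None:
            obj["provenance"] = doc.provenance
        stream.write(json.dumps(obj, ensure_ascii=False) + "\n")
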