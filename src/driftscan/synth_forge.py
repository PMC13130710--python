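"""Synthetic corpus generation for drift experiments.

Two generation modes:

1. **Fixture mode** — a seeded template generator producing short
   clinical-note-like documents (2–3 sentences, ≈57–61 tokens) with
   continuous drift knobs: vocabulary substitution, template reuse, clinical
   formatting conventions (key–value lines, bullets, ALL-CAPS headers),
   entity density and negative-document fraction.  Each knob draws from its
   own random substream, so varying one knob leaves every other concern's
   draws untouched; this makes knob→metric monotonicity a well-posed
   property rather than a statistical accident.

2. **Generation-loop mode** — a multi-round generator-ensemble plus
   LLM-as-judge quality-filtering loop behind pluggable backends.  Round 0
   is strictly zero-shot; later rounds draw k high-scoring samples from the
   accepted pool as few-shot context.  A sample enters the pool only if its
   markup passes a structural sanity check, its mean judge score reaches the
   threshold, and its entity surface string is under the occurrence cap.
   Deterministic mock backends make the loop fully testable offline; real
   LLM backends can be plugged in behind the same contracts.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus_model import PHI_SCHEMA, Corpus, Document, make_document


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Vocabulary, templates and gazetteers
# ---------------------------------------------------------------------------

BASE_VOCAB = (
    "patient clinic visit exam stable mild severe chronic acute follow review "
    "plan dose daily morning evening pain fever cough rash swelling left right "
    "lower upper normal elevated reduced blood pressure pulse oxygen glucose "
    "renal cardiac hepatic lungs clear heart rate rhythm regular labs ordered "
    "results pending continue start stop medication therapy discharge admit "
    "ward bed rest fluids diet advised noted denies reports history improved"
).split()

# short scaffolds that open a fresh sentence; remaining length is filler
_TEMPLATES = (
    ["patient", "was", "seen", "in", "clinic", "for"],
    ["on", "examination", "the", "patient", "has"],
    ["we", "will", "continue", "current", "plan", "with"],
    ["labs", "were", "reviewed", "and", "show"],
    ["the", "patient", "reports", "ongoing"],
    ["assessment", "remains", "unchanged", "with"],
)

# fixed stock sentences; reuse of these drives repeated 4-grams
_STOCK_SENTENCES = (
    ["the", "patient", "denies", "fever", "chills", "nausea", "vomiting", "or", "chest", "pain"],
    ["vital", "signs", "were", "stable", "and", "within", "normal", "limits", "throughout", "the", "visit"],
    ["will", "follow", "up", "in", "two", "weeks", "with", "repeat", "labs", "as", "needed"],
    ["no", "acute", "distress", "was", "noted", "on", "examination", "at", "this", "time"],
    ["medication", "list", "was", "reviewed", "and", "reconciled", "with", "the", "patient", "today"],
    ["the", "plan", "was", "discussed", "with", "the", "patient", "who", "verbalized", "understanding"],
)

_KEYVALUE_HEADS = ("VITALS", "HPI", "PLAN", "MEDS", "EXAM", "LABS")

GAZETTEERS: dict[str, tuple[str, ...]] = {
    "PERSON": (
        "John Smith", "Maria Garcia", "Wei Chen", "Fatima Khan", "Liam O'Brien",
        "Ana Costa", "David Cohen", "Elena Petrova", "Samuel Okafor", "Ingrid Larsen",
        "Omar Haddad", "Grace Kim", "Peter Novak", "Aisha Diallo", "Carlos Mendez",
        "Hannah Weber",
    ),
    "DATE": (
        "12/03/2021", "04/18/2019", "07/22/2020", "11/01/2022", "09/14/2018",
        "01/30/2023", "03/05/2017", "06/27/2024", "08/09/2016", "10/12/2015",
        "02/08/2022", "05/19/2021", "march 3 2020", "july 14 2019",
        "october 2 2023", "january 7 2018",
    ),
    "ADDRESS": (
        "14 Oak Street", "92 Hillcrest Avenue", "7 Birch Lane", "310 Maple Road",
        "55 Cedar Court", "128 Elm Drive", "4 Willow Way", "201 Pine Terrace",
        "68 Aspen Boulevard", "9 Juniper Close", "77 Linden Square",
        "350 Chestnut Row", "23 Poplar Walk", "81 Sycamore Place",
        "640 Magnolia Street", "12 Laurel Crescent",
    ),
    "CONTACT": (
        "555-0142", "555-0178", "555-0113", "555-0067", "555-0199",
        "555-0230", "555-0324", "555-0411", "555-0556", "555-0672",
        "555-0718", "555-0840", "555-0903", "555-0958", "555-0288", "555-0361",
    ),
}

_OOV_PREFIX = "zq"  # substitution maps word → zq<word>, a disjoint vocabulary


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftKnobs:
    """Continuous controls over the fixture corpus distribution.

    Defaults emulate the generated-corpus conditions: 2–3 sentence notes of
    roughly 57–61 tokens, a mildly clinical layout, under one entity per
    document per type, and a ≈41% negative-document share (0.7
    negatives-per-positive odds).
    """

    vocab_substitution_rate: float = 0.0
    template_reuse_rate: float = 0.0
    clinical_format_level: float = 0.3
    entity_density: float = 0.6
    negative_fraction: float = 0.41
    sentence_length: tuple[float, float] = (22.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "vocab_substitution_rate",
            "template_reuse_rate",
            "clinical_format_level",
            "negative_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name}={v} outside [0,1]")
        if self.entity_density < 0:
            raise SynthError("entity_density must be ≥ 0")


# one independent substream per concern: varying a knob never perturbs
# draws belonging to another concern
_STREAMS = {"layout": 0, "template": 1, "reuse": 2, "format": 3, "subst": 4, "entity": 5, "negative": 6}


def _rng(seed: int, doc_idx: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, doc_idx, _STREAMS[stream]])


@dataclass
class _SentDraft:
    words: list[str]
    protected: list[bool]  # entity tokens excluded from substitution
    entity_runs: list[tuple[str, int, int]]  # (label, start_word, end_word)
    fmt: str = "plain"  # plain | keyvalue | bullet
    head: str = ""


def _build_doc(knobs: DriftKnobs, doc_idx: int) -> Document:
    rng_layout = _rng(knobs.seed, doc_idx, "layout")
    rng_tmpl = _rng(knobs.seed, doc_idx, "template")
    rng_reuse = _rng(knobs.seed, doc_idx, "reuse")
    rng_fmt = _rng(knobs.seed, doc_idx, "format")
    rng_subst = _rng(knobs.seed, doc_idx, "subst")
    rng_ent = _rng(knobs.seed, doc_idx, "entity")
    rng_neg = _rng(knobs.seed, doc_idx, "negative")

    mean_len, disp = knobs.sentence_length
    n_sent = int(rng_layout.integers(2, 4))
    lengths = [max(3, int(round(rng_layout.normal(mean_len, disp)))) for _ in range(n_sent)]

    drafts: list[_SentDraft] = []
    for length in lengths:
        # draws are unconditional so streams stay aligned across knob values
        u_reuse = rng_reuse.random()
        stock_idx = int(rng_reuse.integers(0, len(_STOCK_SENTENCES)))
        tmpl_idx = int(rng_tmpl.integers(0, len(_TEMPLATES)))
        scaffold = list(_TEMPLATES[tmpl_idx])
        n_fill = max(0, length - len(scaffold))
        fillers = [BASE_VOCAB[int(i)] for i in rng_tmpl.integers(0, len(BASE_VOCAB), size=n_fill)]
        if u_reuse < knobs.template_reuse_rate:
            words = list(_STOCK_SENTENCES[stock_idx])
        else:
            words = scaffold + fillers
        drafts.append(_SentDraft(words, [False] * len(words), []))

    # entity placement (computed always; applied only to positive documents)
    is_negative = rng_neg.random() < knobs.negative_fraction
    for label in PHI_SCHEMA:
        count = int(rng_ent.poisson(knobs.entity_density))
        for _ in range(count):
            sent_idx = int(rng_ent.integers(0, n_sent))
            gaz = GAZETTEERS[label]
            surface = gaz[int(rng_ent.integers(0, len(gaz)))]
            if is_negative:
                continue
            draft = drafts[sent_idx]
            parts = surface.split(" ")
            start = len(draft.words)
            draft.words.extend(parts)
            draft.protected.extend([True] * len(parts))
            draft.entity_runs.append((label, start, start + len(parts)))

    # vocabulary substitution on unprotected word tokens
    for draft in drafts:
        for i, word in enumerate(draft.words):
            u = rng_subst.random()
            if not draft.protected[i] and u < knobs.vocab_substitution_rate:
                draft.words[i] = _OOV_PREFIX + word

    # clinical formatting
    for draft in drafts:
        u_fmt = rng_fmt.random()
        style = rng_fmt.random()
        head_idx = int(rng_fmt.integers(0, len(_KEYVALUE_HEADS)))
        if u_fmt < knobs.clinical_format_level:
            draft.fmt = "keyvalue" if style < 0.5 else "bullet"
            draft.head = _KEYVALUE_HEADS[head_idx]

    # render text and collect character-offset entities
    pieces: list[str] = []
    entities: list[tuple[str, int, int]] = []
    pos = 0
    for i, draft in enumerate(drafts):
        if i > 0:
            prev_fmt = drafts[i - 1].fmt != "plain"
            sep = "\n" if (prev_fmt or draft.fmt != "plain") else " "
            pieces.append(sep)
            pos += len(sep)
        prefix_words: list[str] = []
        if draft.fmt == "keyvalue":
            prefix_words = [draft.head, ":"]
        elif draft.fmt == "bullet":
            prefix_words = ["-"]
        offset = len(prefix_words)
        word_pos: list[int] = []
        sent_words = prefix_words + draft.words
        if draft.fmt == "plain":
            sent_words = sent_words + ["."]
        rendered: list[str] = []
        for j, w in enumerate(sent_words):
            if j > 0:
                pos += 1  # single space
            word_pos.append(pos)
            rendered.append(w)
            pos += len(w)
        pieces.append(" ".join(rendered))
        for label, ws, we in draft.entity_runs:
            s_char = word_pos[ws + offset]
            e_char = word_pos[we - 1 + offset] + len(sent_words[we - 1 + offset])
            entities.append((label, s_char, e_char))
    text = "".join(pieces)
    return make_document(f"fix{doc_idx}", text, entities, provenance="synthetic")


def generate_fixture_corpus(
    knobs: DriftKnobs, n_docs: int, name: str = "fixture"
) -> Corpus:
    """Deterministic fixture corpus of clinical-note-like documents."""
    if n_docs < 1:
        raise SynthError("n_docs must be ≥ 1")
    docs = [_build_doc(knobs, i) for i in range(n_docs)]
    return Corpus(name, docs, provenance="synthetic")


# ---------------------------------------------------------------------------
# Generation-loop mode: samples, sanity check, backends, loop
# ---------------------------------------------------------------------------

@dataclass
class GenSample:
    """One generated note with inline entity markup ``[X]…[/X]``."""

    text: str
    entity_type: str
    polarity: str  # positive | negative
    judge_scores: list[float] = field(default_factory=list)
    round_index: int = -1
    generator_id: str = ""

    @property
    def mean_judge_score(self) -> float:
        return float(np.mean(self.judge_scores)) if self.judge_scores else float("nan")


@dataclass(frozen=True)
class GenConfig:
    """Multi-round generation loop configuration."""

    entity_type: str
    seed: int
    rounds: int = 30
    samples_per_round_per_generator: int = 250
    few_shot_k: int = 10
    judge_threshold: float = 3.0
    entity_string_cap: int = 10
    negative_ratio: float = 0.7
    negative_ratio_mode: str = "odds"  # odds: neg:pos = ratio; fraction: P(neg) = ratio

    @property
    def negative_probability(self) -> float:
        if self.negative_ratio_mode == "odds":
            return self.negative_ratio / (1.0 + self.negative_ratio)
        if self.negative_ratio_mode == "fraction":
            return self.negative_ratio
        raise SynthError(f"unknown negative_ratio_mode {self.negative_ratio_mode!r}")


_MARKUP_RE = re.compile(r"\[(/?)(" + "|".join(PHI_SCHEMA) + r")\]")


def parse_markup(text: str) -> tuple[str, list[tuple[str, int, int]]] | str:
    """Strip ``[X]…[/X]`` markup; return (plain text, char-span entities)
    or a failure reason code for unbalanced/nested markup."""
    plain: list[str] = []
    out_pos = 0
    entities: list[tuple[str, int, int]] = []
    open_label: str | None = None
    open_start = 0
    last = 0
    for m in _MARKUP_RE.finditer(text):
        plain.append(text[last : m.start()])
        out_pos += m.start() - last
        last = m.end()
        closing, label = m.group(1) == "/", m.group(2)
        if closing:
            if open_label != label:
                return "unbalanced_markup"
            entities.append((label, open_start, out_pos))
            open_label = None
        else:
            if open_label is not None:
                return "nested_markup"
            open_label, open_start = label, out_pos
    if open_label is not None:
        return "unbalanced_markup"
    plain.append(text[last:])
    return "".join(plain), entities


def sanity_check(sample: GenSample) -> str | None:
    """Structural correctness of the synthetic annotation.

    Returns None on pass, else a reason code: unbalanced_markup,
    nested_markup, no_target_span, unexpected_target_span,
    bad_sentence_count.
    """
    parsed = parse_markup(sample.text)
    if isinstance(parsed, str):
        return parsed
    plain, entities = parsed
    n_target = sum(1 for label, _, _ in entities if label == sample.entity_type)
    if sample.polarity == "positive" and n_target == 0:
        return "no_target_span"
    if sample.polarity == "negative" and n_target > 0:
        return "unexpected_target_span"
    from .corpus_model import split_sentences, tokenize

    tokens = tokenize(plain)
    n_sent = len(split_sentences(plain, tokens))
    if not 1 <= n_sent <= 5:
        return "bad_sentence_count"
    return None


def target_entity_strings(sample: GenSample) -> list[str]:
    """Surface strings of target-type spans (for the occurrence cap)."""
    parsed = parse_markup(sample.text)
    if isinstance(parsed, str):
        return []
    plain, entities = parsed
    return [plain[s:e] for label, s, e in entities if label == sample.entity_type]


def sample_to_document(sample: GenSample, doc_id: str) -> Document:
    """Convert markup to a token-span annotated Document."""
    parsed = parse_markup(sample.text)
    if isinstance(parsed, str):
        raise SynthError(f"cannot convert sample with {parsed}")
    plain, entities = parsed
    return make_document(doc_id, plain, entities, provenance="synthetic")


def samples_to_corpus(pool: Sequence[GenSample], name: str = "generated") -> Corpus:
    docs = [sample_to_document(s, f"gen{i}") for i, s in enumerate(pool)]
    return Corpus(name, docs, provenance="synthetic")


class MockGeneratorBackend:
    """Deterministic template-sampling stand-in for an LLM generator.

    With a nonempty few-shot context it reuses a context entity string with
    probability 0.3, so the loop's pool dynamics are observable.  A nonzero
    ``fail_rate`` emits structurally broken markup to exercise the sanity
    check; ``fixed_entity`` pins every positive to one surface string to
    exercise the occurrence cap.
    """

    _POS_TEMPLATES = (
        "Patient {ent} was seen in clinic today. Plan reviewed and continued.",
        "Follow up scheduled with {ent} for repeat labs. No acute distress noted.",
        "Note for {ent}. Vitals stable and medication list reconciled.",
        "Seen {ent} during morning rounds. Reports mild improvement overall.",
    )
    _NEG_TEMPLATES = (
        "Routine visit completed without complications. Plan unchanged for now.",
        "Labs reviewed and within normal limits. Continue current therapy.",
        "No acute findings on examination today. Follow up as needed.",
        "Symptoms improved since last visit. Medication dose unchanged.",
    )

    def __init__(
        self,
        generator_id: str,
        seed: int,
        fail_rate: float = 0.0,
        fixed_entity: str | None = None,
    ) -> None:
        self.generator_id = generator_id
        self.seed = seed
        self.fail_rate = fail_rate
        self.fixed_entity = fixed_entity
        self._calls = 0
        self.few_shot_log: list[int] = []

    def generate(
        self,
        entity_type: str,
        polarity: str,
        few_shot: Sequence[GenSample],
        n: int,
    ) -> list[GenSample]:
        self.few_shot_log.append(len(few_shot))
        out: list[GenSample] = []
        for _ in range(n):
            rng = np.random.default_rng([self.seed & 0x7FFFFFFF, self._calls])
            self._calls += 1
            if polarity == "positive":
                tmpl = self._POS_TEMPLATES[int(rng.integers(0, len(self._POS_TEMPLATES)))]
                if self.fixed_entity is not None:
                    surface = self.fixed_entity
                else:
                    context_strings = [
                        s for fs in few_shot for s in target_entity_strings(fs)
                    ]
                    if context_strings and rng.random() < 0.3:
                        surface = context_strings[int(rng.integers(0, len(context_strings)))]
                    else:
                        gaz = GAZETTEERS[entity_type]
                        surface = gaz[int(rng.integers(0, len(gaz)))]
                ent = f"[{entity_type}]{surface}[/{entity_type}]"
                text = tmpl.format(ent=ent)
                if rng.random() < self.fail_rate:
                    text = text.replace(f"[/{entity_type}]", "", 1)  # break markup
            else:
                tmpl = self._NEG_TEMPLATES[int(rng.integers(0, len(self._NEG_TEMPLATES)))]
                text = tmpl
            out.append(
                GenSample(text, entity_type, polarity, generator_id=self.generator_id)
            )
        return out


class MockJudgeBackend:
    """Deterministic judge: a seeded hash of the sample text maps to 1–5."""

    def __init__(self, seed: int) -> None:
        self.seed = seed

    def judge(self, sample: GenSample) -> float:
        import zlib

        h = zlib.crc32(f"{self.seed}|{sample.text}".encode("utf-8"))
        return float(1 + h % 5)


@dataclass(frozen=True)
class RoundAudit:
    round_index: int
    generated: int
    sanity_failed: int
    judge_rejected: int
    cap_rejected: int
    accepted: int
    pool_size: int
    few_shot_used: int


def run_generation_loop(
    generators: Sequence,
    judge,
    config: GenConfig,
) -> tuple[list[GenSample], list[RoundAudit]]:
    """Multi-round generation with judge filtering and entity-string capping.

    Round 0 is strictly zero-shot; each later round draws up to k accepted
    samples uniformly without replacement as few-shot context (fewer when the
    pool is small — logged, never fatal).
    """
    if not generators:
        raise SynthError("need ≥1 generator backend")
    if config.entity_type not in PHI_SCHEMA:
        raise SynthError(f"unknown entity type {config.entity_type}")
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    p_neg = config.negative_probability
    pool: list[GenSample] = []
    string_counts: Counter = Counter()
    audit: list[RoundAudit] = []
    for rnd in range(config.rounds):
        if rnd == 0 or not pool:
            few_shot: list[GenSample] = []
        else:
            k = min(config.few_shot_k, len(pool))
            idx = rng.choice(len(pool), size=k, replace=False)
            few_shot = [pool[i] for i in sorted(idx)]
        generated = sanity_failed = judge_rejected = cap_rejected = accepted = 0
        for gen in generators:
            for _ in range(config.samples_per_round_per_generator):
                polarity = "negative" if rng.random() < p_neg else "positive"
                sample = gen.generate(config.entity_type, polarity, few_shot, 1)[0]
                sample.round_index = rnd
                generated += 1
                reason = sanity_check(sample)
                if reason is not None:
                    sanity_failed += 1
                    continue
                sample.judge_scores = sample.judge_scores + [float(judge.judge(sample))]
                if sample.mean_judge_score < config.judge_threshold:
                    judge_rejected += 1
                    continue
                strings = target_entity_strings(sample)
                if any(string_counts[s] >= config.entity_string_cap for s in strings):
                    cap_rejected += 1
                    continue
                for s in strings:
                    string_counts[s] += 1
                pool.append(sample)
                accepted += 1
        audit.append(
            RoundAudit(
                rnd, generated, sanity_failed, judge_rejected, cap_rejected,
                accepted, len(pool), len(few_shot),
            )
        )
    return pool, audit


def filter_by_judge_score(
    pool: Sequence[GenSample], min_score: float, exact: bool = False
) -> list[GenSample]:
    """Keep samples with mean judge score ≥ min_score (== when exact)."""
    if exact:
        return [s for s in pool if s.mean_judge_score == min_score]
    return [s for s in pool if s.mean_judge_score >= min_score]


def mix_corpora(
    real: Corpus,
    synthetic: Corpus,
    synthetic_proportion: float,
    n_docs: int,
    seed: int,
) -> Corpus:
    """Seeded real/synthetic mixture with per-document provenance.

    round(p·n) synthetic documents plus the remainder real, sampled uniformly
    without replacement where the source allows, with replacement otherwise.
    """
    if n_docs < 1:
        raise SynthError("n_docs must be ≥ 1")
    if not 0.0 <= synthetic_proportion <= 1.0:
        raise SynthError("synthetic_proportion outside [0,1]")
    n_syn = int(np.floor(synthetic_proportion * n_docs + 0.5))
    n_real = n_docs - n_syn
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    docs: list[Document] = []

    def draw(source: Corpus, count: int, tag: str) -> None:
        if count == 0:
            return
        with_replacement = count > len(source)
        idx = rng.choice(len(source), size=count, replace=with_replacement)
        for j, i in enumerate(idx):
            src = source.documents[int(i)]
            docs.append(
                replace(src, doc_id=f"{tag}{j}-{src.doc_id}", provenance=tag)
            )

    draw(synthetic, n_syn, "synthetic")
    draw(real, n_real, "real")
    return Corpus(f"mix{synthetic_proportion:g}", docs, provenance="mixed")
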