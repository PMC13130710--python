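"""Fixture generator and the multi-round generation loop."""

from collections import Counter

import numpy as np
import pytest

import driftscan as ds
from driftscan.synth_forge import (
    GenSample,
    SynthError,
    parse_markup,
    sample_to_document,
    target_entity_strings,
)


class TestFixtureGenerator:
    def test_deterministic(self):
        knobs = ds.DriftKnobs(seed=21, vocab_substitution_rate=0.2)
        a = ds.generate_fixture_corpus(knobs, 15)
        b = ds.generate_fixture_corpus(knobs, 15)
        for da, db in zip(a, b):
            assert da.text == db.text and da.entities == db.entities

    def test_emulates_short_clinical_notes(self):
        c = ds.generate_fixture_corpus(ds.DriftKnobs(seed=1), 200)
        tokens = np.mean([len(d.tokens) for d in c])
        sents = [len(d.sentences) for d in c]
        assert 50 <= tokens <= 70
        assert min(sents) >= 2

    def test_zero_entity_density(self):
        c = ds.generate_fixture_corpus(ds.DriftKnobs(entity_density=0.0, seed=2), 50)
        assert sum(len(d.entities) for d in c) == 0

    def test_negative_fraction_one_means_no_entities(self):
        c = ds.generate_fixture_corpus(ds.DriftKnobs(negative_fraction=1.0, seed=2), 50)
        assert sum(len(d.entities) for d in c) == 0

    def test_entity_spans_are_valid_gold(self):
        c = ds.generate_fixture_corpus(ds.DriftKnobs(entity_density=1.0, seed=3), 40)
        labels = {e.label for d in c for e in d.entities}
        assert labels == set(ds.PHI_SCHEMA)
        for d in c:
            d.validate()

    def test_knob_bounds_checked(self):
        with pytest.raises(SynthError):
            ds.DriftKnobs(vocab_substitution_rate=1.5)
        with pytest.raises(SynthError):
            ds.generate_fixture_corpus(ds.DriftKnobs(), 0)

    def test_substitution_knob_independent_of_entity_draws(self):
        """Common-random-number substreams: changing the substitution knob
        leaves entity placement untouched."""
        a = ds.generate_fixture_corpus(ds.DriftKnobs(seed=4), 30)
        b = ds.generate_fixture_corpus(
            ds.DriftKnobs(vocab_substitution_rate=0.5, seed=4), 30
        )
        for da, db in zip(a, b):
            assert [e.label for e in da.entities] == [e.label for e in db.entities]


class TestMarkupAndSanity:
    def test_parse_strips_and_locates(self):
        plain, ents = parse_markup("Seen by [PERSON]John Doe[/PERSON] today.")
        assert plain == "Seen by John Doe today."
        assert ents == [("PERSON", 8, 16)]

    @pytest.mark.parametrize(
        "text,polarity,reason",
        [
            ("Seen by [PERSON]John Doe[/PERSON].", "positive", None),
            ("No names mentioned here.", "negative", None),
            ("No names mentioned here.", "positive", "no_target_span"),
            ("Seen by [PERSON]John Doe[/PERSON].", "negative", "unexpected_target_span"),
            ("[PERSON]John", "positive", "unbalanced_markup"),
            ("[PERSON]x[/DATE]", "positive", "unbalanced_markup"),
            ("[PERSON]a [DATE]b[/DATE] c[/PERSON]", "positive", "nested_markup"),
            ("One. Two. Three. Four. Five. Six.", "negative", "bad_sentence_count"),
        ],
    )
    def test_sanity_reason_codes(self, text, polarity, reason):
        sample = GenSample(text, "PERSON", polarity)
        assert ds.sanity_check(sample) == reason

    def test_other_type_span_allowed_in_negative(self):
        s = GenSample("Visit on [DATE]12/03/2021[/DATE].", "PERSON", "negative")
        assert ds.sanity_check(s) is None

    def test_sample_to_document_spans(self):
        s = GenSample("Seen by [PERSON]John Doe[/PERSON] today.", "PERSON", "positive")
        doc = sample_to_document(s, "g0")
        (ent,) = doc.entities
        covered = doc.text[doc.tokens[ent.start_token].start : doc.tokens[ent.end_token - 1].end]
        assert covered == "John Doe"


class RecordingGenerator(ds.MockGeneratorBackend):
    """Mock generator that records the few-shot context per round."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.contexts = []

    def generate(self, entity_type, polarity, few_shot, n):
        self.contexts.append(list(few_shot))
        return super().generate(entity_type, polarity, few_shot, n)


class AlternatingJudge:
    """Scores samples 2.0 / 4.0 alternately (call order)."""

    def __init__(self):
        self.calls = 0

    def judge(self, sample):
        self.calls += 1
        return 2.0 if self.calls % 2 else 4.0


class Judge5:
    def judge(self, sample):
        return 5.0


def small_config(**over):
    base = dict(
        entity_type="PERSON", seed=7, rounds=3, samples_per_round_per_generator=20
    )
    base.update(over)
    return ds.GenConfig(**base)


class TestGenerationLoop:
    def test_no_rejection_path_accepts_everything(self):
        cfg = small_config(entity_string_cap=10**9)
        gens = [ds.MockGeneratorBackend(f"g{i}", seed=i) for i in range(2)]
        pool, audit = ds.run_generation_loop(gens, Judge5(), cfg)
        assert len(pool) == cfg.rounds * len(gens) * cfg.samples_per_round_per_generator
        assert all(a.sanity_failed == a.judge_rejected == a.cap_rejected == 0 for a in audit)

    def test_alternating_judge_accepts_exactly_half(self):
        cfg = small_config(negative_ratio=0.0, entity_string_cap=10**9)
        gens = [ds.MockGeneratorBackend("g0", seed=0)]
        pool, audit = ds.run_generation_loop(gens, AlternatingJudge(), cfg)
        total = cfg.rounds * cfg.samples_per_round_per_generator
        assert len(pool) == total // 2
        assert all(s.mean_judge_score == 4.0 for s in pool)

    def test_fixed_entity_string_capped_at_ten(self):
        cfg = small_config(rounds=3, samples_per_round_per_generator=30, negative_ratio=0.0)
        gen = ds.MockGeneratorBackend("g", seed=5, fixed_entity="John Smith")
        pool, audit = ds.run_generation_loop([gen], Judge5(), cfg)
        assert len(pool) == 10
        assert sum(a.cap_rejected for a in audit) == 90 - 10
        strings = Counter(s for smp in pool for s in target_entity_strings(smp))
        assert strings == {"John Smith": 10}

    def test_round_zero_is_strictly_zero_shot(self):
        gen = RecordingGenerator("g", seed=1)
        ds.run_generation_loop([gen], Judge5(), small_config())
        per_round = gen.few_shot_log
        round_size = small_config().samples_per_round_per_generator
        assert all(k == 0 for k in per_round[:round_size])
        assert any(k > 0 for k in per_round[round_size:])

    def test_few_shot_drawn_from_accepted_pool(self):
        gen = RecordingGenerator("g", seed=1)
        cfg = small_config()
        pool, _ = ds.run_generation_loop([gen], Judge5(), cfg)
        later = [ctx for ctx in gen.contexts if ctx]
        accepted_texts = {s.text for s in pool}
        for ctx in later:
            assert len(ctx) <= cfg.few_shot_k
            assert all(s.text in accepted_texts for s in ctx)

    def test_bit_reproducible(self):
        def run():
            gens = [ds.MockGeneratorBackend(f"g{i}", seed=10 + i, fail_rate=0.1) for i in range(2)]
            return ds.run_generation_loop(gens, ds.MockJudgeBackend(seed=3), small_config())

        pool1, audit1 = run()
        pool2, audit2 = run()
        assert [(s.text, s.judge_scores, s.round_index) for s in pool1] == [
            (s.text, s.judge_scores, s.round_index) for s in pool2
        ]
        assert audit1 == audit2

    def test_pool_never_contains_bad_samples(self):
        gens = [ds.MockGeneratorBackend(f"g{i}", seed=i, fail_rate=0.3) for i in range(2)]
        cfg = small_config(entity_string_cap=3)
        pool, audit = ds.run_generation_loop(gens, ds.MockJudgeBackend(seed=9), cfg)
        strings = Counter(s for smp in pool for s in target_entity_strings(smp))
        assert all(ds.sanity_check(s) is None for s in pool)
        assert all(s.mean_judge_score >= cfg.judge_threshold for s in pool)
        assert all(v <= cfg.entity_string_cap for v in strings.values())
        assert sum(a.accepted for a in audit) == len(pool)

    def test_negative_ratio_modes(self):
        odds = ds.GenConfig(entity_type="PERSON", seed=0, negative_ratio=0.7)
        frac = ds.GenConfig(
            entity_type="PERSON", seed=0, negative_ratio=0.7, negative_ratio_mode="fraction"
        )
        assert odds.negative_probability == pytest.approx(0.7 / 1.7)
        assert frac.negative_probability == pytest.approx(0.7)


class TestJudgeFilter:
    def pool(self):
        return [
            GenSample(f"t{i}", "PERSON", "positive", judge_scores=[float(s)])
            for i, s in enumerate([2, 3, 4, 5])
        ]

    def test_min_one_is_identity(self):
        assert ds.filter_by_judge_score(self.pool(), 1.0) == self.pool()

    def test_threshold_four(self):
        assert len(ds.filter_by_judge_score(self.pool(), 4.0)) == 2

    def test_exact_flag(self):
        pool = [
            GenSample("a", "PERSON", "positive", judge_scores=[4.9]),
            GenSample("b", "PERSON", "positive", judge_scores=[5.0]),
        ]
        assert [s.text for s in ds.filter_by_judge_score(pool, 5.0, exact=True)] == ["b"]


class TestMixCorpora:
    @pytest.fixture
    def sources(self):
        real = ds.generate_fixture_corpus(ds.DriftKnobs(seed=1), 30, name="real")
        syn = ds.generate_fixture_corpus(ds.DriftKnobs(seed=2), 30, name="syn")
        return real, syn

    @pytest.mark.parametrize("p", [i / 10 for i in range(11)])
    def test_exact_composition(self, sources, p):
        real, syn = sources
        mixed = ds.mix_corpora(real, syn, p, 20, seed=0)
        counts = Counter(d.provenance for d in mixed)
        expected_syn = int(np.floor(p * 20 + 0.5))
        assert counts.get("synthetic", 0) == expected_syn
        assert counts.get("real", 0) == 20 - expected_syn
        assert len(mixed) == 20

    def test_sampling_with_replacement_when_source_small(self, sources):
        real, syn = sources
        mixed = ds.mix_corpora(real, syn, 1.0, 50, seed=1)
        assert len(mixed) == 50

    def test_bad_args(self, sources):
        real, syn = sources
        with pytest.raises(SynthError):
            ds.mix_corpora(real, syn, 0.5, 0, seed=0)
        with pytest.raises(SynthError):
            ds.mix_corpora(real, syn, 1.5, 5, seed=0)
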