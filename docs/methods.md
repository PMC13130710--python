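# Methods

This note documents the measurement conventions, the synthetic-data
generators, and the numerical choices behind driftscan, in enough detail to
reproduce any number the toolkit prints.

## Corpus model and tokenization

Drift metrics are only comparable across corpora under a single fixed
tokenization. Tokens are maximal runs of letters, digits and apostrophes;
any other non-space character is a single token. Offsets are half-open
character spans that slice the document text exactly. Sentence boundaries
fall after `.`, `!`, `?` tokens and at newline characters — clinical notes
are newline-structured, and the structural metrics need line awareness.
`is_word` marks tokens containing at least one alphanumeric character;
lexical metrics use lowercased word tokens only, while punctuation/digit
rates and structural statistics see all tokens. Original case is preserved
in documents; lowercasing happens inside the lexical metrics.

BIO decoding repairs a dangling `I-X` by opening a new entity (the relaxed
convention), so evaluation is deterministic on malformed predictions.
Character-offset entity spans must coincide with token boundaries;
misaligned spans are errors, never silently snapped — snapping would
corrupt strict boundary matching downstream.

## Surface metrics

- **JSD** is computed in base 2 on the union support, so it is bounded in
  [0, 1] bits; 0·log 0 := 0. Bigrams never cross sentence boundaries and no
  padding symbols are used, keeping bigram support interpretable on two-to-
  three-sentence notes.
- **Sentence length** uses the population (not sample) standard deviation,
  fixed for exact reproducibility, over all tokens including punctuation.
- **MTLD** (threshold 0.72) averages a forward and a backward pass; each
  pass completes a factor whenever running TTR drops below threshold and
  adds a partial factor (1−TTR)/(1−0.72) for the remainder. When a pass
  completes zero factors the value is an explicit NaN sentinel, never an
  arbitrary large number; correlation later drops such pairs by pairwise
  deletion. MTLD is computed per document and averaged over documents where
  it is defined (undefined only if no document is defined) — documents here
  are short, and a pooled stream would conflate document boundaries.
  Entropy, Yule's K and Distinct-n are pooled corpus-level; this asymmetry
  is deliberate and documented.
- **Distinct-n / self-repetition** pool n-grams across documents without
  letting n-grams span documents: template overuse is a cross-document
  phenomenon. Self-repetition is the repeated-occurrence fraction
  1 − distinct-4/total-4.
- **Flesch–Kincaid** uses a fixed syllable heuristic: maximal vowel-letter
  runs (aeiouy), minus a trailing silent-e run unless the word ends in
  "le", floored at one. No external syllabifier is required; tests check
  the grade against the formula with an independent recount.
- **Perplexity** is token-weighted, exp(Σ NLL / Σ tokens), behind an
  `LMScorer` contract. The packaged backend is an add-one-smoothed unigram
  model fitted on the training corpus; a causal transformer can be plugged
  in behind the same two-method contract, and nothing in the toolkit
  depends on one. With no scorer the profile records `null` with the reason.
- Every pairwise `*_diff` is an **unsigned** absolute difference: drift is
  reported as a magnitude, and sign conventions would be arbitrary for most
  of these statistics.

## Structural metrics

The informal notions "key–value sentence" and "bullet line" are fixed as:
a sentence whose token at position 1–4 is `:` with at least one payload
token after it; and a raw line whose first non-space character is `-`, `*`,
`•`, or a digit immediately followed by `.`, `)` or `/`. ALL-CAPS tokens
are word tokens of length ≥ 2 with at least one cased character and all
cased characters uppercase (digits allowed). Special characters are
everything outside alphanumerics, whitespace and `. , : ; ' -` — the common
clinical punctuation is excluded so the statistic tracks symbols like `/`,
`#`, `@`, `(`, `%`. All fields are corpus-pooled ratios, hence invariant
under duplicating every document.

## Semantic metrics

Granularity is the sentence (one embedding row per sentence). The packaged
encoder is a seeded hash projection: CRC32-bucketed bag-of-words counts
(512 buckets) projected to d = 16 by a Gaussian matrix drawn once from the
seed. It is deterministic, corpus-independent and dependency-free; any
encoder with the same `encode` contract can replace it.

- **MMD** uses the biased V-statistic with k(x,y) = exp(−‖x−y‖²/(2σ²)),
  σ = median of nonzero pairwise Euclidean distances over the pooled
  sample. The biased estimator is chosen for small-sample stability; the
  reported value is √max(0, MMD²). An all-zero distance matrix (a
  degenerate cloud) is an error rather than a silent 0/0.
- **Fréchet distance** is reported as the squared distance
  ‖μ₁−μ₂‖² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^½) with sample (ddof = 1) covariances. When
  the matrix square root is numerically non-finite, εI (ε = 1e−6) is added
  to both covariances first; small negative round-off is clipped to zero.
- **Cluster drift** fits k-means (k-means++ init, 10 restarts, fixed seed)
  on the reference rows only, assigns both samples to the nearest centroid
  and takes base-2 JSD between the normalized assignment histograms. The
  default k = 10 is configurable and recorded, with the seed and backend
  identity, in the profile metadata.

## Strict tagging evaluation and ΔF1

A predicted entity is a true positive iff its label, start token and end
token match a gold span exactly; evaluation is per entity type with spans
of other types ignored, mirroring one-type-at-a-time tagger training.
Zero-denominator convention: precision (recall) is 0 when there are no
predictions (no gold spans). When both sides are empty the result carries
zero counts and F1 = 0 but is flagged `vacuous`, so callers can exclude
such documents instead of silently inflating averages.

ΔF1 for an (evaluation target, entity type) cell is max(real-trained F1) −
mean(synthetic-trained F1); it may be negative when synthetic training
wins. OOD summaries exclude in-distribution rows (evaluation target equal
to the training source) and report mean and population std.

## Correlation and ranking

Pearson and Spearman (mid-rank ties) are both always computed — the two
are first-class because either may be the quantity of interest — with the
ranking key selectable (default Pearson). Missing or NaN metric values are
handled by pairwise deletion with the per-metric n reported; no
imputation. Metrics with fewer than 3 usable pairs or zero variance are
flagged and left unranked. Ties in |r| break lexicographically by metric
name for determinism. The matrix export orders metric columns by rank and
rows by configuration id, so reruns are byte-identical.

## Fixture generator

The fixture generator emulates short clinical-note-like documents: 2–3
sentences per document, target sentence length normal(22, 4) tokens,
yielding ≈57–61 tokens per document; a mildly clinical layout
(`clinical_format_level` 0.3 by default); Poisson(0.6) entities per
document per PHI type drawn from built-in gazetteers; and a 41% negative
(entity-free) document share, the fraction implied by 0.7
negatives-per-positive odds. Knobs:

| knob | drives | default |
|---|---|---|
| `vocab_substitution_rate` | share of non-entity word tokens replaced by out-of-vocabulary variants (unigram/bigram JSD, Jaccard) | 0.0 |
| `template_reuse_rate` | probability a sentence is a verbatim stock sentence (4-gram self-repetition, Distinct-n) | 0.0 |
| `clinical_format_level` | probability a sentence renders as a key–value or bullet line with ALL-CAPS head (structural family) | 0.3 |
| `entity_density` | expected entities per document per type | 0.6 |
| `negative_fraction` | probability a document carries no entities | 0.41 |
| `sentence_length` | (mean, dispersion) of tokens per sentence | (22, 4) |

Each concern (layout, template content, reuse, formatting, substitution,
entity placement, negativity) draws from its **own seeded substream**, and
draws are made unconditionally in a fixed order. Consequently raising one
knob produces a *nested* set of changes — e.g. the sentences reused at rate
0.2 are a superset of those reused at 0.1 — which is what makes the strict
knob→metric monotonicity properties in the test suite well-posed rather
than statistical accidents, and keeps knobs from leaking into each other's
draws.

What the fixture generator does **not** emulate: genuine clinical
discourse, realistic entity context distributions, annotation noise, long
documents, or any specific institution's formatting. Passing tests
therefore demonstrate that the *measurement machinery* behaves correctly
and responds monotonically to controlled distributional change — not that
any particular real corpus pair will show a particular drift value.

## Generation loop

The multi-round loop reproduces the generator-ensemble + judge protocol:
round 0 is strictly zero-shot; each later round draws up to k = 10 samples
uniformly without replacement from the accepted pool as few-shot context
(restricting the draw to accepted samples is how "highly judged" is
honored; no score-proportional weighting is applied). A sample is admitted
iff (1) its inline `[X]…[/X]` markup passes the structural sanity check
(balanced, non-nested, polarity-consistent, 1–5 sentences), (2) its mean
judge score (1–5) reaches the threshold 3.0, and (3) each of its target
entity surface strings has been admitted fewer than 10 times. The cap is
checked at pool-admission time. Defaults are 30 rounds × 250 samples per
round per generator; tests and the acceptance script scale this to 3 × 2
generators × 20–50 samples, which exercises every admission path at a
fraction of the cost. The "negative ratio 0.7" is ambiguous between
odds and fraction; both modes are implemented, with
negatives:positives odds = 0.7 (≈41% negatives) as the default, and the
mode recorded in the configuration. One loop instance serves one entity
type; independent pools per type are enforced by construction.

The mock generator is a seeded template sampler over the gazetteers (with
optional markup corruption and entity pinning to exercise rejection
paths); the mock judge maps a seeded hash of the sample text to 1–5. Both
are deterministic, so the whole loop is bit-reproducible and testable
offline; real LLM backends implement the same two contracts.

## Profile assembly and orchestration

The 24-metric roster is frozen in `METRIC_ROSTER` (15 surface, 5
structural, 4 semantic). Metrics unavailable under the current
configuration are `null` with a reason string, never silently dropped.
Profile metadata records toolkit version, seed, backend identities, k and
embedding dimension. End-to-end runs require ≥3 configurations, embed a
hash of the effective inputs in both CSV exports, and are byte-identical
across reruns with the same inputs and seed.

## Known limitations

- The unigram perplexity backend measures lexical fit, not fluency; a
  transformer scorer would order corpora differently.
- The hash-projection encoder captures bag-of-words geometry only;
  semantic metrics under it respond to lexical overlap rather than meaning.
- MTLD on very short or fully distinct documents is undefined by design;
  heavy use of the sentinel reduces the n available to correlation.
- Strict matching gives no credit for partial boundary overlap; this is
  intentional (it is the standard de-identification protocol) but harsh on
  long ADDRESS-like spans.
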