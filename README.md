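# driftscan

Toolkit for measuring **distributional drift** between a training corpus and
an evaluation corpus of clinical text, and for relating that drift to the
performance of PHI (protected health information) de-identification models.

Synthetic clinical notes generated by large language models are an appealing
substitute for scarce, access-restricted real notes, but taggers trained on
them often degrade on real text. driftscan quantifies *how far* a synthetic
(or any other) corpus sits from a reference corpus — lexically, structurally
and semantically — and tests *which* of those drift signals predicts the
downstream F1 drop, without requiring access to target labels.

## What it computes

**Drift metrics (24, three families)** for a (train, eval) corpus pair:

- *Surface*: Jensen–Shannon divergence (base 2) on unigram and bigram
  distributions, JSD(p,q) = ½KL(p‖m) + ½KL(q‖m) with m = ½(p+q); vocabulary
  Jaccard overlap |V₁∩V₂|/|V₁∪V₂|; absolute differences in sentence-length
  mean/std, punctuation and digit token rates, vocabulary entropy, MTLD
  (type–token threshold 0.72), Yule's K = 10⁴(Σₘ m²V(m) − N)/N², Distinct-1/2,
  4-gram self-repetition, Flesch–Kincaid grade, and language-model
  perplexity exp(ΣNLL/Σtokens) behind a pluggable scorer.
- *Structural*: line-break density per 100 tokens, key–value sentence
  fraction, bullet/enumerated line fraction, ALL-CAPS token share,
  special-character token fraction.
- *Semantic*: over sentence embeddings from a pluggable encoder — RBF-kernel
  maximum mean discrepancy (median-distance bandwidth, biased V-statistic),
  squared Fréchet distance ‖μ₁−μ₂‖² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^½) between Gaussian
  summaries, JSD over k-means cluster-assignment histograms (centroids fit
  on the reference sample), and the Euclidean distance between embedding
  means.

**Tagging evaluation**: strict entity-level precision/recall/F1 over four
harmonized PHI categories (ADDRESS, CONTACT, DATE, PERSON) — a prediction
counts only when label and both token boundaries match exactly — and the
degradation statistic **ΔF1 = best real-trained F1 − mean synthetic-trained
F1** per (evaluation target, entity type) cell.

**Correlation**: Pearson and Spearman coefficients of every drift metric
with ΔF1 across configurations, ranked by |r|, with a configurations ×
metrics matrix export for heatmap rendering.

**Synthetic data**: a seeded fixture generator for short clinical-note-like
documents (2–3 sentences, ≈57–61 tokens) with continuous drift knobs, and a
multi-round generator-ensemble + judge loop (zero-shot round 0, few-shot
k=10 from the accepted pool, judge threshold 3.0, a 10-occurrence cap per
entity string, negative ratio 0.7) behind pluggable backends with
deterministic mocks.

## Worked example

```python
import driftscan as ds

ref = ds.generate_fixture_corpus(ds.DriftKnobs(seed=0), 100, name="reference")
drift = ds.generate_fixture_corpus(
    ds.DriftKnobs(vocab_substitution_rate=0.3, template_reuse_rate=0.2, seed=0),
    100, name="drifted")

profile = ds.compute_profile(ref, drift, seed=0)
for k in ("jsd_unigram", "jsd_bigram", "vocab_jaccard", "mmd", "cluster_drift"):
    print(f"{k:26s} {profile.values[k]:.4f}")
```

prints

```
jsd_unigram                0.1797
jsd_bigram                 0.4562
vocab_jaccard              0.5977
mmd                        0.1713
cluster_drift              0.0679
```

Replacing 30% of the non-entity vocabulary moved about 0.18 bit of unigram
mass (and more for bigrams, whose contexts fragment faster), dropped shared
vocabulary to ~60%, and is visible in embedding space (MMD 0.17). The same
pair compared against itself gives 0 everywhere (1.0 for the Jaccard
overlap).

Strict scoring and ΔF1:

```python
res = ds.strict_entity_prf(gold_corpus, pred_corpus, "PERSON")  # exact-boundary match
cell = ds.delta_f1(run_records, eval_target="i2b2-like", entity_type="PERSON")
print(res.f1, cell.delta)
```

A command-line interface mirrors the library:

```bash
driftscan profile --train ref.jsonl --eval syn.jsonl --out profile.json
driftscan eval-ner --gold g.conll --pred p.conll --entity PERSON --out eval.json
driftscan synth fixture --n 1000 --seed 1 --out corpus.jsonl
driftscan synth loop --entity DATE --seed 1 --out pool.jsonl --audit audit.csv
driftscan mix --real r.jsonl --syn s.jsonl --prop 0.4 --n 500 --out mixed.jsonl
```

Corpora are read and written as CoNLL-style BIO TSV or JSONL with
character-offset entity spans (see `driftscan.corpus_model`).

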