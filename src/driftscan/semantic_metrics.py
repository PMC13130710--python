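"""Embedding-space drift metrics.

Sentence embeddings come from a pluggable :class:`EmbeddingBackend`; the
packaged backend is a seeded hash-projection stub (token-hash count vectors
projected to a low-dimensional space by a fixed Gaussian matrix), which keeps
the whole pipeline deterministic and dependency-free.  A transformer encoder
can be plugged in behind the same contract.

Metrics: RBF-kernel maximum mean discrepancy with the median-distance
bandwidth, Fréchet distance between Gaussian summaries (squared-distance
convention), cluster-assignment drift (JSD over k-means histograms with
centroids fit on the reference sample), and the Euclidean distance between
embedding means.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy.linalg import sqrtm
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .corpus_model import Corpus, tokenize
from .surface_metrics import Distribution, MetricError, jsd


class EmbeddingBackend(Protocol):
    """Deterministic sentence encoder contract."""

    name: str
    dim: int

    def encode(self, sentences: Sequence[str]) -> np.ndarray:
        """Return a (len(sentences), dim) matrix; same input → same output."""
        ...


class HashProjectionEncoder:
    """Seeded random projection of token-hash count vectors.

    Each sentence becomes a CRC32-bucketed bag-of-words count vector of size
    ``n_buckets``, projected to ``dim`` coordinates by a Gaussian matrix drawn
    once from ``seed``.  Fully deterministic and corpus-independent.
    """

    def __init__(self, dim: int = 16, n_buckets: int = 512, seed: int = 0) -> None:
        if dim < 2:
            raise MetricError("embedding dim must be ≥ 2")
        self.dim = dim
        self.n_buckets = n_buckets
        self.seed = seed
        self.name = f"hash-projection(d={dim},seed={seed})"
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((n_buckets, dim)) / np.sqrt(n_buckets)

    def _counts(self, sentence: str) -> np.ndarray:
        vec = np.zeros(self.n_buckets)
        for tok in tokenize(sentence):
            if tok.is_word:
                bucket = zlib.crc32(tok.text.lower().encode("utf-8")) % self.n_buckets
                vec[bucket] += 1.0
        return vec

    def encode(self, sentences: Sequence[str]) -> np.ndarray:
        counts = np.stack([self._counts(s) for s in sentences]) if sentences else np.zeros((0, self.n_buckets))
        return counts @ self._proj


@dataclass
class EmbeddingSet:
    """A matrix of sentence embeddings with its source corpus name."""

    matrix: np.ndarray
    source: str

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise MetricError("embedding matrix must be 2-D")
        if not np.isfinite(self.matrix).all():
            raise MetricError(f"non-finite embeddings from {self.source}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def embed_corpus(corpus: Corpus, backend: EmbeddingBackend) -> EmbeddingSet:
    """Encode every sentence of the corpus, in corpus order."""
    sentences = [doc.sentence_text(span) for doc in corpus for span in doc.sentences]
    if len(sentences) < 2:
        raise MetricError(f"corpus {corpus.name} has <2 sentences")
    return EmbeddingSet(backend.encode(sentences), corpus.name)


def _median_bandwidth(pooled: np.ndarray) -> float:
    d = cdist(pooled, pooled)
    vals = d[np.triu_indices_from(d, k=1)]
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise MetricError("degenerate embedding cloud")
    return float(np.median(nonzero))


def mmd_rbf(X: EmbeddingSet, Y: EmbeddingSet) -> float:
    """Biased (V-statistic) RBF-kernel MMD with median bandwidth.

    k(x,y) = exp(−‖x−y‖²/(2σ²)) with σ the median of nonzero pairwise
    distances over the pooled sample; returns √max(0, MMD²).
    """
    if X.n < 2 or Y.n < 2:
        raise MetricError("MMD requires n ≥ 2 per sample")
    pooled = np.vstack([X.matrix, Y.matrix])
    sigma = _median_bandwidth(pooled)
    gamma = 1.0 / (2.0 * sigma * sigma)

    def kmean(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.exp(-gamma * cdist(a, b, "sqeuclidean")).mean())

    mmd2 = kmean(X.matrix, X.matrix) + kmean(Y.matrix, Y.matrix) - 2 * kmean(X.matrix, Y.matrix)
    return float(np.sqrt(max(mmd2, 0.0)))


def frechet_distance(X: EmbeddingSet, Y: EmbeddingSet) -> float:
    """Squared Fréchet distance between Gaussian summaries:
    ‖μX−μY‖² + Tr(ΣX + ΣY − 2(ΣX ΣY)^½)."""
    if X.n < 2 or Y.n < 2:
        raise MetricError("Fréchet distance requires n ≥ 2 per sample")
    mu_x, mu_y = X.matrix.mean(axis=0), Y.matrix.mean(axis=0)
    cov_x = np.cov(X.matrix, rowvar=False)
    cov_y = np.cov(Y.matrix, rowvar=False)
    cov_x = np.atleast_2d(cov_x)
    cov_y = np.atleast_2d(cov_y)

    covmean = sqrtm(cov_x @ cov_y)
    if not np.isfinite(covmean).all():
        eps = 1e-6
        eye = np.eye(cov_x.shape[0])
        covmean = sqrtm((cov_x + eps * eye) @ (cov_y + eps * eye))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    d2 = float(np.sum((mu_x - mu_y) ** 2) + np.trace(cov_x + cov_y - 2.0 * covmean))
    if not np.isfinite(d2):
        raise MetricError("Fréchet distance non-finite after regularization")
    return max(d2, 0.0)


def cluster_drift(real: EmbeddingSet, syn: EmbeddingSet, k: int = 10, seed: int = 0) -> float:
    """JSD (bits) between cluster-assignment histograms.

    k-means (k-means++ init, 10 restarts, fixed seed) is fit on the real
    rows; both samples are assigned to the nearest centroid.
    """
    if real.n < k:
        raise MetricError(f"k exceeds reference size ({k} > {real.n})")
    if syn.n < 1:
        raise MetricError("empty synthetic sample")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    km.fit(real.matrix)
    hist_real = np.bincount(km.predict(real.matrix), minlength=k).astype(float)
    hist_syn = np.bincount(km.predict(syn.matrix), minlength=k).astype(float)
    support = tuple(range(k))
    p = Distribution(support, hist_real / hist_real.sum())
    q = Distribution(support, hist_syn / hist_syn.sum())
    return jsd(p, q)


def mean_embedding_distance(X: EmbeddingSet, Y: EmbeddingSet) -> float:
    """Euclidean distance between the two embedding means."""
    if X.n < 1 or Y.n < 1:
        raise MetricError("empty embedding set")
    return float(np.linalg.norm(X.matrix.mean(axis=0) - Y.matrix.mean(axis=0)))
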