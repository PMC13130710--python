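"""Run configuration, the merged drift profile, and pipeline orchestration.

The canonical drift-metric roster is frozen here: 24 named metrics across
the three families (15 surface, 5 structural, 4 semantic).  ``profile_pair``
computes all enabled families for one (train, eval) corpus pair;
``end_to_end`` chains strict tagging evaluation, ΔF1 and metric–ΔF1
correlation into the ranking and heatmap-matrix exports.

Outputs embed a hash of the effective configuration so that reruns with an
identical configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .corpus_model import Corpus, read_conll_bio, read_jsonl_spans
from .drift_correlation import CorrelationError, PairedSample, rank_metrics
from .semantic_metrics import (
    HashProjectionEncoder,
    cluster_drift,
    embed_corpus,
    frechet_distance,
    mean_embedding_distance,
    mmd_rbf,
)
from .structural_metrics import structural_drift
from .surface_metrics import UnigramLMScorer, is_undefined, surface_profile
from .tagging_eval import RunRecord, delta_f1

logger = logging.getLogger("driftscan")

#: Canonical enumeration of the 24 drift metrics, name → family.
METRIC_ROSTER: dict[str, str] = {
    # surface (15)
    "jsd_unigram": "surface",
    "jsd_bigram": "surface",
    "vocab_jaccard": "surface",
    "sent_len_mean_diff": "surface",
    "sent_len_std_diff": "surface",
    "punct_rate_diff": "surface",
    "digit_rate_diff": "surface",
    "vocab_entropy_diff": "surface",
    "mtld_diff": "surface",
    "yules_k_diff": "surface",
    "distinct1_diff": "surface",
    "distinct2_diff": "surface",
    "self_repetition_diff": "surface",
    "fk_grade_diff": "surface",
    "perplexity_diff": "surface",
    # structural (5)
    "line_break_density_diff": "structural",
    "keyvalue_fraction_diff": "structural",
    "bullet_fraction_diff": "structural",
    "allcaps_share_diff": "structural",
    "specialchar_fraction_diff": "structural",
    # semantic (4)
    "mmd": "semantic",
    "frechet_distance": "semantic",
    "cluster_drift": "semantic",
    "embedding_mean_distance": "semantic",
}

FAMILIES = ("surface", "structural", "semantic")


class ConfigError(ValueError):
    """Configuration validation error; message carries the field path."""


@dataclass
class DriftProfile:
    """Named drift metric → value map with family tags and provenance."""

    train_name: str
    eval_name: str
    values: dict[str, float | None]
    reasons: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def family(self, name: str) -> str:
        return METRIC_ROSTER[name]

    def to_json_dict(self) -> dict:
        return {
            "train": self.train_name,
            "eval": self.eval_name,
            "metrics": {
                name: {
                    "value": None if v is None or (isinstance(v, float) and math.isnan(v)) else v,
                    "family": METRIC_ROSTER[name],
                    **({"reason": self.reasons[name]} if name in self.reasons else {}),
                }
                for name, v in self.values.items()
            },
            "metadata": self.metadata,
        }


@dataclass
class RunConfig:
    """Configuration for one (train, eval) profile run."""

    train_path: str
    eval_path: str
    corpus_format: str = "jsonl"  # jsonl | conll
    families: tuple[str, ...] = FAMILIES
    lm_backend: str | None = "unigram"
    embed_backend: str = "stub"
    embed_dim: int = 16
    kmeans_k: int = 10
    seed: int = 0
    correlation_key: str = "pearson"
    out_dir: str = "."

    def validate(self) -> None:
        for fld in ("train_path", "eval_path"):
            if not Path(getattr(self, fld)).exists():
                raise ConfigError(f"{fld}: path {getattr(self, fld)!r} does not exist")
        if self.corpus_format not in ("jsonl", "conll"):
            raise ConfigError(f"corpus_format: unknown format {self.corpus_format!r}")
        for fam in self.families:
            if fam not in FAMILIES:
                raise ConfigError(f"families: unknown family {fam!r}")
        if self.lm_backend not in (None, "unigram"):
            raise ConfigError(f"lm_backend: unknown backend {self.lm_backend!r}")
        if self.embed_backend != "stub":
            raise ConfigError(f"embed_backend: unknown backend {self.embed_backend!r}")
        if self.correlation_key not in ("pearson", "spearman"):
            raise ConfigError(f"correlation_key: {self.correlation_key!r}")

    def config_hash(self) -> str:
        payload = json.dumps(vars(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_corpus(path: str | Path, corpus_format: str, name: str | None = None) -> Corpus:
    path = Path(path)
    reader = read_jsonl_spans if corpus_format == "jsonl" else read_conll_bio
    with open(path, encoding="utf-8") as fh:
        return reader(fh, name=name or path.stem)


def compute_profile(
    train: Corpus,
    eval: Corpus,
    families: Sequence[str] = FAMILIES,
    lm_backend: str | None = "unigram",
    embed_dim: int = 16,
    kmeans_k: int = 10,
    seed: int = 0,
) -> DriftProfile:
    """Compute the merged drift profile for an in-memory corpus pair."""
    values: dict[str, float | None] = {name: None for name in METRIC_ROSTER}
    reasons: dict[str, str] = {}

    if "surface" in families:
        scorer = UnigramLMScorer(train) if lm_backend == "unigram" else None
        sp = surface_profile(train, eval, scorer)
        for name, v in sp.as_dict().items():
            if v is None:
                reasons[name] = "no scorer"
            elif is_undefined(v):
                reasons[name] = "undefined on this pair"
            values[name] = v
        logger.info("stage=surface train=%s eval=%s", train.name, eval.name)
    else:
        for name, fam in METRIC_ROSTER.items():
            if fam == "surface":
                reasons[name] = "family disabled"

    if "structural" in families:
        for name, v in structural_drift(train, eval).items():
            values[name] = v
        logger.info("stage=structural train=%s eval=%s", train.name, eval.name)
    else:
        for name, fam in METRIC_ROSTER.items():
            if fam == "structural":
                reasons[name] = "family disabled"

    backend_name = None
    if "semantic" in families:
        backend = HashProjectionEncoder(dim=embed_dim, seed=seed)
        backend_name = backend.name
        ex = embed_corpus(train, backend)
        ey = embed_corpus(eval, backend)
        values["mmd"] = mmd_rbf(ex, ey)
        values["frechet_distance"] = frechet_distance(ex, ey)
        values["cluster_drift"] = cluster_drift(ex, ey, k=kmeans_k, seed=seed)
        values["embedding_mean_distance"] = mean_embedding_distance(ex, ey)
        logger.info(
            "stage=semantic train=%s eval=%s n_train=%d n_eval=%d",
            train.name, eval.name, ex.n, ey.n,
        )
    else:
        for name, fam in METRIC_ROSTER.items():
            if fam == "semantic":
                reasons[name] = "family disabled"

    metadata = {
        "toolkit_version": __version__,
        "seed": seed,
        "lm_backend": lm_backend,
        "embed_backend": backend_name,
        "embed_dim": embed_dim,
        "kmeans_k": kmeans_k,
    }
    return DriftProfile(train.name, eval.name, values, reasons, metadata)


def profile_pair(config: RunConfig) -> DriftProfile:
    """Load the configured corpus pair and compute the merged profile."""
    config.validate()
    train = load_corpus(config.train_path, config.corpus_format)
    eval = load_corpus(config.eval_path, config.corpus_format)
    profile = compute_profile(
        train,
        eval,
        families=config.families,
        lm_backend=config.lm_backend,
        embed_dim=config.embed_dim,
        kmeans_k=config.kmeans_k,
        seed=config.seed,
    )
    profile.metadata["config_hash"] = config.config_hash()
    return profile


@dataclass(frozen=True)
class PairConfiguration:
    """One end-to-end configuration: a corpus pair and its ΔF1 cell."""

    config_id: str
    train: Corpus
    eval: Corpus
    eval_target: str
    entity_type: str


def end_to_end(
    configurations: Sequence[PairConfiguration],
    records: Sequence[RunRecord],
    out_dir: str | Path,
    correlation_key: str = "pearson",
    seed: int = 0,
    lm_backend: str | None = "unigram",
) -> tuple[Path, Path]:
    """Profile every configuration, attach ΔF1, rank metrics, export CSVs.

    Writes ``ranking.csv`` and ``heatmap.csv`` into ``out_dir`` and returns
    their paths.  Deterministic given inputs and seeds; outputs embed a hash
    of the effective inputs.
    """
    if len(configurations) < 3:
        raise ConfigError(
            f"insufficient configurations: need ≥3, got {len(configurations)}"
        )
    samples = []
    for cfg in configurations:
        try:
            profile = compute_profile(cfg.train, cfg.eval, lm_backend=lm_backend, seed=seed)
        except Exception as exc:
            raise RuntimeError(f"stage=profile config={cfg.config_id}: {exc}") from exc
        try:
            delta = delta_f1(records, cfg.eval_target, cfg.entity_type).delta
        except Exception as exc:
            raise RuntimeError(f"stage=delta config={cfg.config_id}: {exc}") from exc
        samples.append(PairedSample(cfg.config_id, profile.values, delta))
    try:
        rows, matrix = rank_metrics(samples, coefficient=correlation_key)
    except CorrelationError as exc:
        raise RuntimeError(f"stage=correlate: {exc}") from exc

    payload = json.dumps(
        {
            "configs": [c.config_id for c in configurations],
            "key": correlation_key,
            "seed": seed,
            "version": __version__,
        },
        sort_keys=True,
    )
    run_hash = hashlib.sha256(payload.encode()).hexdigest()[:16]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ranking_path = out_dir / "ranking.csv"
    heatmap_path = out_dir / "heatmap.csv"
    with open(ranking_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# driftscan ranking key={correlation_key} hash={run_hash}\n")
        fh.write("metric,family,pearson_r,spearman_rho,n,rank\n")
        for row in rows:
            fh.write(
                f"{row.metric},{METRIC_ROSTER[row.metric]},"
                f"{row.pearson_r:.10g},{row.spearman_rho:.10g},{row.n},{row.rank}\n"
            )
    with open(heatmap_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# driftscan heatmap key={correlation_key} hash={run_hash}\n")
        matrix.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
    logger.info("stage=end_to_end configs=%d out=%s", len(configurations), out_dir)
    return ranking_path, heatmap_path
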