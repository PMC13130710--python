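"""Strict entity-level scoring of PHI predictions and the ΔF1 statistic.

A predicted entity counts as a true positive only when its label and both
token boundaries match a gold span exactly.  Evaluation is per entity type,
with spans of other types ignored, mirroring one-type-at-a-time tagger
training.  ΔF1 for an (evaluation target, entity type) cell is the best
real-trained F1 minus the mean synthetic-trained F1; higher values indicate
greater degradation and it may be negative when synthetic training wins.

Zero-denominator convention: precision (recall) is 0 when there are no
predictions (no gold spans); when both gold and predictions are empty the
result carries zero counts, F1 = 0, and is flagged ``vacuous`` so callers
can exclude it from averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .corpus_model import Corpus


class EvalError(ValueError):
    """Raised on gold/prediction corpus mismatches or missing groups."""


@dataclass(frozen=True)
class EvalResult:
    entity_type: str
    tp: int
    fp: int
    fn: int
    vacuous: bool = False

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass(frozen=True)
class RunRecord:
    """One train→evaluate run of a tagger."""

    train_source: str
    train_size: str
    eval_target: str
    entity_type: str
    seed: int
    f1: float
    provenance: str  # real | synthetic | mixed

    def __post_init__(self) -> None:
        if not 0.0 <= self.f1 <= 1.0:
            raise EvalError(f"f1 {self.f1} outside [0,1]")


@dataclass(frozen=True)
class DeltaF1Record:
    eval_target: str
    entity_type: str
    best_real_f1: float
    mean_synthetic_f1: float

    @property
    def delta(self) -> float:
        return self.best_real_f1 - self.mean_synthetic_f1


def strict_entity_prf(gold: Corpus, pred: Corpus, entity_type: str) -> EvalResult:
    """Strict entity-level precision/recall/F1 for one entity type.

    Gold and prediction corpora must agree on doc_ids (in order) and on
    per-document token counts.
    """
    if len(gold) != len(pred):
        raise EvalError(
            f"document count mismatch: {len(gold)} gold vs {len(pred)} predicted"
        )
    tp = fp = fn = 0
    any_span = False
    for g, p in zip(gold, pred):
        if g.doc_id != p.doc_id:
            raise EvalError(f"doc_id mismatch: {g.doc_id} vs {p.doc_id}")
        if len(g.tokens) != len(p.tokens):
            raise EvalError(f"tokenization mismatch in doc {g.doc_id}")
        g_spans = {
            (e.start_token, e.end_token) for e in g.entities if e.label == entity_type
        }
        p_spans = {
            (e.start_token, e.end_token) for e in p.entities if e.label == entity_type
        }
        if g_spans or p_spans:
            any_span = True
        tp += len(g_spans & p_spans)
        fp += len(p_spans - g_spans)
        fn += len(g_spans - p_spans)
    return EvalResult(entity_type, tp, fp, fn, vacuous=not any_span)


def delta_f1(
    records: Iterable[RunRecord], eval_target: str, entity_type: str
) -> DeltaF1Record:
    """Best real-trained F1 minus mean synthetic-trained F1 for one cell."""
    cell = [
        r for r in records if r.eval_target == eval_target and r.entity_type == entity_type
    ]
    real = [r.f1 for r in cell if r.provenance == "real"]
    synthetic = [r.f1 for r in cell if r.provenance == "synthetic"]
    if not real or not synthetic:
        raise EvalError(
            f"cell ({eval_target}, {entity_type}) needs ≥1 real and ≥1 synthetic record"
        )
    return DeltaF1Record(eval_target, entity_type, max(real), float(np.mean(synthetic)))


def ood_summary(
    records: Sequence[RunRecord],
) -> dict[tuple[str, str], tuple[float, float, int]]:
    """Mean and population std of F1 over out-of-distribution targets.

    In-distribution records (evaluation target equals the training source)
    are excluded.  Keys are (train_source, entity_type); values are
    (mean, std, n).  Cells with no OOD record are omitted.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if r.eval_target == r.train_source:
            continue
        cells.setdefault((r.train_source, r.entity_type), []).append(r.f1)
    return {
        key: (float(np.mean(v)), float(np.std(v)), len(v)) for key, v in cells.items()
    }
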