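"""Correlation of drift metrics with ΔF1 degradation across configurations.

Each configuration (train source, evaluation target, entity type, training
size) pairs a drift profile with one ΔF1 value.  Every metric is correlated
with ΔF1 by both the Pearson product-moment coefficient and Spearman's
rank coefficient, and metrics are ranked by absolute value of the selected
coefficient.  Missing or undefined metric values are handled by pairwise
deletion; the per-row sample size is reported.  Ties in |r| break
lexicographically by metric name for determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

class CorrelationError(ValueError):
    """Raised when there is not enough usable variation to correlate."""


@dataclass(frozen=True)
class PairedSample:
    """One configuration's drift profile paired with its ΔF1."""

    config_id: str
    metrics: Mapping[str, float | None]
    delta: float


@dataclass(frozen=True)
class CorrelationRow:
    metric: str
    pearson_r: float
    spearman_rho: float
    n: int
    rank: int


def _clean(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    if len(x) != len(y):
        raise CorrelationError("length mismatch")
    xa = np.array([math.nan if v is None else float(v) for v in x])
    ya = np.array([math.nan if v is None else float(v) for v in y])
    mask = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[mask], ya[mask]
    if len(xa) < 3:
        raise CorrelationError("insufficient variation: fewer than 3 paired values")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise CorrelationError("insufficient variation: zero variance")
    return xa, ya


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with pairwise deletion of missing values."""
    xa, ya = _clean(x, y)
    return float(stats.pearsonr(xa, ya).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation (mid-ranks for ties), pairwise deletion."""
    xa, ya = _clean(x, y)
    return float(stats.spearmanr(xa, ya).statistic)


def rank_metrics(
    samples: Sequence[PairedSample], coefficient: str = "pearson"
) -> tuple[list[CorrelationRow], pd.DataFrame]:
    """Correlate every metric with ΔF1 and rank by |coefficient|.

    Returns the ranked rows (metrics with insufficient data are appended
    unranked with rank 0 and NaN coefficients) and a configurations × metrics
    matrix with the delta column, metric columns ordered by rank — the input
    for heatmap rendering.
    """
    if coefficient not in ("pearson", "spearman"):
        raise CorrelationError(f"unknown coefficient {coefficient!r}")
    if not samples:
        raise CorrelationError("no samples")
    names = list(samples[0].metrics.keys())
    for s in samples[1:]:
        if list(s.metrics.keys()) != names:
            raise CorrelationError("metric names differ across samples")

    deltas = [s.delta for s in samples]
    usable: list[tuple[str, float, float, int]] = []
    unusable: list[str] = []
    for name in names:
        vals = [s.metrics[name] for s in samples]
        try:
            r = pearson(vals, deltas)
            rho = spearman(vals, deltas)
        except CorrelationError:
            unusable.append(name)
            continue
        n = int(
            np.sum(
                [
                    v is not None and math.isfinite(float(v))
                    for v in vals
                ]
            )
        )
        usable.append((name, r, rho, n))
    if not usable:
        raise CorrelationError("no metric has enough usable data")

    key_idx = 1 if coefficient == "pearson" else 2
    usable.sort(key=lambda row: (-abs(row[key_idx]), row[0]))
    rows = [
        CorrelationRow(name, r, rho, n, rank)
        for rank, (name, r, rho, n) in enumerate(usable, start=1)
    ]
    rows += [
        CorrelationRow(name, math.nan, math.nan, 0, 0) for name in sorted(unusable)
    ]

    # deterministic matrix: sorted config ids, metric columns by rank
    ordered = [row.metric for row in rows if row.rank > 0]
    matrix = pd.DataFrame(
        {
            "config_id": [s.config_id for s in samples],
            "delta_f1": deltas,
            **{name: [s.metrics[name] for s in samples] for name in ordered},
        }
    ).sort_values("config_id", kind="stable", ignore_index=True)
    return rows, matrix
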