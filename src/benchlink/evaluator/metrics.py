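"""Evaluation metrics: correlations and cross-condition differentials."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedMetric(ValueError):
    """A metric could not be computed (too few points, zero variance);
    surfaced in reports as an undefined-metric record, never a crash."""


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < min_n:
        raise UndefinedMetric(f"need >= {min_n} points, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetric("zero variance")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation."""
    x, y = _check_pair(x, y)
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Rank correlation: Pearson on mid-ranks (ties averaged)."""
    x, y = _check_pair(x, y)
    return float(stats.spearmanr(x, y).statistic)


METRICS = {"pearson": pearson, "spearman": spearman}


def paired_complete(
    obs: pd.DataFrame, pred: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two condition tables on their shared sequences, dropping rows
    with any missing value in the requested columns."""
    shared = obs.index.intersection(pred.index)
    o = obs.loc[shared, columns]
    p = pred.loc[shared, columns]
    keep = o.notna().all(axis=1) & p.notna().all(axis=1)
    return o[keep], p[keep]


def differential_metric(
    obs: pd.DataFrame,
    pred: pd.DataFrame,
    pair: tuple[str, str],
    metric: str = "pearson",
) -> tuple[float, int]:
    """Correlation of per-sequence between-condition differences.

    Measures whether the model captures condition-specific (e.g. cell
    type-specific) activity rather than a shared sequence effect: for
    conditions (A, B), correlate obs_A - obs_B with pred_A - pred_B across
    sequences.  Invariant to any per-condition additive shift.
    """
    a, b = pair
    for table, side in ((obs, "observed"), (pred, "predicted")):
        missing = {a, b} - set(table.columns)
        if missing:
            raise UndefinedMetric(f"condition {sorted(missing)} missing from {side}")
    o, p = paired_complete(obs, pred, [a, b])
    value = METRICS[metric](o[a] - o[b], p[a] - p[b])
    return value, len(o)
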