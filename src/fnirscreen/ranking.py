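"""Chi-squared channel prioritization.

Each continuous feature (channel) is discretized into quantile bins and
tested for independence against the binary label with a chi-squared
contingency test; the channel's priority score is ln(1/p). Quantile
binning makes the score invariant under any strictly increasing
transform of the feature, and bins whose expected count falls below 1
are merged with a neighbor to keep the chi-squared approximation sane.
The paper-facing interface ranks whole feature matrices; an array-level
helper serves per-fold ranking inside cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .containers import FeatureMatrix

__all__ = [
    "PriorityScores",
    "chi2_priority_scores",
    "chi2_scores_array",
    "chi2_score_from_table",
    "binned_table",
    "rank_features",
]


@dataclass
class PriorityScores:
    """Per-channel chi-squared priority scores.

    ``order`` lists channel ids by descending score, ties broken by
    ascending channel id. ``binning`` records the number of (merged)
    bins actually used per channel.
    """

    channel_ids: np.ndarray
    p_values: np.ndarray  # in (0, 1]
    scores: np.ndarray  # ln(1/p) >= 0
    order: np.ndarray  # channel ids, descending score
    n_bins_nominal: int
    binning: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rank = {cid: i + 1 for i, cid in enumerate(self.order)}
        return pd.DataFrame(
            {
                "channel_id": self.channel_ids,
                "p_value": self.p_values,
                "score": self.scores,
                "rank": [rank[int(c)] for c in self.channel_ids],
            }
        ).sort_values("rank", ignore_index=True)


def _quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-bin a continuous column; returns integer codes.

    Interior edges are the n_bins-quantiles of the data; duplicate edges
    (heavy ties) collapse the affected bins.
    """
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs[1:-1])
    return np.searchsorted(edges, x, side="right")


def _contingency(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    bins = np.unique(codes)
    table = np.zeros((len(bins), 2), dtype=float)
    for i, b in enumerate(bins):
        sel = codes == b
        table[i, 0] = np.sum(sel & (y == 0))
        table[i, 1] = np.sum(sel & (y == 1))
    return table


def _merge_sparse_bins(table: np.ndarray, min_expected: float = 1.0) -> np.ndarray:
    """Merge adjacent bins until every cell's expected count >= min_expected."""
    table = table.copy()
    while table.shape[0] > 2:
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        bad_rows = np.flatnonzero((expected < min_expected).any(axis=1))
        if bad_rows.size == 0:
            break
        r = int(bad_rows[0])
        # merge into the smaller adjacent neighbor
        if r == 0:
            other = 1
        elif r == table.shape[0] - 1:
            other = r - 1
        else:
            other = r - 1 if table[r - 1].sum() <= table[r + 1].sum() else r + 1
        lo, hi = min(r, other), max(r, other)
        table[lo] += table[hi]
        table = np.delete(table, hi, axis=0)
    return table


def binned_table(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """The merged bins x classes contingency table a feature is scored on."""
    codes = _quantile_bin(np.asarray(x, dtype=float), n_bins)
    return _merge_sparse_bins(_contingency(codes, np.asarray(y, dtype=int)))


def chi2_score_from_table(table: np.ndarray) -> tuple[float, float]:
    """(p_value, score) from a bins x classes contingency table.

    Uses the Pearson chi-squared test of independence without continuity
    correction; degrees of freedom are (bins - 1) for two classes.
    Returns (1.0, 0.0) with a warning when fewer than 2 nonempty bins
    remain.
    """
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or np.any(table.sum(axis=0) == 0):
        warnings.warn("fewer than 2 informative bins; score set to 0", stacklevel=2)
        return 1.0, 0.0
    res = chi2_contingency(table, correction=False)
    p = float(res.pvalue)
    p = max(p, np.finfo(float).tiny)  # keep the score finite
    return p, float(-np.log(p))


def chi2_scores_array(
    X: np.ndarray, y: np.ndarray, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Chi-squared p-values and scores for each column of ``X``.

    Returns (p_values, scores, n_bins_used).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be nonempty")
    p_values = np.empty(X.shape[1])
    scores = np.empty(X.shape[1])
    bins_used: list[int] = []
    for j in range(X.shape[1]):
        table = binned_table(X[:, j], y, n_bins)
        p, s = chi2_score_from_table(table)
        p_values[j] = p
        scores[j] = s
        bins_used.append(int(table.shape[0]))
    return p_values, scores, bins_used


def chi2_priority_scores(fm: FeatureMatrix, n_bins: int = 10) -> PriorityScores:
    """Rank channels by chi-squared association of binned features with labels."""
    p_values, scores, bins_used = chi2_scores_array(fm.X, fm.label, n_bins=n_bins)
    cids = fm.channel_ids
    # descending score; ties by ascending channel id
    order_idx = np.lexsort((cids, -scores))
    return PriorityScores(
        channel_ids=cids.copy(),
        p_values=p_values,
        scores=scores,
        order=cids[order_idx],
        n_bins_nominal=n_bins,
        binning={int(c): b for c, b in zip(cids, bins_used)},
    )


def rank_features(scores: PriorityScores, k: int) -> list[int]:
    """Top-k channel ids by descending priority score (ties: ascending id)."""
    n = len(scores.order)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    return [int(c) for c in scores.order[:k]]
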