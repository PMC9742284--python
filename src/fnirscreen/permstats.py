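"""Permutation-null distributions and significance testing.

The permutation null is built by reshuffling the subject label vector
uniformly (preserving class counts) and rerunning the identical
cross-validation pipeline — including any per-fold channel ranking — on
the permuted labels. Each permutation repetition pairs with one actual
CV repetition, so the actual and null metric distributions are compared
with a paired two-sided Wilcoxon signed-rank test (exact distribution
for up to 25 informative pairs, normal approximation above), Bonferroni
corrected over the tested subset sizes and metrics. A two-sample
Kolmogorov-Smirnov alternative is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, norm, rankdata

from .classify_eval import CVConfig, EvalResult, _evaluate
from .containers import FeatureMatrix
from .ranking import PriorityScores

__all__ = [
    "NullDistribution",
    "SignificanceReport",
    "permutation_null",
    "compare_to_null",
    "signed_rank_p",
]

#: Exact signed-rank enumeration is used up to this many nonzero pairs.
EXACT_LIMIT = 25


@dataclass
class NullDistribution:
    """Per-k null metric distributions from label-reshuffled reruns."""

    results: dict[int, EvalResult]  # k -> EvalResult under permuted labels
    n_permutations: int
    seed: int

    @property
    def k_range(self) -> list[int]:
        return sorted(self.results)


@dataclass
class SignificanceReport:
    """Raw and Bonferroni-corrected p-values per subset size and metric."""

    table: pd.DataFrame  # columns: k, metric, p_raw, p_corrected, significant
    n_comparisons: int
    alpha: float
    test: str


def signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped (Wilcoxon's rule); if all differences
    are zero the test is vacuous and p = 1. Absolute differences are
    midranked, so ties are handled; for up to 25 nonzero pairs the exact
    conditional null distribution of the positive-rank sum over all sign
    assignments is enumerated by dynamic programming, beyond that a
    tie-corrected normal approximation is used.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        # scale midranks to integers (x2) and convolve the sign-flip polynomial
        ir = np.round(2 * ranks).astype(int)
        total = int(ir.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for v in ir:
            shifted = np.zeros_like(counts)
            shifted[v:] = counts[: counts.size - v]
            counts = counts + shifted
        denom = counts.sum()  # 2**n
        w = int(round(2 * w_pos))
        p_ge = counts[w:].sum() / denom
        p_le = counts[: w + 1].sum() / denom
        return float(min(1.0, 2.0 * min(p_ge, p_le)))
    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    z = (w_pos - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def permutation_null(
    fm: FeatureMatrix,
    cfg: CVConfig,
    n_permutations: int = 20,
    scores: PriorityScores | None = None,
) -> NullDistribution:
    """Null metric distributions from uniformly reshuffled label vectors.

    Each permutation repetition draws a uniform permutation of the label
    vector over subjects (class counts preserved by construction), then
    runs one repetition of the identical CV pipeline — fresh fold
    partition, per-fold standardization and (in per-fold mode) per-fold
    ranking — across ``cfg.k_range``, sharing the partition across k.

    Notes
    -----
    In ``full-matrix`` ranking mode the ranking is recomputed on the
    permuted labels, keeping the null pipeline identical to the actual
    one. Precomputed ``scores`` are therefore ignored under permutation.
    """
    ks = sorted(set(cfg.k_range))
    ss = np.random.SeedSequence([cfg.seed, 0x5EED])
    perm_rng = np.random.default_rng(ss)
    perm_seeds = [int(s) for s in ss.generate_state(n_permutations) % (2**31)]
    conf = {k: np.zeros((n_permutations, 4), dtype=int) for k in ks}
    for p, perm_seed in enumerate(perm_seeds):
        y_perm = perm_rng.permutation(fm.label)
        one_rep = replace(cfg, n_repetitions=1, seed=perm_seed)
        res = _evaluate(fm, ks, one_rep, scores=None, labels=y_perm)
        for k in ks:
            conf[k][p] = res[k].confusion[0]
    results = {}
    for k in ks:
        tp, fn, tn, fp = conf[k].T
        results[k] = EvalResult(
            k=k,
            sensitivity=tp / (tp + fn),
            specificity=tn / (tn + fp),
            confusion=conf[k],
        )
    return NullDistribution(results=results, n_permutations=n_permutations, seed=cfg.seed)


def compare_to_null(
    actual: dict[int, EvalResult],
    null: NullDistribution,
    n_comparisons: int | None = None,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> SignificanceReport:
    """Test actual metric distributions against their permutation nulls.

    For every subset size k and metric (sensitivity, specificity), a
    two-sided test compares the actual per-repetition values with the
    null values; p-values are Bonferroni corrected with factor
    ``n_comparisons`` (default: number of k values x 2 metrics).

    Parameters
    ----------
    test : {"wilcoxon", "ks"}
        Paired signed-rank (default, pairs actual and null by repetition
        index) or two-sample Kolmogorov-Smirnov.

    Raises
    ------
    ValueError
        In paired mode, if actual and null repetition counts differ.
    """
    if test not in ("wilcoxon", "ks"):
        raise ValueError("test must be 'wilcoxon' or 'ks'")
    ks_common = [k for k in sorted(actual) if k in null.results]
    if not ks_common:
        raise ValueError("no common subset sizes between actual and null results")
    m = n_comparisons if n_comparisons is not None else len(ks_common) * 2
    rows = []
    for k in ks_common:
        for metric in ("sensitivity", "specificity"):
            a = getattr(actual[k], metric)
            b = getattr(null.results[k], metric)
            if test == "wilcoxon":
                if len(a) != len(b):
                    raise ValueError(
                        f"paired test needs equal repetition counts, got {len(a)} vs {len(b)}"
                    )
                p_raw = signed_rank_p(a - b)
            else:
                p_raw = float(ks_2samp(a, b).pvalue)
            p_corr = min(1.0, p_raw * m)
            rows.append(
                {
                    "k": k,
                    "metric": metric,
                    "p_raw": p_raw,
                    "p_corrected": p_corr,
                    "significant": p_corr < alpha,
                }
            )
    return SignificanceReport(
        table=pd.DataFrame(rows), n_comparisons=m, alpha=alpha, test=test
    )
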