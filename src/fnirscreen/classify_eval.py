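"""Linear-SVM discrimination with repeated subject-disjoint k-fold CV.

Each repetition draws a fresh (stratified) 5-fold partition over
subjects; within a fold, features are standardized on the training rows,
channels are (optionally) re-ranked on the training rows, a linear SVM
with box constraint 1 is trained, and the held-out subjects are
predicted. Confusion counts are pooled over the folds of a repetition,
giving one sensitivity/specificity pair per repetition. Because every
subject occupies exactly one row of the feature matrix, train and test
partitions never share a subject.

The k-sweep evaluator feeds increasingly large top-ranked channel
subsets into the classifier while sharing the fold partitions across k
within a repetition, so accuracy curves over k are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import FeatureMatrix
from .features import standardize_arrays
from .ranking import PriorityScores, chi2_scores_array

__all__ = [
    "CVConfig",
    "EvalResult",
    "compute_sens_spec",
    "crossval_classify",
    "incremental_subset_eval",
    "summary_table",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation configuration.

    ``ranking_mode`` selects where channel ranking happens:
    ``"per-fold"`` (leakage-safe default) re-ranks on each training fold;
    ``"full-matrix"`` ranks once on the whole matrix before CV, which
    mirrors filter-then-classify practice but lets ranking see test
    subjects.
    """

    n_folds: int = 5
    n_repetitions: int = 20
    k_range: tuple[int, ...] = tuple(range(2, 11))
    stratified: bool = True
    seed: int = 0
    ranking_mode: str = "per-fold"  # "per-fold" | "full-matrix"
    n_bins: int = 10
    box_constraint: float = 1.0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.ranking_mode not in ("per-fold", "full-matrix"):
            raise ValueError("ranking_mode must be 'per-fold' or 'full-matrix'")
        if any(k < 1 for k in self.k_range):
            raise ValueError("k_range entries must be >= 1")


@dataclass
class EvalResult:
    """Per-repetition classification metrics for one feature-subset size.

    ``confusion`` holds pooled per-repetition counts in the order
    (TP, FN, TN, FP); sensitivities and specificities are the exact
    ratios of those counts.
    """

    k: int
    sensitivity: np.ndarray  # (n_repetitions,)
    specificity: np.ndarray
    confusion: np.ndarray  # (n_repetitions, 4): tp, fn, tn, fp

    @property
    def accuracy(self) -> np.ndarray:
        tp, fn, tn, fp = self.confusion.T
        return (tp + tn) / self.confusion.sum(axis=1)

    @property
    def median_sensitivity(self) -> float:
        return float(np.median(self.sensitivity))

    @property
    def median_specificity(self) -> float:
        return float(np.median(self.specificity))


def compute_sens_spec(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP), exact ratios.

    Raises
    ------
    ValueError
        If either class is absent from the pooled test counts (metric
        undefined; prevented upstream by stratification).
    """
    if tp + fn == 0:
        raise ValueError("no positive subjects in test pool; sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative subjects in test pool; specificity undefined")
    return tp / (tp + fn), tn / (tn + fp)


def _check_stratifiable(y: np.ndarray, cfg: CVConfig) -> None:
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if cfg.stratified and min(n_pos, n_neg) < cfg.n_folds:
        raise ValueError(
            f"cannot stratify {cfg.n_folds} folds with class sizes "
            f"{{positive: {n_pos}, negative: {n_neg}}}"
        )


def _partition(y: np.ndarray, cfg: CVConfig, rep_seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """One repetition's subject-disjoint fold partition.

    Subjects are shuffled once, then dealt round-robin to folds within
    each stratum (label group), continuing a global fold counter so fold
    sizes stay balanced. Strata are identified by their index sets (not
    their label values) and processed in order of smallest member, so
    swapping the two class labels yields the identical partition — which
    makes sensitivity and specificity exactly exchange under label swap.
    """
    n = len(y)
    if n < cfg.n_folds:
        raise ValueError(f"cannot split {n} subjects into {cfg.n_folds} folds")
    rng = np.random.default_rng(rep_seed)
    pos = np.empty(n, dtype=int)
    pos[rng.permutation(n)] = np.arange(n)
    if cfg.stratified:
        strata: dict[int, list[int]] = {}
        for idx in range(n):
            strata.setdefault(int(y[idx]), []).append(idx)
        groups = sorted(strata.values(), key=min)
    else:
        groups = [list(range(n))]
    folds: list[list[int]] = [[] for _ in range(cfg.n_folds)]
    counter = 0
    for g in groups:
        for idx in sorted(g, key=lambda i: pos[i]):
            folds[counter % cfg.n_folds].append(idx)
            counter += 1
    all_idx = np.arange(n)
    out = []
    for f in folds:
        test_idx = np.array(sorted(f), dtype=int)
        out.append((np.setdiff1d(all_idx, test_idx), test_idx))
    return out


def _rep_seeds(cfg: CVConfig, n: int) -> list[int]:
    ss = np.random.SeedSequence(cfg.seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _run_repetition(
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    ks: Sequence[int],
    cfg: CVConfig,
    full_order: np.ndarray | None,
) -> dict[int, np.ndarray]:
    """Pooled confusion counts (tp, fn, tn, fp) per k for one partition."""
    conf = {k: np.zeros(4, dtype=int) for k in ks}
    for train_idx, test_idx in folds:
        X_train, X_test = standardize_arrays(X[train_idx], X[test_idx])
        y_train, y_test = y[train_idx], y[test_idx]
        if full_order is not None:
            order = full_order
        else:
            _, scores, _ = chi2_scores_array(X_train, y_train, n_bins=cfg.n_bins)
            order = np.lexsort((np.arange(X.shape[1]), -scores))
        for k in ks:
            cols = order[:k]
            clf = SVC(kernel="linear", C=cfg.box_constraint)
            clf.fit(X_train[:, cols], y_train)
            pred = clf.predict(X_test[:, cols])
            conf[k][0] += int(np.sum((pred == 1) & (y_test == 1)))  # tp
            conf[k][1] += int(np.sum((pred == 0) & (y_test == 1)))  # fn
            conf[k][2] += int(np.sum((pred == 0) & (y_test == 0)))  # tn
            conf[k][3] += int(np.sum((pred == 1) & (y_test == 0)))  # fp
    return conf


def _order_from_scores(fm: FeatureMatrix, scores: PriorityScores) -> np.ndarray:
    """Column indices of fm in the ranked channel order."""
    col_of = {int(c): i for i, c in enumerate(fm.channel_ids)}
    return np.array([col_of[int(c)] for c in scores.order], dtype=int)


def _evaluate(
    fm: FeatureMatrix,
    ks: Sequence[int],
    cfg: CVConfig,
    scores: PriorityScores | None = None,
    labels: np.ndarray | None = None,
) -> dict[int, EvalResult]:
    """Shared driver: repeated CV over the given subset sizes."""
    X = fm.X
    y = fm.label if labels is None else np.asarray(labels, dtype=int)
    _check_stratifiable(y, cfg)
    if max(ks) > X.shape[1]:
        raise ValueError(f"k={max(ks)} exceeds {X.shape[1]} channels")
    full_order = None
    if cfg.ranking_mode == "full-matrix":
        if scores is not None:
            full_order = _order_from_scores(fm, scores)
        else:
            _, sc, _ = chi2_scores_array(X, y, n_bins=cfg.n_bins)
            full_order = np.lexsort((np.arange(X.shape[1]), -sc))
    n_rep = cfg.n_repetitions
    conf = {k: np.zeros((n_rep, 4), dtype=int) for k in ks}
    for rep, rep_seed in enumerate(_rep_seeds(cfg, n_rep)):
        folds = _partition(y, cfg, rep_seed)
        rep_conf = _run_repetition(X, y, folds, ks, cfg, full_order)
        for k in ks:
            conf[k][rep] = rep_conf[k]
    results = {}
    for k in ks:
        sens = np.empty(n_rep)
        spec = np.empty(n_rep)
        for r in range(n_rep):
            sens[r], spec[r] = compute_sens_spec(*conf[k][r])
        results[k] = EvalResult(k=k, sensitivity=sens, specificity=spec, confusion=conf[k])
    return results


def crossval_classify(
    fm: FeatureMatrix,
    cfg: CVConfig,
    k: int | None = None,
    scores: PriorityScores | None = None,
    channels: Sequence[int] | None = None,
) -> EvalResult:
    """Repeated stratified 5-fold linear-SVM classification at one subset size.

    Parameters
    ----------
    k : int, optional
        Number of top-ranked channels to use; defaults to all channels
        (no selection).
    scores : PriorityScores, optional
        Precomputed full-matrix ranking (only used in
        ``ranking_mode="full-matrix"``).
    channels : sequence of int, optional
        Explicit channel subset; bypasses ranking entirely.
    """
    if channels is not None:
        fm = fm.select_channels(channels)
        cfg = replace(cfg, ranking_mode="full-matrix")
        scores = None
        k = len(channels)
        # explicit subset: keep given order, no re-ranking
        res = _evaluate_fixed_order(fm, cfg, np.arange(len(channels)))
        return res
    if k is None:
        k = fm.X.shape[1]
    return _evaluate(fm, [k], cfg, scores=scores)[k]


def _evaluate_fixed_order(fm: FeatureMatrix, cfg: CVConfig, order: np.ndarray) -> EvalResult:
    X, y = fm.X, fm.label
    _check_stratifiable(y, cfg)
    k = len(order)
    n_rep = cfg.n_repetitions
    conf = np.zeros((n_rep, 4), dtype=int)
    for rep, rep_seed in enumerate(_rep_seeds(cfg, n_rep)):
        folds = _partition(y, cfg, rep_seed)
        conf[rep] = _run_repetition(X, y, folds, [k], cfg, order)[k]
    sens = np.empty(n_rep)
    spec = np.empty(n_rep)
    for r in range(n_rep):
        sens[r], spec[r] = compute_sens_spec(*conf[r])
    return EvalResult(k=k, sensitivity=sens, specificity=spec, confusion=conf)


def incremental_subset_eval(
    fm: FeatureMatrix,
    cfg: CVConfig,
    scores: PriorityScores | None = None,
) -> dict[int, EvalResult]:
    """Evaluate increasingly large top-ranked channel subsets.

    One :class:`EvalResult` per k in ``cfg.k_range``. Fold partitions are
    shared across k within a repetition, so per-k metric curves are
    paired samples.
    """
    ks = sorted(set(cfg.k_range))
    return _evaluate(fm, ks, cfg, scores=scores)


def summary_table(results: Mapping[int, EvalResult]) -> pd.DataFrame:
    """Median +- SD table over repetitions, one row per subset size."""
    rows = []
    for k in sorted(results):
        r = results[k]
        rows.append(
            {
                "n_features": k,
                "sensitivity_median": np.median(r.sensitivity),
                "sensitivity_sd": np.std(r.sensitivity, ddof=1),
                "specificity_median": np.median(r.specificity),
                "specificity_sd": np.std(r.specificity, ddof=1),
            }
        )
    return pd.DataFrame(rows)


def results_long_table(results: Mapping[int, EvalResult]) -> pd.DataFrame:
    """Long-format per-repetition metrics (k, repetition, sensitivity, specificity)."""
    rows = []
    for k in sorted(results):
        r = results[k]
        for rep in range(len(r.sensitivity)):
            rows.append(
                {
                    "k": k,
                    "repetition": rep,
                    "sensitivity": r.sensitivity[rep],
                    "specificity": r.specificity[rep],
                }
            )
    return pd.DataFrame(rows)
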