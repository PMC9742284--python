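"""Activation features, feature-matrix assembly, labels, standardization.

"Activation" here means the standard deviation of the oxyhemoglobin
concentration change in a 10-s window: a larger hemodynamic response
inflates the within-window SD while the window mean stays near zero.
Per-channel activations are averaged over the retained (non-artifact)
windows of the session to give one feature per channel per subject.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, HemoSeries, SubjectMeta, WindowTable
from .preprocess import window_sds

__all__ = [
    "windowed_activation",
    "session_features",
    "build_feature_matrix",
    "median_split_labels",
    "standardize",
    "FeatureMatrix",
]


def windowed_activation(
    series: HemoSeries,
    mask: WindowTable,
    source: str = "hbo",
) -> dict[int, np.ndarray]:
    """Per-channel window SDs of the oxyhemoglobin signal, retained windows only.

    The SD is recomputed in the mask's windows (sample SD, n-1
    denominator) and entries flagged as outliers are dropped. By default
    only the oxyhemoglobin series is used; ``source="hbr"`` switches to
    deoxyhemoglobin.

    Returns
    -------
    dict mapping channel id -> 1-D array of retained window SDs (mM).
    Channels whose windows are all excluded are omitted, with a warning.
    """
    if source not in ("hbo", "hbr"):
        raise ValueError("source must be 'hbo' or 'hbr'")
    x = series.hbo if source == "hbo" else series.hbr
    if not np.array_equal(series.channel_ids, mask.channel_ids):
        raise ValueError("mask channel ids do not match the series")
    sds = window_sds(x, mask.window_samples)
    if sds.shape[1] != mask.n_windows:
        raise ValueError("mask was not computed from a series of this length")
    out: dict[int, np.ndarray] = {}
    dropped = []
    for i, cid in enumerate(series.channel_ids):
        keep = ~mask.is_outlier[i]
        if not np.any(keep):
            dropped.append(int(cid))
            continue
        out[int(cid)] = sds[i, keep]
    if dropped:
        warnings.warn(f"all windows excluded for channel(s) {dropped}; marked missing", stacklevel=2)
    return out


def session_features(activations: Mapping[int, np.ndarray]) -> dict[int, float]:
    """Session-averaged activation: mean of the retained window SDs per channel."""
    return {cid: float(np.mean(v)) for cid, v in activations.items()}


def median_split_labels(
    scores: Mapping[str, float] | pd.Series,
    tie_rule: str = "strict_greater",
) -> tuple[pd.Series, float]:
    """Dichotomize scores at their median into high (1) / low (0) groups.

    Parameters
    ----------
    scores : mapping of subject id -> score
        Missing (NaN) scores are dropped.
    tie_rule : {"strict_greater", "greater_equal"}
        Whether a score exactly at the median counts as high. The strict
        rule is the default; published split sizes with ties are only
        reproducible under one rule or the other, so it is configurable.

    Returns
    -------
    (labels, cutoff)
        ``labels`` is a Series of 0/1 indexed by the retained subject
        ids; ``cutoff`` is the median used.

    Raises
    ------
    ValueError
        Fewer than 4 non-missing scores, all scores equal, or one side
        of the split empty.
    """
    s = pd.Series(scores, dtype=float).dropna()
    if len(s) < 4:
        raise ValueError(f"need at least 4 non-missing scores, got {len(s)}")
    if s.nunique() == 1:
        raise ValueError("all scores equal; median split undefined")
    cutoff = float(s.median())
    if tie_rule == "strict_greater":
        labels = (s > cutoff).astype(int)
    elif tie_rule == "greater_equal":
        labels = (s >= cutoff).astype(int)
    else:
        raise ValueError("tie_rule must be 'strict_greater' or 'greater_equal'")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("median split left one class empty; adjust tie_rule")
    return labels, cutoff


def build_feature_matrix(
    activations: Mapping[str, Mapping[int, np.ndarray]],
    metas: Sequence[SubjectMeta],
    label: str = "group",
    tie_rule: str = "strict_greater",
    missing: str = "error",
) -> FeatureMatrix:
    """Assemble the subjects x channels feature matrix with a binary label.

    Entry (s, c) is the mean of subject s's retained window SDs in
    channel c. Rows are aligned to ``metas`` order (restricted to the
    labeled subjects).

    Parameters
    ----------
    activations : mapping subject id -> (mapping channel id -> window SDs)
    label : str
        ``"group"`` labels patients 1 and controls 0. Any other value is
        taken as a neuropsychological test name: only patients with that
        score are retained and labeled by median split (1 = high scorer).
    missing : {"error", "impute"}
        Policy for channels absent in some subject: strict error
        (default), or column-median imputation.

    Raises
    ------
    ValueError
        Fewer than 2 subjects per class, or a missing channel in strict
        mode.
    """
    meta_by_id = {m.subject_id: m for m in metas}
    if label == "group":
        labeled = {
            m.subject_id: (1 if m.group == "patient" else 0)
            for m in metas
            if m.subject_id in activations
        }
        label_definition = {"target": "group", "positive": "patient"}
    else:
        scores = {
            m.subject_id: m.test_scores.get(label, np.nan)
            for m in metas
            if m.group == "patient" and m.subject_id in activations
        }
        lab_series, cutoff = median_split_labels(scores, tie_rule=tie_rule)
        labeled = {sid: int(v) for sid, v in lab_series.items()}
        label_definition = {
            "target": label,
            "positive": "high_scorer",
            "cutoff": cutoff,
            "tie_rule": tie_rule,
        }

    subject_ids = [m.subject_id for m in metas if m.subject_id in labeled]
    if len(subject_ids) < 4:
        raise ValueError(f"only {len(subject_ids)} labeled subjects; need at least 2 per class")

    rows = [session_features(activations[sid]) for sid in subject_ids]
    df = pd.DataFrame(rows, index=subject_ids)
    df = df[sorted(df.columns)]
    if df.isna().any().any():
        missing_map = {
            sid: [int(c) for c in df.columns[df.loc[sid].isna()]]
            for sid in df.index[df.isna().any(axis=1)]
        }
        if missing == "error":
            raise ValueError(f"missing channels per subject: {missing_map}")
        elif missing == "impute":
            warnings.warn(f"imputing column medians for missing channels: {missing_map}", stacklevel=2)
            df = df.fillna(df.median())
        else:
            raise ValueError("missing must be 'error' or 'impute'")
    y = np.array([labeled[sid] for sid in subject_ids], dtype=int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    df.columns = df.columns.astype(int)
    return FeatureMatrix(values=df, label=y, label_definition=label_definition)


def standardize(
    train: FeatureMatrix,
    apply_to: FeatureMatrix | None = None,
) -> FeatureMatrix:
    """Column-wise z-scoring with the training matrix's statistics.

    Centers and scales every column by the mean and sample SD computed on
    ``train`` only, and applies those statistics to ``apply_to``
    (defaults to ``train`` itself) — the transform never sees test rows.

    Raises
    ------
    ValueError
        If a training column has zero SD (names the channel).
    """
    mu = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero) > 0:
        raise ValueError(f"zero-SD training column(s) for channel(s) {list(zero.index)}")
    target = apply_to if apply_to is not None else train
    if list(target.values.columns) != list(train.values.columns):
        raise ValueError("apply_to must have the same channel columns as train")
    z = (target.values - mu) / sd
    return FeatureMatrix(
        values=z,
        label=target.label.copy(),
        label_definition=dict(target.label_definition),
    )


def standardize_arrays(
    train_X: np.ndarray, apply_X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Array-level z-scoring used inside cross-validation folds.

    Statistics come from ``train_X`` only; zero-SD columns are scaled by
    1 (they carry no information and would otherwise divide by zero on
    tiny training folds).
    """
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (train_X - mu) / sd, (apply_X - mu) / sd
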