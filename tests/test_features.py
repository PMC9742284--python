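"""Windowed activation, feature-matrix assembly, labels, standardization."""

import numpy as np
import pandas as pd
import pytest

from fnirscreen import (
    FeatureMatrix,
    build_feature_matrix,
    detect_artifact_windows,
    median_split_labels,
    standardize,
    windowed_activation,
)
from fnirscreen.containers import SubjectMeta, WindowTable
from fnirscreen.features import session_features
from helpers import FS, W, make_series


def series_from_window_sds(sds_by_channel):
    base = np.sin(2 * np.pi * np.arange(W) / W)
    base = (base - base.mean()) / base.std(ddof=1)
    rows = [np.concatenate([s * base for s in sds]) for sds in sds_by_channel]
    return make_series(np.vstack(rows))


def manual_table(series, outlier_cols):
    n_ch = series.hbo.shape[0]
    n_w = series.hbo.shape[1] // W
    mask = np.zeros((n_ch, n_w), dtype=bool)
    for ch, col in outlier_cols:
        mask[ch, col] = True
    return WindowTable(
        channel_ids=series.channel_ids,
        window_s=10.0,
        window_samples=W,
        sds=np.zeros((n_ch, n_w)),
        medians=np.zeros(n_ch),
        mads=np.zeros(n_ch),
        is_outlier=mask,
    )


class TestWindowedActivation:
    def test_constant_signal_zero_activation(self):
        series = make_series(np.full((2, 5 * W), 1.3))
        table = manual_table(series, [])
        act = windowed_activation(series, table)
        assert all(np.all(v == 0) for v in act.values())

    def test_full_cycle_sinusoid_sd(self):
        """0.1 Hz unit sinusoid, one cycle per 10-s window: SD ~ 1/sqrt(2)."""
        t = np.arange(6 * W) / FS
        series = make_series(np.sin(2 * np.pi * 0.1 * t)[None, :])
        act = windowed_activation(series, manual_table(series, []))
        assert act[1] == pytest.approx(np.full(6, 0.7071), abs=0.02)

    def test_mask_removes_exactly_one_entry(self):
        series = series_from_window_sds([[1.0, 1.1, 0.9, 10.0, 1.05, 0.95]])
        table = detect_artifact_windows(series)
        assert np.flatnonzero(table.is_outlier[0]).tolist() == [3]
        act = windowed_activation(series, table)
        assert len(act[1]) == 5

    def test_all_windows_excluded_channel_missing(self):
        series = series_from_window_sds([[1.0, 2.0, 3.0], [1.0, 1.0, 1.0]])
        table = manual_table(series, [(0, 0), (0, 1), (0, 2)])
        with pytest.warns(UserWarning, match="all windows excluded"):
            act = windowed_activation(series, table)
        assert 1 not in act and 2 in act

    def test_masked_artifact_window_never_changes_feature(self):
        """Injecting an artifact into a window that gets masked leaves the
        session feature identical to the clean series without that window."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal(12 * W)
        clean_sds = np.std(x[: 12 * W].reshape(12, W), axis=1, ddof=1)
        x_artifact = x.copy()
        x_artifact[5 * W : 6 * W] += 40.0 * np.sign(np.sin(np.arange(W)))
        series = make_series(x_artifact[None, :])
        table = detect_artifact_windows(series)
        assert table.is_outlier[0, 5]
        feat = session_features(windowed_activation(series, table))[1]
        expected = np.delete(clean_sds, np.flatnonzero(table.is_outlier[0])).mean()
        assert feat == pytest.approx(expected, rel=1e-12)

    def test_time_reversal_invariance(self):
        """Reversing the series whole-windows leaves session features unchanged."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal((2, 8 * W))
        fwd = make_series(x)
        rev = make_series(x[:, ::-1].copy())
        f1 = session_features(windowed_activation(fwd, detect_artifact_windows(fwd)))
        f2 = session_features(windowed_activation(rev, detect_artifact_windows(rev)))
        for c in f1:
            assert f1[c] == pytest.approx(f2[c], rel=1e-9)


class TestBuildFeatureMatrix:
    def _activations(self, values_by_subject):
        return {
            sid: {c: np.asarray(v, dtype=float) for c, v in chans.items()}
            for sid, chans in values_by_subject.items()
        }

    def _metas(self, n_pat=2, n_ctl=2, scores=None):
        metas = [
            SubjectMeta(f"P{i}", "patient", (scores or {}).get(f"P{i}", {}))
            for i in range(n_pat)
        ]
        metas += [SubjectMeta(f"C{i}", "control") for i in range(n_ctl)]
        return metas

    def test_singleton_and_mean_of_retained(self):
        acts = self._activations(
            {
                "P0": {1: [5.0]},  # singleton -> feature 5.0
                "P1": {1: [1.0, 3.0]},  # middle window masked out of {1,2,3}
                "C0": {1: [2.0, 2.0]},
                "C1": {1: [4.0]},
            }
        )
        fm = build_feature_matrix(acts, self._metas())
        assert fm.values.loc["P0", 1] == 5.0
        assert fm.values.loc["P1", 1] == 2.0
        assert fm.label.tolist() == [1, 1, 0, 0]

    def test_missing_channel_strict_error_and_imputation(self):
        acts = self._activations(
            {
                "P0": {1: [1.0], 2: [1.0]},
                "P1": {1: [2.0]},  # channel 2 missing
                "C0": {1: [3.0], 2: [3.0]},
                "C1": {1: [4.0], 2: [5.0]},
            }
        )
        with pytest.raises(ValueError, match="missing channels"):
            build_feature_matrix(acts, self._metas())
        with pytest.warns(UserWarning, match="imputing"):
            fm = build_feature_matrix(acts, self._metas(), missing="impute")
        assert fm.values.loc["P1", 2] == 3.0  # column median of {1, 3, 5}

    def test_row_label_alignment_under_permutation(self):
        acts = self._activations(
            {f"S{i}": {1: [float(i)], 2: [float(10 - i)]} for i in range(6)}
        )
        metas = [SubjectMeta(f"S{i}", "patient" if i % 2 else "control") for i in range(6)]
        fm1 = build_feature_matrix(acts, metas)
        fm2 = build_feature_matrix(acts, metas[::-1])
        assert fm2.subject_ids == fm1.subject_ids[::-1]
        fingerprint1 = {s: (fm1.values.loc[s, 1], int(l)) for s, l in zip(fm1.subject_ids, fm1.label)}
        fingerprint2 = {s: (fm2.values.loc[s, 1], int(l)) for s, l in zip(fm2.subject_ids, fm2.label)}
        assert fingerprint1 == fingerprint2

    def test_strong_effect_reduces_patient_features(self, cohort_effect3, fm_effect3):
        params, _, _ = cohort_effect3
        y = fm_effect3.label
        for c in params.informative_channels:
            col = fm_effect3.values[c].to_numpy()
            assert col[y == 1].mean() < col[y == 0].mean()

    def test_median_split_target(self):
        scores = {f"P{i}": {"BNT": float(i)} for i in range(6)}
        acts = self._activations({f"P{i}": {1: [float(i)]} for i in range(6)})
        metas = [SubjectMeta(f"P{i}", "patient", scores[f"P{i}"]) for i in range(6)]
        fm = build_feature_matrix(acts, metas, label="BNT")
        # median 2.5; strict > rule: P3..P5 high
        assert fm.label.tolist() == [0, 0, 0, 1, 1, 1]
        assert fm.label_definition["cutoff"] == 2.5


class TestMedianSplit:
    def test_odd_count_strict_rule(self):
        labels, cutoff = median_split_labels({f"s{i}": i for i in range(1, 16)})
        assert cutoff == 8.0
        assert int(labels.sum()) == 7 and int((1 - labels).sum()) == 8

    def test_even_count(self):
        labels, cutoff = median_split_labels({f"s{i}": i for i in range(1, 17)})
        assert cutoff == 8.5
        assert int(labels.sum()) == 8 and int((1 - labels).sum()) == 8

    def test_tie_rules_differ_on_tied_scores(self):
        scores = {"a": 1.0, "b": 2.0, "c": 2.0, "d": 3.0, "e": 4.0}
        strict, _ = median_split_labels(scores, tie_rule="strict_greater")
        ge, _ = median_split_labels(scores, tie_rule="greater_equal")
        assert int(strict.sum()) == 2  # d, e
        assert int(ge.sum()) == 4  # b, c, d, e

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            median_split_labels({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="undefined"):
            median_split_labels({c: 5.0 for c in "abcd"})
        with pytest.raises(ValueError, match="empty"):
            # strict > leaves the high class empty
            median_split_labels({"a": 1.0, "b": 2.0, "c": 2.0, "d": 2.0, "e": 2.0})


class TestStandardize:
    def _fm(self, X, labels=None):
        n = X.shape[0]
        labels = labels if labels is not None else np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
        return FeatureMatrix(
            values=pd.DataFrame(X, index=[f"s{i}" for i in range(n)], columns=range(1, X.shape[1] + 1)),
            label=labels,
        )

    def test_self_transform_zero_mean_unit_sd(self):
        rng = np.random.default_rng(8)
        fm = self._fm(rng.standard_normal((12, 5)) * 3 + 7)
        z = standardize(fm)
        assert np.allclose(z.values.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(z.values.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_row_at_train_means_maps_to_zero(self):
        rng = np.random.default_rng(9)
        train = self._fm(rng.standard_normal((10, 4)))
        row = train.values.mean(axis=0).to_numpy()[None, :]
        test = self._fm(np.vstack([row, row + 1]), labels=np.array([1, 0]))
        z = standardize(train, apply_to=test)
        assert np.allclose(z.values.iloc[0].to_numpy(), 0, atol=1e-12)

    def test_constant_column_rejected_naming_channel(self):
        X = np.random.default_rng(10).standard_normal((8, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="2"):
            standardize(self._fm(X))
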