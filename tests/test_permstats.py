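"""Permutation nulls and signed-rank significance testing."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.stats import rankdata

from fnirscreen import (
    CVConfig,
    compare_to_null,
    crossval_classify,
    incremental_subset_eval,
    permutation_null,
    signed_rank_p,
)
from fnirscreen.classify_eval import EvalResult


def brute_force_signed_rank(d):
    """Exact two-sided signed-rank p by full enumeration of sign vectors."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    r = rankdata(np.abs(d))
    w = r[d > 0].sum()
    dist = np.array(
        [sum(rr for rr, s in zip(r, signs) if s) for signs in itertools.product([0, 1], repeat=d.size)]
    )
    p_ge = np.mean(dist >= w - 1e-9)
    p_le = np.mean(dist <= w + 1e-9)
    return min(1.0, 2.0 * min(p_ge, p_le))


class TestSignedRank:
    def test_all_zero_differences_give_p_one(self):
        assert signed_rank_p(np.zeros(10)) == 1.0

    def test_twenty_all_positive_pairs_match_exact_enumeration(self):
        """Constant +0.3 shift over 20 pairs: p = 2 * 2^-20 = 2^-19."""
        p = signed_rank_p(np.full(20, 0.3))
        assert p == pytest.approx(2.0**-19, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.standard_normal(11), 2)  # rounding induces ties
        assert signed_rank_p(d) == pytest.approx(brute_force_signed_rank(d), rel=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        d = rng.standard_normal(15)
        ours = signed_rank_p(d)
        ref = stats.wilcoxon(d, method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(8)
        d = rng.standard_normal(60) + 0.3
        ours = signed_rank_p(d)
        ref = stats.wilcoxon(d, method="approx", correction=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


def _fake_results(values_by_k, metric_pairs=None):
    out = {}
    for k, vals in values_by_k.items():
        vals = np.asarray(vals, dtype=float)
        out[k] = EvalResult(
            k=k,
            sensitivity=vals,
            specificity=vals if metric_pairs is None else np.asarray(metric_pairs[k]),
            confusion=np.zeros((len(vals), 4), dtype=int),
        )
    return out


class TestCompareToNull:
    def _null(self, values_by_k):
        from fnirscreen.permstats import NullDistribution

        return NullDistribution(results=_fake_results(values_by_k), n_permutations=0, seed=0)

    def test_identical_distributions_not_significant(self):
        vals = {4: np.linspace(0.4, 0.6, 20)}
        report = compare_to_null(_fake_results(vals), self._null(vals))
        assert (report.table["p_raw"] == 1.0).all()
        assert not report.table["significant"].any()

    def test_constant_shift_detected_with_exact_p(self):
        base = {4: np.linspace(0.4, 0.6, 20)}
        shifted = {4: np.linspace(0.4, 0.6, 20) + 0.3}
        report = compare_to_null(_fake_results(shifted), self._null(base))
        assert report.table["p_raw"].to_numpy() == pytest.approx(2.0**-19, rel=1e-9)

    def test_bonferroni_multiplication_and_cap(self):
        # raw p of 2^-19 times a huge factor caps at 1
        base = {4: np.linspace(0.4, 0.6, 20)}
        shifted = {4: np.linspace(0.4, 0.6, 20) + 0.3}
        report = compare_to_null(
            _fake_results(shifted), self._null(base), n_comparisons=10**7
        )
        raw = report.table["p_raw"].iloc[0]
        assert report.table["p_corrected"].iloc[0] == min(1.0, raw * 10**7)
        # and the default factor is |k_range| x 2 metrics
        rep2 = compare_to_null(_fake_results(shifted), self._null(base))
        assert rep2.n_comparisons == 2
        assert rep2.table["p_corrected"].iloc[0] == pytest.approx(raw * 2)

    def test_unequal_repetition_counts_rejected_in_paired_mode(self):
        a = _fake_results({4: np.linspace(0.4, 0.6, 20)})
        b = self._null({4: np.linspace(0.4, 0.6, 10)})
        with pytest.raises(ValueError, match="equal repetition counts"):
            compare_to_null(a, b)
        # the KS variant accepts unequal sizes
        report = compare_to_null(a, b, test="ks")
        assert len(report.table) == 2


class TestPermutationNull:
    def test_reshuffles_preserve_class_counts(self, make_gaussian_fm):
        fm = make_gaussian_fm(seed=20, n_pos=21, n_neg=18, shift=2.0, shift_channels=(1,))
        cfg = CVConfig(n_repetitions=1, k_range=(2,), seed=21)
        null = permutation_null(fm, cfg, n_permutations=6)
        conf = null.results[2].confusion
        assert np.all(conf[:, 0] + conf[:, 1] == 21)  # tp + fn = patients
        assert np.all(conf[:, 2] + conf[:, 3] == 18)  # tn + fp = controls

    def test_null_accuracy_near_chance(self, make_gaussian_fm):
        fm = make_gaussian_fm(seed=22, shift=3.0, shift_channels=(1, 2))
        cfg = CVConfig(n_repetitions=1, k_range=(2,), seed=23)
        null = permutation_null(fm, cfg, n_permutations=20)
        med = np.median(null.results[2].accuracy)
        se = np.sqrt(0.25 / 40)
        assert abs(med - 0.5) <= 3 * se

    def test_separated_cohort_actual_beats_unmoved_null(self, make_gaussian_fm):
        """Strong class separation: actual ~ 1.0 while the null stays ~ 0.5."""
        fm = make_gaussian_fm(seed=24, shift=8.0, shift_channels=(1, 2))
        cfg = CVConfig(n_repetitions=20, k_range=(2,), seed=25)
        actual = incremental_subset_eval(fm, cfg)
        null = permutation_null(fm, cfg, n_permutations=20)
        assert np.median(actual[2].accuracy) == 1.0
        assert abs(np.median(null.results[2].accuracy) - 0.5) <= 3 * np.sqrt(0.25 / 40)
        report = compare_to_null(actual, null)
        assert report.table["significant"].all()

    def test_deterministic_given_seed(self, make_gaussian_fm):
        fm = make_gaussian_fm(seed=26, shift=1.0, shift_channels=(1,))
        cfg = CVConfig(n_repetitions=1, k_range=(2, 4), seed=27)
        n1 = permutation_null(fm, cfg, n_permutations=5)
        n2 = permutation_null(fm, cfg, n_permutations=5)
        for k in (2, 4):
            assert np.array_equal(n1.results[k].confusion, n2.results[k].confusion)
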