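import numpy as np
import pandas as pd
import pytest

from fnirscreen import (
    CVConfig,
    FeatureMatrix,
    SynthParams,
    generate_cohort,
    generate_layout,
)
from fnirscreen.pipeline import RunConfig, extract_features


@pytest.fixture(scope="session")
def layout():
    return generate_layout(0)


@pytest.fixture(scope="session")
def cohort_effect3(layout):
    """Full-length synthetic cohort with a strong (3x) group effect in 4 channels."""
    params = SynthParams(duration=300.0, seed=11, effect_size=3.0)
    recordings, metas = generate_cohort(params, layout=layout)
    return params, recordings, metas


@pytest.fixture(scope="session")
def fm_effect3(cohort_effect3):
    """Feature matrix built from the strong-effect cohort."""
    params, recordings, metas = cohort_effect3
    fm, _, _ = extract_features(RunConfig(), recordings, metas)
    return fm


@pytest.fixture
def make_gaussian_fm():
    """Factory for feature matrices with Gaussian features and a class shift."""

    def _make(
        seed: int = 0,
        n_pos: int = 20,
        n_neg: int = 20,
        n_channels: int = 8,
        shift: float = 0.0,
        shift_channels: tuple[int, ...] = (),
    ) -> FeatureMatrix:
        rng = np.random.default_rng(seed)
        n = n_pos + n_neg
        y = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
        X = rng.standard_normal((n, n_channels))
        for c in shift_channels:
            X[y == 1, c - 1] += shift
        values = pd.DataFrame(
            X, index=[f"S{i:03d}" for i in range(n)], columns=range(1, n_channels + 1)
        )
        return FeatureMatrix(values=values, label=y, label_definition={"target": "synthetic"})

    return _make


@pytest.fixture
def small_cv():
    return CVConfig(n_folds=5, n_repetitions=10, k_range=(2, 4), seed=7)
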