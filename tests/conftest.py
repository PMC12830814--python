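import numpy as np
import pandas as pd
import pytest

from metaprs import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 300 x 200 cohort with missingness, ambiguous variants, file
    orientation churn, and a real disease signal."""
    config = SimConfig(
        n_individuals=300,
        n_variants=200,
        seed=42,
        missing_rate=0.02,
        ambiguous_fraction=0.05,
        swap_fraction=0.2,
        flip_fraction=0.1,
        trait_effects=(0.6, 0.1, 0, 0, 0, 0, 0.2, -0.1, 0.1),
        covariate_effects={"age": 0.02, "bmi": 0.05},
    )
    return simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def mann_whitney_auc(scores, y):
    """Independent rank-free AUC oracle: all-pairs counting."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for a in pos:
        wins += np.sum(a > neg) + 0.5 * np.sum(a == neg)
    return wins / (len(pos) * len(neg))
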