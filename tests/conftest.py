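import itertools

import numpy as np
import pytest

from driverscan import FeatureMatrix, ks_skewness_score


def quality_key(score):
    """Ordering equivalent to (p-value ascending, statistic descending) for
    KS scores: larger (m*D+^2, D+) is better."""
    return (score.n_events * score.statistic**2, score.statistic)


def exhaustive_best_ks(fm: FeatureMatrix, max_size: int):
    """Independent oracle: enumerate every feature subset up to max_size and
    score its union; return (best subset, best score)."""
    best = None
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(range(fm.n_features), size):
            union = fm.values[list(combo)].max(axis=0)
            ranks = np.flatnonzero(union) + 1
            if ranks.size == 0:
                continue
            s = ks_skewness_score(ranks, fm.n_samples)
            if best is None or quality_key(s) > quality_key(best[1]):
                best = (combo, s)
    return best


def random_binary_matrix(seed: int, n_features: int = 15, n_samples: int = 40):
    """Random sparse binary matrix with no all-zero rows (seeded)."""
    rng = np.random.default_rng(seed)
    while True:
        X = (
            rng.random((n_features, n_samples))
            < rng.uniform(0.05, 0.3, (n_features, 1))
        ).astype(np.uint8)
        if not (X.sum(axis=1) == 0).any():
            return FeatureMatrix(
                X,
                [f"f{i}" for i in range(n_features)],
                [f"s{j}" for j in range(n_samples)],
            )


@pytest.fixture
def small_matrix() -> FeatureMatrix:
    """3 features x 4 samples, hand-written."""
    values = np.array(
        [
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [1, 0, 1, 0],
        ],
        dtype=np.uint8,
    )
    return FeatureMatrix(values, ["fA", "fB", "fC"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def planted_matrix() -> tuple[FeatureMatrix, list[str]]:
    """3 mutually exclusive true features covering ranks 1-30 of N=60 plus 5
    scattered null features; returns (matrix, true feature ids)."""
    rng = np.random.default_rng(7)
    N = 60
    X = np.zeros((8, N), dtype=np.uint8)
    blocks = np.array_split(rng.permutation(30), 3)
    for i, b in enumerate(blocks):
        X[i, b] = 1
    for i in range(3, 8):
        X[i, rng.choice(N, size=10, replace=False)] = 1
    ids = [f"true_{i}" for i in range(3)] + [f"noise_{i}" for i in range(5)]
    return FeatureMatrix(X, ids, [f"s{j:02d}" for j in range(N)]), ids[:3]
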