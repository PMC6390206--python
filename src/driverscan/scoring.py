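"""Left-skewness scores for binary features over a ranked sample list.

A feature's events (1's) occupy a set of ranks r_1 < ... < r_m within the
N ranked samples.  The score measures how strongly those ranks concentrate
at the top (left) of the ranking.  Two scores are provided:

* ``ks`` (default) — a one-sided, one-sample Kolmogorov-Smirnov statistic,
      D+ = max_i ( i/m - (r_i - 1)/N ),
  the maximal excess of the empirical CDF of event ranks over the uniform
  reference on 1..N, with the asymptotic one-sided tail bound
  p = exp(-2 m D+^2).
* ``wilcoxon`` — the rank-sum of event positions, standardised with a
  normal approximation (continuity corrected), one-sided against the
  alternative that events occupy smaller ranks.

Scores from unions with different event counts are compared by p-value
first (comparable across m), then by statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import FeatureMatrix

__all__ = [
    "SkewnessScore",
    "ks_skewness_score",
    "wilcoxon_skewness_score",
    "score_union",
    "is_improvement",
]

_METHODS = ("ks", "wilcoxon")


@dataclass(frozen=True)
class SkewnessScore:
    """A left-skewness score for one (meta-)feature.

    ``statistic`` is D+ in [0, 1] for ``ks``, or the standardised rank-sum
    deviation (positive = left-skewed) for ``wilcoxon``.  Larger statistics
    and smaller p-values indicate stronger left-skew.
    """

    method: str
    statistic: float
    p_value: float
    n_events: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")
        if self.method == "ks" and not (0.0 <= self.statistic <= 1.0):
            raise ValueError(f"KS statistic must lie in [0, 1], got {self.statistic}")
        if not (1 <= self.n_events <= self.n_samples):
            raise ValueError("require 1 <= n_events <= n_samples")


def _check_ranks(event_ranks: np.ndarray, n_samples: int) -> np.ndarray:
    ranks = np.asarray(event_ranks, dtype=np.int64)
    if ranks.size == 0:
        raise ValueError("unscorable feature: no events")
    if ranks.min() < 1 or ranks.max() > n_samples:
        raise ValueError(f"ranks must lie in 1..{n_samples}")
    if np.unique(ranks).size != ranks.size:
        raise ValueError("ranks must be distinct")
    return np.sort(ranks)


def ks_skewness_score(event_ranks, n_samples: int) -> SkewnessScore:
    """One-sided KS left-skewness of the given event ranks.

    D+ = max_i ( i/m - (r_i - 1)/N ) over the sorted ranks, clipped to
    [0, 1]; p = exp(-2 m D+^2) clipped to (0, 1].  A single event at rank 1
    attains the maximum D+ = 1.
    """
    ranks = _check_ranks(event_ranks, n_samples)
    m = int(ranks.size)
    i = np.arange(1, m + 1, dtype=np.int64)
    # integer-exact numerator: max_i (N*i - m*(r_i - 1)), then one division
    max_a = int(np.max(n_samples * i - m * (ranks - 1)))
    d = float(max_a) / (m * n_samples)
    d = min(max(d, 0.0), 1.0)
    p = min(max(float(np.exp(-2.0 * m * d * d)), np.nextafter(0.0, 1.0)), 1.0)
    return SkewnessScore("ks", d, p, int(m), int(n_samples))


def wilcoxon_skewness_score(event_ranks, n_samples: int) -> SkewnessScore:
    """Rank-sum left-skewness with normal approximation.

    One-sided against "event ranks are smaller than non-event ranks".
    Ranks are a permutation of 1..N so no ties arise.  Requires both groups
    non-empty (1 <= m < N).
    """
    ranks = _check_ranks(event_ranks, n_samples)
    m = int(ranks.size)
    if m >= n_samples:
        raise ValueError("wilcoxon requires both groups non-empty (m < N)")
    w = float(ranks.sum())
    mu = m * (n_samples + 1) / 2.0
    sigma = np.sqrt(m * (n_samples - m) * (n_samples + 1) / 12.0)
    z = (w - mu + 0.5) / sigma
    p = min(max(float(stats.norm.cdf(z)), np.nextafter(0.0, 1.0)), 1.0)
    return SkewnessScore("wilcoxon", -float(z), p, m, int(n_samples))


def score_union(fm: FeatureMatrix, member_rows, method: str = "ks") -> SkewnessScore:
    """Score the logical OR of the given rows of a ranking-aligned matrix.

    Columns of ``fm`` must already be in ranking order (best first).
    """
    rows = sorted(set(int(r) for r in member_rows))
    if not rows:
        raise ValueError("member_rows is empty")
    union = fm.values[rows, :].max(axis=0)
    ranks = np.flatnonzero(union) + 1
    if ranks.size == 0:
        raise ValueError("union of member rows has no events")
    if method == "ks":
        return ks_skewness_score(ranks, fm.n_samples)
    if method == "wilcoxon":
        return wilcoxon_skewness_score(ranks, fm.n_samples)
    raise ValueError(f"unknown method {method!r}")


def is_improvement(candidate: SkewnessScore, incumbent: SkewnessScore) -> bool:
    """Strict ordering used by the greedy search: smaller p wins; on equal
    p-values the larger statistic wins; exact ties are not improvements."""
    if candidate.method != incumbent.method:
        raise ValueError(
            f"cannot compare scores of different methods "
            f"({candidate.method} vs {incumbent.method})"
        )
    if candidate.p_value != incumbent.p_value:
        return candidate.p_value < incumbent.p_value
    return candidate.statistic > incumbent.statistic


# ---------------------------------------------------------------------------
# Vectorised internals used by the search (one row per candidate union).
#
# Candidates are compared by a lexicographic quality key (key1, key2) where
# larger is strictly better and equality in both components means equal
# scores:
#   ks:       key1 = m * D+^2  (p = exp(-2*key1), monotone),  key2 = D+
#   wilcoxon: key1 = -z        (p = Phi(z), monotone),        key2 = -z
# Rows that cannot be scored carry key1 = -inf.


def _ks_keys(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (m*D+^2, D+) for a boolean (n, N) matrix in ranking order."""
    n, N = X.shape
    C = np.cumsum(X, axis=1, dtype=np.int64)
    m = C[:, -1]
    j = np.arange(N, dtype=np.int64)
    # D+ = max over event positions j (0-based) of (N*C_j - m*j) / (m*N)
    A = N * C - m[:, None] * j
    A = np.where(X, A, np.int64(np.iinfo(np.int64).min))
    maxA = A.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = maxA / (m * float(N))
    d0 = np.clip(raw, 0.0, 1.0)  # 0 where m == 0; masked below
    key1 = np.where(m > 0, m * d0 * d0, -np.inf)
    d = np.where(m > 0, d0, -np.inf)
    return key1, d


def _wilcoxon_keys(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (-z, -z) for a boolean (n, N) matrix in ranking order."""
    n, N = X.shape
    j = np.arange(1, N + 1, dtype=np.int64)
    m = X.sum(axis=1, dtype=np.int64)
    w = X @ j
    mu = m * (N + 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.sqrt(m * (N - m) * (N + 1) / 12.0)
        z = (w - mu + 0.5) / sigma
    key = np.where((m > 0) & (m < N), -z, -np.inf)
    return key, key


def _keys_for(X: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    if method == "ks":
        return _ks_keys(X)
    if method == "wilcoxon":
        return _wilcoxon_keys(X)
    raise ValueError(f"unknown method {method!r}")


def _score_from_keys(method: str, key1: float, key2: float, m: int, N: int) -> SkewnessScore:
    """Reconstruct a SkewnessScore from the internal quality key."""
    if method == "ks":
        p = min(max(float(np.exp(-2.0 * key1)), np.nextafter(0.0, 1.0)), 1.0)
        return SkewnessScore("ks", float(key2), p, m, N)
    p = min(max(float(stats.norm.cdf(-key1)), np.nextafter(0.0, 1.0)), 1.0)
    return SkewnessScore("wilcoxon", float(key2), p, m, N)
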