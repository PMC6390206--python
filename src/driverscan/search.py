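"""Stepwise greedy meta-feature search.

Starting from the best-scoring single feature (or a user-chosen seed), the
search repeatedly forms the logical OR of the incumbent meta-feature with
every remaining feature, accepts the best strictly improving union, and
stops when no addition improves the score or the size budget is exhausted.
A "top-N" modality restarts the greedy search from each of the N
best-scoring single features and keeps the best result, guarding against
the greedy search's local optima.

All candidate evaluation is vectorised over features; a full greedy step on
a 1000-feature matrix costs one boolean OR and one cumulative sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine
from .matrix import FeatureMatrix, SampleRanking, align
from .scoring import SkewnessScore, _keys_for, _score_from_keys, is_improvement

__all__ = [
    "SearchConfig",
    "MetaFeature",
    "TopNResult",
    "stepwise_search",
    "topn_search",
]


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of a greedy meta-feature search.

    ``start_mode`` is one of ``"best_single"`` (start from the top-scoring
    feature), ``"seeded"`` (start from ``seed_feature``), or ``"top_n"``
    (restart from each of the ``top_n`` best single features).
    """

    method: str = "ks"
    max_size: int = 7
    start_mode: str = "best_single"
    seed_feature: str | None = None
    top_n: int = 7

    def __post_init__(self) -> None:
        if self.method not in ("ks", "wilcoxon"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        if self.start_mode not in ("best_single", "seeded", "top_n"):
            raise ValueError(f"unknown start_mode {self.start_mode!r}")
        if self.start_mode == "seeded" and not self.seed_feature:
            raise ValueError("seeded start_mode requires seed_feature")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass(frozen=True)
class MetaFeature:
    """An ordered set of features whose union is the search result.

    ``member_feature_ids`` lists members in order of addition;
    ``step_scores`` holds the accepted score after each addition (strictly
    improving); ``final_score`` is the last of them.
    """

    member_feature_ids: tuple[str, ...]
    member_rows: tuple[int, ...]
    union_vector: np.ndarray
    step_scores: tuple[SkewnessScore, ...]

    @property
    def final_score(self) -> SkewnessScore:
        return self.step_scores[-1]

    @property
    def size(self) -> int:
        return len(self.member_feature_ids)

    def __post_init__(self) -> None:
        if len(self.member_feature_ids) != len(self.step_scores):
            raise ValueError("one step score per member is required")
        for earlier, later in zip(self.step_scores, self.step_scores[1:]):
            if not is_improvement(later, earlier):
                raise ValueError("step scores must be strictly improving")


@dataclass(frozen=True)
class TopNResult:
    """All runs of a top-N search plus the best one.

    ``overlap_matrix[i, j]`` counts members shared between run i and run j.
    """

    runs: tuple[tuple[str, MetaFeature], ...]
    best: MetaFeature
    overlap_matrix: np.ndarray


# ---------------------------------------------------------------------------
# Core greedy loop on a raw boolean matrix whose columns are in ranking
# order.  Internal quality keys: lexicographic (key1, key2), larger better.


def _single_feature_keys(X: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    return _keys_for(X, method)


def _best_candidate(
    key1: np.ndarray, key2: np.ndarray, exclude: np.ndarray
) -> int | None:
    """Lexicographic argmax over rows, lowest row index on ties; None if no
    scorable candidate remains."""
    k1 = np.where(exclude, -np.inf, key1)
    best1 = k1.max()
    if best1 == -np.inf:
        return None
    at = np.flatnonzero(k1 == best1)
    if at.size > 1:
        k2 = key2[at]
        at = at[k2 == k2.max()]
    return int(at[0])


def _greedy_core(
    X: np.ndarray, start_row: int, max_size: int, method: str
) -> tuple[list[int], list[tuple[float, float, int]]]:
    """Greedy expansion from ``start_row``.

    Returns member row indices in order of addition and the accepted
    (key1, key2, m) per step.  The KS path runs through the compiled
    kernel when available (bit-identical to the numpy path below).
    """
    if method == "ks" and _engine.HAVE_NUMBA:
        if not X[start_row].any():
            raise ValueError("start feature is unscorable (no events)")
        return _engine.greedy_ks(X, start_row, max_size)
    return _greedy_numpy(X, start_row, max_size, method)


def _greedy_numpy(
    X: np.ndarray, start_row: int, max_size: int, method: str
) -> tuple[list[int], list[tuple[float, float, int]]]:
    """Pure-numpy reference implementation of the greedy expansion."""
    n, N = X.shape
    members = [start_row]
    union = X[start_row].copy()
    k1, k2 = _keys_for(union[None, :], method)
    if k1[0] == -np.inf:
        raise ValueError("start feature is unscorable (no events)")
    inc = (float(k1[0]), float(k2[0]), int(union.sum()))
    steps = [inc]
    exclude = np.zeros(n, dtype=bool)
    exclude[start_row] = True
    while len(members) < max_size:
        Xor = X | union  # (n, N) candidate unions
        key1, key2 = _keys_for(Xor, method)
        # unions identical to the incumbent cannot improve; their equal
        # score is rejected by the strict comparison below
        best = _best_candidate(key1, key2, exclude)
        if best is None:
            break
        cand = (float(key1[best]), float(key2[best]))
        if not (cand[0] > inc[0] or (cand[0] == inc[0] and cand[1] > inc[1])):
            break
        union = Xor[best]
        inc = (cand[0], cand[1], int(union.sum()))
        members.append(best)
        steps.append(inc)
        exclude[best] = True
    return members, steps


def _run_value_search(
    X: np.ndarray, cfg: SearchConfig, seed_row: int | None = None
) -> tuple[list[int], list[tuple[float, float, int]]]:
    """Full search on a raw boolean matrix; used by the public API and by
    the permutation-null machinery (which needs no FeatureMatrix wrapper)."""
    key1, key2 = _single_feature_keys(X, cfg.method)
    scorable = key1 > -np.inf
    if not scorable.any():
        raise ValueError("no scorable features (every row is all-zero)")
    if cfg.start_mode == "seeded" or seed_row is not None:
        if seed_row is None:
            raise ValueError("seed row not resolved")
        if not scorable[seed_row]:
            raise ValueError("seed feature has no events and cannot be scored")
        return _greedy_core(X, seed_row, cfg.max_size, cfg.method)
    if cfg.start_mode == "top_n":
        raise ValueError("use topn_search for start_mode='top_n'")
    start = _best_candidate(key1, key2, ~scorable)
    return _greedy_core(X, start, cfg.max_size, cfg.method)


def _final_key(steps: list[tuple[float, float, int]]) -> tuple[float, float]:
    return (steps[-1][0], steps[-1][1])


def _as_meta_feature(
    fm: FeatureMatrix, members: list[int], steps: list[tuple[float, float, int]], method: str
) -> MetaFeature:
    union = fm.values[members, :].max(axis=0)
    scores = tuple(
        _score_from_keys(method, k1, k2, m, fm.n_samples) for (k1, k2, m) in steps
    )
    return MetaFeature(
        member_feature_ids=tuple(fm.feature_ids[i] for i in members),
        member_rows=tuple(members),
        union_vector=union,
        step_scores=scores,
    )


def _as_bool(fm: FeatureMatrix) -> np.ndarray:
    return fm.values.astype(bool)


def stepwise_search(fm: FeatureMatrix, cfg: SearchConfig | None = None) -> MetaFeature:
    """Run the greedy search on a ranking-aligned matrix.

    ``fm`` columns must already be in ranking order (best sample first); use
    :func:`driverscan.matrix.align` beforehand.  Ties among equally scoring
    candidates are broken by the lowest row index.
    """
    cfg = cfg or SearchConfig()
    X = _as_bool(fm)
    seed_row = None
    if cfg.start_mode == "seeded":
        try:
            seed_row = fm.feature_ids.index(cfg.seed_feature)
        except ValueError:
            raise ValueError(
                f"seed feature {cfg.seed_feature!r} not present in the matrix"
            ) from None
    members, steps = _run_value_search(X, cfg, seed_row)
    return _as_meta_feature(fm, members, steps, cfg.method)


def topn_search(fm: FeatureMatrix, cfg: SearchConfig | None = None) -> TopNResult:
    """Restart the greedy search from each of the N best single features.

    Starting features are the N top-scoring single features (same tie rule
    as the greedy step); the best run under the score ordering is reported
    alongside all runs and their pairwise member-overlap counts.
    """
    cfg = cfg or SearchConfig(start_mode="top_n")
    X = _as_bool(fm)
    key1, key2 = _single_feature_keys(X, cfg.method)
    scorable = np.flatnonzero(key1 > -np.inf)
    if cfg.top_n > scorable.size:
        raise ValueError(
            f"top_n={cfg.top_n} exceeds the {scorable.size} scorable feature(s)"
        )
    # rank rows by (key1, key2) descending, row index ascending
    order = sorted(
        scorable.tolist(), key=lambda i: (-key1[i], -key2[i], i)
    )
    starts = order[: cfg.top_n]
    runs: list[tuple[str, MetaFeature]] = []
    best_mf: MetaFeature | None = None
    best_key: tuple[float, float] | None = None
    for row in starts:
        members, steps = _greedy_core(X, row, cfg.max_size, cfg.method)
        mf = _as_meta_feature(fm, members, steps, cfg.method)
        runs.append((fm.feature_ids[row], mf))
        fk = _final_key(steps)
        if best_key is None or fk > best_key:
            best_key, best_mf = fk, mf
    k = len(runs)
    overlap = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        si = set(runs[i][1].member_feature_ids)
        for j in range(k):
            overlap[i, j] = len(si & set(runs[j][1].member_feature_ids))
    return TopNResult(runs=tuple(runs), best=best_mf, overlap_matrix=overlap)


def search_aligned(
    fm: FeatureMatrix, ranking: SampleRanking, cfg: SearchConfig | None = None
) -> MetaFeature | TopNResult:
    """Align ``fm`` to ``ranking`` then dispatch on the configured mode."""
    cfg = cfg or SearchConfig()
    fm2, _ = align(fm, ranking)
    if cfg.start_mode == "top_n":
        return topn_search(fm2, cfg)
    return stepwise_search(fm2, cfg)
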