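"""Synthetic benchmark datasets with known ground truth.

Two designs are generated over N ranked samples (columns already ordered
best to worst, so the implicit ranking is column order):

* **true-positive datasets** — p mutually exclusive left-skewed features
  whose union covers exactly the first f*N columns, plus n-p null
  features; and
* **null datasets** — n null features only.

Each null feature draws its event count from Poisson(lambda) with
lambda = f*N/p — matching the per-feature event count of the true
positives — and scatters the events uniformly over the N samples, so null
features are indistinguishable from true positives in marginal frequency
but carry no rank association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import FeatureMatrix, SampleRanking

__all__ = [
    "SimulationParams",
    "SimulatedDataset",
    "simulate_tp_dataset",
    "simulate_null_dataset",
]

TRUE_POSITIVE = "true_positive"
NULL = "null"


@dataclass(frozen=True)
class SimulationParams:
    """Generator parameters.

    N : samples; n : total features; p : true-positive features;
    f : left-skew proportion (the union of true positives covers the first
    f*N columns).  The Poisson mean for null event counts is derived:
    lambda = f*N/p.
    """

    N: int
    n: int = 1000
    p: int = 5
    f: float = 0.5

    def __post_init__(self) -> None:
        if self.N < 2 or self.n < 1 or self.p < 1:
            raise ValueError("N >= 2, n >= 1, p >= 1 required")
        if self.p > self.n:
            raise ValueError("p cannot exceed n")
        if not (0.0 < self.f <= 1.0):
            raise ValueError("f must lie in (0, 1]")
        if self.f * self.N < self.p:
            raise ValueError(
                f"f*N = {self.f * self.N:g} < p = {self.p}: "
                "cannot give every true-positive feature an event"
            )

    @property
    def lam(self) -> float:
        """Poisson mean for null-feature event counts: f*N/p."""
        return self.f * self.N / self.p

    @property
    def k_skewed(self) -> int:
        """Number of left-most columns covered by the true-positive union."""
        return int(round(self.f * self.N))


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated matrix with per-feature truth labels.

    Columns are in ranking order (best sample first); ``ranking`` exposes
    that implicit ordering as a :class:`SampleRanking`.
    """

    matrix: FeatureMatrix
    truth: tuple[str, ...]
    params: SimulationParams
    seed: int

    @property
    def ranking(self) -> SampleRanking:
        return SampleRanking.from_ordered(self.matrix.sample_ids)

    @property
    def true_positive_ids(self) -> set[str]:
        return {
            fid
            for fid, lab in zip(self.matrix.feature_ids, self.truth)
            if lab == TRUE_POSITIVE
        }


def _sample_ids(N: int) -> list[str]:
    width = len(str(N))
    return [f"s{j + 1:0{width}d}" for j in range(N)]


def _null_rows(rng: np.random.Generator, count: int, N: int, lam: float) -> np.ndarray:
    """Null features: Poisson(lam) event counts (redrawn into 1..N), events
    placed uniformly without replacement."""
    rows = np.zeros((count, N), dtype=np.uint8)
    for i in range(count):
        c = 0
        while not (1 <= c <= N):
            c = int(rng.poisson(lam))
        pos = rng.choice(N, size=c, replace=False)
        rows[i, pos] = 1
    return rows


def simulate_tp_dataset(params: SimulationParams, seed: int = 0) -> SimulatedDataset:
    """Generate a true-positive dataset.

    The first k = round(f*N) columns are partitioned uniformly at random
    into p mutually exclusive blocks (sizes floor(k/p) or ceil(k/p), the
    remainder spread over the first k mod p blocks); block i is the event
    set of true-positive feature i, so the union of the p features is
    exactly the indicator of columns 1..k.  The remaining n-p features are
    null features.  Rows are shuffled so truth is not encoded in row order.
    """
    rng = np.random.default_rng(seed)
    N, n, p = params.N, params.n, params.p
    k = params.k_skewed
    rows = np.zeros((n, N), dtype=np.uint8)
    positions = rng.permutation(k)
    base, rem = divmod(k, p)
    sizes = [base + 1 if i < rem else base for i in range(p)]
    offset = 0
    for i, size in enumerate(sizes):
        rows[i, positions[offset : offset + size]] = 1
        offset += size
    rows[p:] = _null_rows(rng, n - p, N, params.lam)
    ids = [f"tp_{i + 1}" for i in range(p)] + [f"null_{i + 1}" for i in range(n - p)]
    truth = [TRUE_POSITIVE] * p + [NULL] * (n - p)
    shuffle = rng.permutation(n)
    matrix = FeatureMatrix(rows[shuffle], [ids[i] for i in shuffle], _sample_ids(N))
    return SimulatedDataset(
        matrix=matrix,
        truth=tuple(truth[i] for i in shuffle),
        params=params,
        seed=seed,
    )


def simulate_null_dataset(params: SimulationParams, seed: int = 0) -> SimulatedDataset:
    """Generate a pure-null dataset of n null features."""
    rng = np.random.default_rng(seed)
    rows = _null_rows(rng, params.n, params.N, params.lam)
    ids = [f"null_{i + 1}" for i in range(params.n)]
    matrix = FeatureMatrix(rows, ids, _sample_ids(params.N))
    return SimulatedDataset(
        matrix=matrix, truth=tuple([NULL] * params.n), params=params, seed=seed
    )
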