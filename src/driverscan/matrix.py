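"""Binary alteration matrices and phenotype-induced sample rankings.

The search space is a features x samples matrix of 0/1 indicators (1 =
alteration present in that sample).  Samples are ordered by a continuous
per-sample measurement (pathway activity, drug sensitivity, protein level,
...), best first; the search then asks which union of features concentrates
its events among the highest-ranked samples.

This module handles I/O (TSV/CSV and the GCT 1.2 dialect), validation,
frequency pre-filtering, ranking construction, and alignment of a matrix to
a ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "SampleRanking",
    "FilterConfig",
    "read_feature_matrix",
    "write_feature_matrix",
    "prefilter_features",
    "rank_samples",
    "align",
]


class MatrixFormatError(ValueError):
    """Raised when an input file violates the binary-matrix contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class FilterConfig:
    """Alteration-frequency pre-filter bounds (inclusive).

    Features with event frequency below ``min_freq`` are too sparse to rank
    reliably; features above ``max_freq`` are near-ubiquitous and carry little
    discriminating signal.  Defaults follow the standard 3%-60% convention.
    """

    min_freq: float = 0.03
    max_freq: float = 0.60

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_freq < self.max_freq <= 1.0):
            raise ValueError(
                f"require 0 <= min_freq < max_freq <= 1, got "
                f"({self.min_freq}, {self.max_freq})"
            )


class FeatureMatrix:
    """Binary features x samples matrix with identifier bookkeeping.

    Parameters
    ----------
    values : array-like of shape (n_features, n_samples)
        Entries strictly in {0, 1}.
    feature_ids, sample_ids : sequences of unique strings
        Row and column labels.
    """

    def __init__(
        self,
        values: np.ndarray,
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> None:
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n_feat, n_samp = values.shape
        feature_ids = [str(x) for x in feature_ids]
        sample_ids = [str(x) for x in sample_ids]
        if len(feature_ids) != n_feat or len(sample_ids) != n_samp:
            raise ValueError("id lengths do not match matrix shape")
        if n_feat < 1:
            raise ValueError("matrix must contain at least one feature")
        if n_samp < 2:
            raise ValueError("matrix must contain at least two samples")
        _check_unique(feature_ids, "feature")
        _check_unique(sample_ids, "sample")
        if not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise MatrixFormatError(
                f"non-binary entry at feature {feature_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}: {values[tuple(bad)]!r}"
            )
        self.values = values.astype(np.uint8, copy=True)
        self.values.setflags(write=False)
        self.feature_ids = list(feature_ids)
        self.sample_ids = list(sample_ids)

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Per-feature event frequency (row sum / sample count)."""
        return self.values.sum(axis=1) / self.n_samples

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"<FeatureMatrix {self.n_features} features x {self.n_samples} samples>"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])

    def select_features(self, rows: Iterable[int]) -> "FeatureMatrix":
        rows = list(rows)
        return FeatureMatrix(
            self.values[rows, :], [self.feature_ids[i] for i in rows], self.sample_ids
        )

    def select_samples(self, cols: Iterable[int]) -> "FeatureMatrix":
        cols = list(cols)
        return FeatureMatrix(
            self.values[:, cols], self.feature_ids, [self.sample_ids[j] for j in cols]
        )


@dataclass(frozen=True)
class SampleRanking:
    """An ordering of samples, best first (index 0 = highest rank).

    ``measure`` optionally records the continuous value that induced the
    ordering; ``direction`` says whether larger ("decreasing" ordering) or
    smaller ("increasing") values rank first.
    """

    ordered_sample_ids: tuple[str, ...]
    measure: Mapping[str, float] | None = None
    direction: str = "decreasing"

    def __post_init__(self) -> None:
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError(f"unknown direction {self.direction!r}")
        ids = tuple(str(s) for s in self.ordered_sample_ids)
        object.__setattr__(self, "ordered_sample_ids", ids)
        if not ids:
            raise ValueError("ranking is empty")
        _check_unique(ids, "sample")
        if self.measure is not None:
            vals = [self.measure[s] for s in ids if s in self.measure]
            if len(vals) == len(ids):
                arr = np.asarray(vals, dtype=float)
                diffs = np.diff(arr)
                ok = (diffs <= 0).all() if self.direction == "decreasing" else (diffs >= 0).all()
                if not ok:
                    raise ValueError("ordering inconsistent with measure/direction")

    def __len__(self) -> int:
        return len(self.ordered_sample_ids)

    @classmethod
    def from_ordered(cls, sample_ids: Sequence[str]) -> "SampleRanking":
        return cls(tuple(sample_ids))

    def restrict(self, keep: set[str]) -> "SampleRanking":
        """Keep only the given samples, preserving order."""
        ids = tuple(s for s in self.ordered_sample_ids if s in keep)
        if not ids:
            raise ValueError("restriction removed every sample")
        meas = None
        if self.measure is not None:
            meas = {s: self.measure[s] for s in ids if s in self.measure}
        return SampleRanking(ids, meas or None, self.direction)


def rank_samples(measure: Mapping[str, float], direction: str = "decreasing") -> SampleRanking:
    """Order samples by a continuous measurement.

    Ties are broken by stable input order, so rankings are reproducible
    given the same input dict ordering.
    """
    if direction not in ("decreasing", "increasing"):
        raise ValueError(f"unknown direction {direction!r}")
    if not measure:
        raise ValueError("measure is empty")
    ids = [str(s) for s in measure]
    vals = np.asarray([measure[s] for s in measure], dtype=float)
    bad = [ids[i] for i in range(len(ids)) if not np.isfinite(vals[i])]
    if bad:
        raise ValueError(f"non-finite measure for samples: {bad}")
    key = -vals if direction == "decreasing" else vals
    order = np.argsort(key, kind="stable")
    ordered = tuple(ids[i] for i in order)
    return SampleRanking(ordered, dict(zip(ids, vals.tolist())), direction)


def read_ranking(path: str | Path, direction: str = "decreasing") -> SampleRanking:
    """Read a ranking file: two-column TSV (sample, value) or one pre-ordered
    sample id per line."""
    path = Path(path)
    rows = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not rows:
        raise ValueError(f"empty ranking file: {path}")
    first = rows[0].split("\t")
    if len(first) == 1:
        return SampleRanking.from_ordered([r.split("\t")[0] for r in rows])
    measure: dict[str, float] = {}
    start = 0
    try:  # header row is optional
        float(first[1])
    except ValueError:
        start = 1
    for r in rows[start:]:
        parts = r.split("\t")
        measure[parts[0]] = float(parts[1])
    return rank_samples(measure, direction)


def align(
    fm: FeatureMatrix, ranking: SampleRanking
) -> tuple[FeatureMatrix, SampleRanking]:
    """Restrict matrix and ranking to their shared samples; reorder matrix
    columns to ranking order.

    Samples present on only one side are dropped with a logged warning.
    """
    fm_set = set(fm.sample_ids)
    rank_set = set(ranking.ordered_sample_ids)
    common = fm_set & rank_set
    if not common:
        raise ValueError("matrix and ranking share no samples")
    dropped_fm = len(fm_set) - len(common)
    dropped_rank = len(rank_set) - len(common)
    if dropped_fm or dropped_rank:
        logger.warning(
            "align: dropped %d sample(s) from matrix, %d from ranking "
            "(%d shared)", dropped_fm, dropped_rank, len(common),
        )
    new_rank = ranking.restrict(common)
    col_of = {s: j for j, s in enumerate(fm.sample_ids)}
    cols = [col_of[s] for s in new_rank.ordered_sample_ids]
    if cols == list(range(fm.n_samples)):
        return fm, new_rank
    return fm.select_samples(cols), new_rank


def prefilter_features(fm: FeatureMatrix, cfg: FilterConfig | None = None) -> FeatureMatrix:
    """Drop features whose event frequency lies outside [min_freq, max_freq].

    Bounds are inclusive: a feature at exactly the boundary frequency is
    retained.  Feature order is preserved.
    """
    cfg = cfg or FilterConfig()
    freq = fm.frequencies
    keep = np.flatnonzero((freq >= cfg.min_freq) & (freq <= cfg.max_freq))
    if keep.size == 0:
        raise ValueError(
            f"pre-filter removed every feature (bounds {cfg.min_freq}-"
            f"{cfg.max_freq}); relax the thresholds"
        )
    if keep.size == fm.n_features:
        return fm
    return fm.select_features(keep.tolist())


# ---------------------------------------------------------------------------
# File I/O

_BINARY_TOKENS = {"0": 0, "1": 1}


def _parse_binary_frame(df: pd.DataFrame, path: Path) -> np.ndarray:
    values = np.empty(df.shape, dtype=np.uint8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            tok = str(raw[i, j]).strip()
            if tok not in _BINARY_TOKENS:
                raise MatrixFormatError(
                    f"{path}: non-binary value {raw[i, j]!r} at feature "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}"
                )
            values[i, j] = _BINARY_TOKENS[tok]
    return values


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".gct":
        return "gct"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def read_feature_matrix(path: str | Path, format: str | None = None) -> FeatureMatrix:
    """Load a binary feature matrix from TSV, CSV, or GCT 1.2.

    Layout: header row of sample ids, first column of feature ids (GCT adds
    its two header lines and a Description column).  Cells must be literal
    0/1 tokens; anything else is a format error naming the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise MatrixFormatError(f"{path}: not a GCT file (first line {version!r})")
            dims = fh.readline().split()
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        else:  # Description is positional in GCT 1.2
            df = df.iloc[:, 1:]
        if len(dims) >= 2 and (int(dims[0]), int(dims[1])) != df.shape:
            raise MatrixFormatError(
                f"{path}: GCT header declares {dims[0]}x{dims[1]}, found {df.shape}"
            )
    elif fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0, dtype=str)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: empty matrix")
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise MatrixFormatError(
            f"{path}: missing value at feature {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    values = _parse_binary_frame(df, path)
    return FeatureMatrix(values, list(df.index), list(df.columns))


def write_feature_matrix(fm: FeatureMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix as TSV/CSV or GCT 1.2 (Description column mirrors the
    feature id)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{fm.n_features}\t{fm.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(fm.sample_ids) + "\n")
            for i, fid in enumerate(fm.feature_ids):
                row = "\t".join(str(v) for v in fm.values[i])
                fh.write(f"{fid}\t{fid}\t{row}\n")
    elif fmt in ("tsv", "csv"):
        fm.to_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",")
    else:
        raise ValueError(f"unknown format {fmt!r}")
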