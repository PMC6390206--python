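"""Meta-plot visualisation of a search result.

A meta-plot stacks, top to bottom: an area plot of the per-sample
measurement in ranking order; one binary track per member feature in the
order they were added; the union track (red); and a running enrichment
score (ES) below.  The ES walks the ranking left to right, rising by 1/m
at each of the m event positions and falling by 1/(N-m) elsewhere, so it
ends at exactly 0 and peaks early for left-skewed unions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["MetaPlotSpec", "running_enrichment_score", "render_meta_plot"]


def running_enrichment_score(union_vector) -> np.ndarray:
    """Running enrichment score of a binary union vector over the ranking.

    Increment by 1/m at event positions, decrement by 1/(N-m) otherwise;
    the walk telescopes back to 0 at position N.  Requires 1 <= m < N.
    """
    u = np.asarray(union_vector)
    if u.ndim != 1 or not np.isin(u, (0, 1)).all():
        raise ValueError("union_vector must be a 1-D binary vector")
    N = u.size
    m = int(u.sum())
    if m == 0 or m == N:
        raise ValueError("enrichment score requires 1 <= events < N")
    steps = np.where(u == 1, 1.0 / m, -1.0 / (N - m))
    return np.cumsum(steps)


@dataclass(frozen=True)
class MetaPlotSpec:
    """All tracks of a meta-plot, each of length N (ranking order)."""

    feature_tracks: tuple[np.ndarray, ...]
    feature_ids: tuple[str, ...]
    measure_track: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.feature_tracks:
            raise ValueError("meta-plot requires at least one feature track")
        if len(self.feature_ids) != len(self.feature_tracks):
            raise ValueError("one id per feature track is required")
        N = self.feature_tracks[0].size
        for t in self.feature_tracks:
            if t.size != N or not np.isin(t, (0, 1)).all():
                raise ValueError("feature tracks must be equal-length binary vectors")
        if self.measure_track is not None and np.asarray(self.measure_track).size != N:
            raise ValueError("measure track length must match feature tracks")

    @property
    def union_track(self) -> np.ndarray:
        return np.maximum.reduce([np.asarray(t) for t in self.feature_tracks])

    @property
    def n_samples(self) -> int:
        return self.feature_tracks[0].size


def _draw_track(ax, values: np.ndarray, color: str) -> None:
    ax.imshow(
        np.asarray(values)[None, :],
        aspect="auto",
        cmap=matplotlib.colors.ListedColormap(["#f0f0f0", color]),
        vmin=0,
        vmax=1,
        interpolation="nearest",
    )
    ax.set_xticks([])
    ax.set_yticks([])


def render_meta_plot(spec: MetaPlotSpec, out_path: str | Path, format: str = "svg") -> Path:
    """Write the meta-plot to ``out_path`` (svg or png).

    Layout is deterministic given the spec; SVG output is byte-stable.
    """
    if format not in ("svg", "png"):
        raise ValueError(f"unknown format {format!r}")
    out_path = Path(out_path)
    n_tracks = len(spec.feature_tracks)
    n_panels = n_tracks + 2 + (1 if spec.measure_track is not None else 0)
    ratios = ([3] if spec.measure_track is not None else []) + [1] * (n_tracks + 1) + [3]
    with matplotlib.rc_context({"svg.hashsalt": "driverscan"}):
        fig, axes = plt.subplots(
            n_panels,
            1,
            figsize=(8, 1.2 + 0.45 * n_panels),
            gridspec_kw={"height_ratios": ratios},
            constrained_layout=True,
        )
        axes = np.atleast_1d(axes)
        idx = 0
        x = np.arange(spec.n_samples)
        if spec.measure_track is not None:
            ax = axes[idx]
            ax.fill_between(x, np.asarray(spec.measure_track, dtype=float), step="mid",
                            color="#4477aa", alpha=0.8)
            ax.set_xlim(-0.5, spec.n_samples - 0.5)
            ax.set_xticks([])
            ax.set_ylabel("measure", fontsize=8)
            idx += 1
        for fid, track in zip(spec.feature_ids, spec.feature_tracks):
            _draw_track(axes[idx], np.asarray(track), "#222222")
            axes[idx].set_ylabel(fid, rotation=0, ha="right", va="center", fontsize=8)
            idx += 1
        _draw_track(axes[idx], spec.union_track, "#cc3311")
        axes[idx].set_ylabel("union", rotation=0, ha="right", va="center", fontsize=8)
        idx += 1
        es = running_enrichment_score(spec.union_track)
        axes[idx].plot(x, es, color="#009988", linewidth=1.2)
        axes[idx].axhline(0.0, color="#888888", linewidth=0.6)
        axes[idx].set_xlim(-0.5, spec.n_samples - 0.5)
        axes[idx].set_ylabel("ES", fontsize=8)
        axes[idx].set_xlabel("sample rank", fontsize=8)
        fig.savefig(out_path, format=format, metadata={"Date": None} if format == "svg" else None)
        plt.close(fig)
    return out_path
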