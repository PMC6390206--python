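"""Model/results façade over the greedy meta-feature search.

:class:`MetaFeatureSearch` is constructed from a feature matrix and a
sample ranking (the data) together with the search settings (the model
parameters); :meth:`MetaFeatureSearch.fit` runs the search and returns a
:class:`SearchResults` carrying the selected meta-feature, its step score
trace, a ``summary()`` table, permutation significance via
``significance()``, and the meta-plot via ``plot()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matrix import (
    FeatureMatrix,
    FilterConfig,
    SampleRanking,
    align,
    prefilter_features,
    rank_samples,
    read_feature_matrix,
    read_ranking,
)
from .plotting import MetaPlotSpec, render_meta_plot
from .search import MetaFeature, SearchConfig, TopNResult, stepwise_search, topn_search
from .significance import (
    NullDistribution,
    cache_fetch_or_compute,
    config_digest,
    generate_null,
    permutation_pvalue,
)

__all__ = ["MetaFeatureSearch", "SearchResults"]


class MetaFeatureSearch:
    """Greedy search for the feature union most left-skewed in a ranking.

    Parameters
    ----------
    matrix : FeatureMatrix
        Binary features x samples.
    ranking : SampleRanking
        Sample ordering, best first.  The matrix is aligned to it (shared
        samples only, columns reordered) at construction.
    method : {"ks", "wilcoxon"}
        Left-skewness score.
    max_size : int
        Maximum number of features in the meta-feature.
    start : {"best", feature id}
        Start from the best-scoring single feature, or seed with a named
        feature.
    top_n : int or None
        If given, restart from each of the top_n best single features and
        keep the best run.
    prefilter : FilterConfig or None
        Frequency pre-filter applied to the aligned matrix (None disables).

    Examples
    --------
    >>> model = MetaFeatureSearch(matrix, ranking, method="ks", max_size=7)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.significance(B=1000, seed=7)
    """

    def __init__(
        self,
        matrix: FeatureMatrix,
        ranking: SampleRanking,
        method: str = "ks",
        max_size: int = 7,
        start: str = "best",
        top_n: int | None = None,
        prefilter: FilterConfig | None = None,
    ) -> None:
        fm, rk = align(matrix, ranking)
        if prefilter is not None:
            fm = prefilter_features(fm, prefilter)
        self.matrix = fm
        self.ranking = rk
        if top_n is not None:
            self.config = SearchConfig(
                method=method, max_size=max_size, start_mode="top_n", top_n=top_n
            )
        elif start == "best":
            self.config = SearchConfig(method=method, max_size=max_size)
        else:
            self.config = SearchConfig(
                method=method, max_size=max_size, start_mode="seeded", seed_feature=start
            )

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        ranking_path: str | Path,
        direction: str = "decreasing",
        **kwargs,
    ) -> "MetaFeatureSearch":
        """Build a model from a matrix file (TSV/CSV/GCT) and a ranking file
        (two-column sample/value TSV, or one pre-ordered id per line)."""
        fm = read_feature_matrix(matrix_path)
        rk = read_ranking(ranking_path, direction)
        return cls(fm, rk, **kwargs)

    def fit(self) -> "SearchResults":
        """Run the configured search and return its results."""
        if self.config.start_mode == "top_n":
            topn = topn_search(self.matrix, self.config)
            return SearchResults(self, topn.best, topn)
        mf = stepwise_search(self.matrix, self.config)
        return SearchResults(self, mf, None)


class SearchResults:
    """Outcome of a fitted :class:`MetaFeatureSearch`.

    Attributes
    ----------
    meta_feature : MetaFeature
        The selected members, their union vector, and the step score trace.
    topn_result : TopNResult or None
        All restart runs when the model used top-N mode.
    permutation_p : float or None
        Permutation p-value, populated by :meth:`significance`.
    """

    def __init__(
        self,
        model: MetaFeatureSearch,
        meta_feature: MetaFeature,
        topn_result: TopNResult | None,
    ) -> None:
        self.model = model
        self.meta_feature = meta_feature
        self.topn_result = topn_result
        self.permutation_p: float | None = None
        self.null_distribution: NullDistribution | None = None

    @property
    def member_feature_ids(self) -> tuple[str, ...]:
        return self.meta_feature.member_feature_ids

    @property
    def final_score(self):
        return self.meta_feature.final_score

    def significance(
        self,
        B: int = 1000,
        seed: int = 0,
        cache_dir: str | Path | None = None,
        n_jobs: int = 1,
    ) -> float:
        """Permutation p-value of the final score against B searches on
        permuted rankings (cached in ``cache_dir`` when given)."""
        if cache_dir is not None:
            null = cache_fetch_or_compute(
                self.model.matrix, self.model.config, B, seed, cache_dir, n_jobs=n_jobs
            )
        else:
            null = generate_null(
                self.model.matrix, self.model.config, B, seed, n_jobs=n_jobs
            )
        self.null_distribution = null
        self.permutation_p = permutation_pvalue(self.final_score, null)
        return self.permutation_p

    def summary(self) -> str:
        """Plain-text summary: one row per accepted step, then the final
        score and (when computed) the permutation p-value."""
        mf = self.meta_feature
        cfg = self.model.config
        lines = [
            "Meta-feature search results",
            "===========================",
            f"method: {cfg.method}    max_size: {cfg.max_size}    "
            f"start_mode: {cfg.start_mode}"
            + (f"    top_n: {cfg.top_n}" if cfg.start_mode == "top_n" else ""),
            f"samples: {self.model.matrix.n_samples}    "
            f"features searched: {self.model.matrix.n_features}",
            "",
            f"{'step':>4}  {'feature':<24}{'statistic':>10}  {'p-value':>10}  {'events':>6}",
        ]
        for i, (fid, sc) in enumerate(zip(mf.member_feature_ids, mf.step_scores), 1):
            lines.append(
                f"{i:>4}  {fid:<24}{sc.statistic:>10.4f}  {sc.p_value:>10.3e}  {sc.n_events:>6}"
            )
        lines.append("")
        fs = mf.final_score
        lines.append(
            f"final score: statistic={fs.statistic:.4f} p={fs.p_value:.3e} "
            f"({fs.n_events}/{fs.n_samples} samples altered)"
        )
        if self.permutation_p is not None:
            lines.append(
                f"permutation p-value: {self.permutation_p:.4g} "
                f"(B={self.null_distribution.B})"
            )
        return "\n".join(lines)

    def plot(self, out_path: str | Path, format: str = "svg") -> Path:
        """Render the meta-plot for the selected meta-feature."""
        spec = self.to_plot_spec()
        return render_meta_plot(spec, out_path, format=format)

    def to_plot_spec(self) -> MetaPlotSpec:
        mf = self.meta_feature
        fm = self.model.matrix
        rows = [fm.values[r].astype(np.uint8) for r in mf.member_rows]
        measure = None
        if self.model.ranking.measure is not None:
            try:
                measure = np.asarray(
                    [self.model.ranking.measure[s] for s in self.model.ranking.ordered_sample_ids],
                    dtype=float,
                )
            except KeyError:
                measure = None
        return MetaPlotSpec(
            feature_tracks=tuple(rows),
            feature_ids=mf.member_feature_ids,
            measure_track=measure,
        )

    def to_dict(self) -> dict:
        """JSON-ready record of the result (accepted by the plot CLI)."""
        mf = self.meta_feature
        cfg = self.model.config
        return {
            "members": list(mf.member_feature_ids),
            "union_vector": mf.union_vector.astype(int).tolist(),
            "ordered_samples": list(self.model.ranking.ordered_sample_ids),
            "step_scores": [
                {
                    "feature": fid,
                    "method": sc.method,
                    "statistic": sc.statistic,
                    "p_value": sc.p_value,
                    "n_events": sc.n_events,
                    "n_samples": sc.n_samples,
                }
                for fid, sc in zip(mf.member_feature_ids, mf.step_scores)
            ],
            "permutation_p": self.permutation_p,
            "config": {
                "method": cfg.method,
                "max_size": cfg.max_size,
                "start_mode": cfg.start_mode,
                "seed_feature": cfg.seed_feature,
                "top_n": cfg.top_n,
            },
            "config_digest": (
                self.null_distribution.config_digest
                if self.null_distribution is not None
                else None
            ),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
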