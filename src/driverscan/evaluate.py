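"""Benchmarking, reproducibility, and enrichment utilities.

Three evaluation procedures:

* :func:`run_performance_experiment` — the simulation benchmark: generate
  true-positive and null datasets over a grid of sample sizes, run the
  search plus permutation test on each, and report mean TPR/FPR as the
  weight-average over strata (number of true-positive members for TPR,
  meta-feature size for FPR), weighted by the number of searches per
  stratum.
* :func:`subsample_reproducibility` — Jaccard-index stability of the
  returned meta-feature under repeated sub-sampling of the cohort, with an
  optional permuted-ranking control and a one-sided rank-sum comparison.
* :func:`hyper_enrichment` / :func:`adjust_fdr` — hypergeometric
  enrichment of selected features against a reference id list, with
  Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import FeatureMatrix, FilterConfig, SampleRanking, align, prefilter_features
from .search import MetaFeature, SearchConfig, TopNResult, stepwise_search, topn_search
from .significance import generate_null, permutation_pvalue
from .simulate import SimulationParams, simulate_null_dataset, simulate_tp_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "PerformanceTable",
    "ReproducibilityResult",
    "run_performance_experiment",
    "jaccard_index",
    "subsample_reproducibility",
    "hyper_enrichment",
    "adjust_fdr",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings for the simulation benchmark.

    Defaults follow the standard benchmark design: n = 1000 features of
    which p = 5 are mutually exclusive true positives jointly covering the
    top half of the ranking (f = 0.5), search budget 7, top-1 start,
    significance at alpha = 0.05.
    """

    sample_sizes: tuple[int, ...] = (50, 60, 70, 80, 90, 100, 250, 500)
    replicates: int = 500
    n: int = 1000
    p: int = 5
    f: float = 0.5
    B: int = 1000
    alpha: float = 0.05
    max_size: int = 7
    top_n: int = 1
    method: str = "ks"
    seed: int = 0
    prefilter: FilterConfig | None = field(default_factory=FilterConfig)
    dataset_kinds: tuple[str, ...] = ("true_positive", "null")

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def search_config(self) -> SearchConfig:
        if self.top_n == 1:
            return SearchConfig(method=self.method, max_size=self.max_size)
        return SearchConfig(
            method=self.method,
            max_size=self.max_size,
            start_mode="top_n",
            top_n=self.top_n,
        )


@dataclass(frozen=True)
class PerformanceTable:
    """Stratified benchmark outcome.

    ``table`` has one row per (sample size, dataset kind, stratum): for
    true-positive datasets the stratum is the number of true-positive
    members in the returned meta-feature; for null datasets it is the
    meta-feature size.  ``mean_tpr`` / ``mean_fpr`` map sample size to the
    weight-averaged rate in percent.
    """

    table: pd.DataFrame
    mean_tpr: dict[int, float]
    mean_fpr: dict[int, float]
    config: ExperimentConfig

    def summary(self) -> str:
        lines = ["Sample size    Mean TPR (%)    Mean FPR (%)"]
        for N in self.config.sample_sizes:
            tpr = self.mean_tpr.get(N, float("nan"))
            fpr = self.mean_fpr.get(N, float("nan"))
            lines.append(f"{N:>11d}    {tpr:>12.2f}    {fpr:>12.2f}")
        return "\n".join(lines)


def _run_one(
    dataset, cfg: ExperimentConfig, null_seed: int
) -> tuple[MetaFeature, float]:
    """Search one simulated dataset and attach its permutation p-value."""
    fm = dataset.matrix
    if cfg.prefilter is not None:
        fm = prefilter_features(fm, cfg.prefilter)
    scfg = cfg.search_config()
    if scfg.start_mode == "top_n":
        result = topn_search(fm, scfg)
        mf = result.best
    else:
        mf = stepwise_search(fm, scfg)
    null = generate_null(fm, scfg, B=cfg.B, seed=null_seed)
    p = permutation_pvalue(mf.final_score, null)
    return mf, p


def run_performance_experiment(cfg: ExperimentConfig) -> PerformanceTable:
    """Estimate TPR and FPR of the search across sample sizes.

    For each sample size and replicate one true-positive and one null
    dataset are generated and searched.  A search "rejects" when its
    permutation p-value is <= alpha.  The per-stratum rates are
    weight-averaged with weights equal to the stratum counts, which makes
    the reported mean equal to the overall rejection fraction.
    """
    rows = []
    master = np.random.default_rng(cfg.seed)
    for N in cfg.sample_sizes:
        params = SimulationParams(N=N, n=cfg.n, p=cfg.p, f=cfg.f)
        for kind in cfg.dataset_kinds:
            strata: dict[int, list[int]] = {}
            for _ in range(cfg.replicates):
                data_seed = int(master.integers(2**31))
                null_seed = int(master.integers(2**31))
                if kind == "true_positive":
                    ds = simulate_tp_dataset(params, seed=data_seed)
                else:
                    ds = simulate_null_dataset(params, seed=data_seed)
                mf, p = _run_one(ds, cfg, null_seed)
                if kind == "true_positive":
                    tp_ids = ds.true_positive_ids
                    stratum = len(set(mf.member_feature_ids) & tp_ids)
                else:
                    stratum = mf.size
                strata.setdefault(stratum, []).append(int(p <= cfg.alpha))
            for stratum, flags in sorted(strata.items()):
                rows.append(
                    {
                        "sample_size": N,
                        "dataset": kind,
                        "stratum": stratum,
                        "count": len(flags),
                        "significant": int(np.sum(flags)),
                    }
                )
    table = pd.DataFrame(rows)
    mean_tpr: dict[int, float] = {}
    mean_fpr: dict[int, float] = {}
    for N in cfg.sample_sizes:
        for kind, out in (("true_positive", mean_tpr), ("null", mean_fpr)):
            if kind not in cfg.dataset_kinds:
                continue
            sub = table[(table.sample_size == N) & (table.dataset == kind)]
            counts = sub["count"].to_numpy(dtype=float)
            rates = sub["significant"].to_numpy(dtype=float) / counts
            out[N] = float(100.0 * np.average(rates, weights=counts))
    return PerformanceTable(table=table, mean_tpr=mean_tpr, mean_fpr=mean_fpr, config=cfg)


def jaccard_index(A: Iterable[str], B: Iterable[str]) -> float:
    """|A ∩ B| / |A ∪ B| for two feature-id sets."""
    A, B = set(A), set(B)
    if not A and not B:
        raise ValueError("Jaccard index of two empty sets is undefined")
    return len(A & B) / len(A | B)


@dataclass(frozen=True)
class ReproducibilityResult:
    """Jaccard stability under sub-sampling.

    ``J_original`` holds one Jaccard index per sub-sampling iteration
    against the full-data meta-feature; ``J_control`` the same computed
    under a fixed permuted ranking (None when no control was requested);
    ``comparison_p`` is the one-sided rank-sum p-value that J_original
    exceeds J_control.
    """

    J_original: tuple[float, ...]
    J_control: tuple[float, ...] | None
    comparison_p: float | None
    fraction: float
    iterations: int


def _search_members(fm: FeatureMatrix, ranking: SampleRanking, cfg: SearchConfig) -> set[str]:
    fm2, _ = align(fm, ranking)
    if cfg.start_mode == "top_n":
        return set(topn_search(fm2, cfg).best.member_feature_ids)
    return set(stepwise_search(fm2, cfg).member_feature_ids)


def _subsample_js(
    fm: FeatureMatrix,
    ranking: SampleRanking,
    cfg: SearchConfig,
    fraction: float,
    iterations: int,
    rng: np.random.Generator,
) -> list[float]:
    reference = _search_members(fm, ranking, cfg)
    ids = list(ranking.ordered_sample_ids)
    k = int(np.floor(fraction * len(ids)))
    js: list[float] = []
    for _ in range(iterations):
        keep = set(np.asarray(ids, dtype=object)[rng.choice(len(ids), size=k, replace=False)])
        sub_ranking = ranking.restrict(keep)
        try:
            members = _search_members(fm, sub_ranking, cfg)
        except ValueError as exc:
            logger.warning("subsample search failed (%s); recording J = 0", exc)
            members = set()
        js.append(jaccard_index(reference, members) if members else 0.0)
    return js


def subsample_reproducibility(
    fm: FeatureMatrix,
    ranking: SampleRanking,
    cfg: SearchConfig | None = None,
    fraction: float = 0.8,
    iterations: int = 100,
    control: str = "permuted_ranking",
    seed: int = 0,
) -> ReproducibilityResult:
    """Assess stability of the search result under cohort sub-sampling.

    The meta-feature from the full data is the reference; each iteration
    re-runs the search on a random ``fraction`` of samples (without
    replacement, ranking order preserved) and records the Jaccard index of
    its members against the reference.  With ``control="permuted_ranking"``
    the whole procedure is repeated once under a fixed random permutation
    of the ranking, and the two J distributions are compared with a
    one-sided rank-sum test (original > control).

    An iteration whose search returns nothing contributes J = 0.
    """
    cfg = cfg or SearchConfig()
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if control not in ("none", "permuted_ranking"):
        raise ValueError(f"unknown control {control!r}")
    fm_aligned, ranking = align(fm, ranking)
    rng = np.random.default_rng(seed)
    j_orig = _subsample_js(fm_aligned, ranking, cfg, fraction, iterations, rng)
    j_ctrl: list[float] | None = None
    comparison_p: float | None = None
    if control == "permuted_ranking":
        perm = rng.permutation(len(ranking))
        permuted = SampleRanking.from_ordered(
            [ranking.ordered_sample_ids[i] for i in perm]
        )
        j_ctrl = _subsample_js(fm_aligned, permuted, cfg, fraction, iterations, rng)
        comparison_p = float(
            stats.mannwhitneyu(j_orig, j_ctrl, alternative="greater").pvalue
        )
    return ReproducibilityResult(
        J_original=tuple(j_orig),
        J_control=tuple(j_ctrl) if j_ctrl is not None else None,
        comparison_p=comparison_p,
        fraction=fraction,
        iterations=iterations,
    )


def hyper_enrichment(
    selected: Iterable[str], unselected: Iterable[str], reference: Iterable[str]
) -> float:
    """Upper-tail hypergeometric enrichment of ``selected`` in ``reference``.

    The universe is ``selected ∪ unselected``; the p-value is the
    probability of drawing at least |selected ∩ reference| reference
    members among |selected| draws without replacement from the universe.
    """
    selected, unselected, reference = set(selected), set(unselected), set(reference)
    if not selected:
        raise ValueError("selected set is empty")
    if selected & unselected:
        raise ValueError("selected and unselected sets must be disjoint")
    universe = selected | unselected
    M = len(universe)
    K = len(universe & reference)
    n_draw = len(selected)
    k = len(selected & reference)
    return float(stats.hypergeom.sf(k - 1, M, K, n_draw))


def adjust_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()
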