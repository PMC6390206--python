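# driverscan

Greedy search for **candidate driver meta-features**: given a matrix of
binary genomic alterations (somatic mutations, copy-number events, ...) and
a ranking of the same samples by a continuous phenotype (pathway activity,
drug sensitivity, protein abundance), `driverscan` finds the small set of
features whose logical-OR union is most *left-skewed* — whose events
concentrate among the top-ranked samples — and attaches a permutation
p-value to the result.

The OR-union is the point: cancers are heterogeneous, and distinct samples
may carry *different* alterations driving the same phenotype (e.g. mutually
exclusive `BRAF`/`NRAS` mutations upstream of MEK signalling). A union of
complementary, individually weak features can track the phenotype far better
than any single feature.

## Method

Let the N samples be ranked best-first and let a (meta-)feature have events
at ranks r₁ < … < r_m. Left-skewness is scored by a one-sided, one-sample
Kolmogorov–Smirnov statistic

    D⁺ = max_i ( i/m − (rᵢ − 1)/N ),      p = exp(−2 m D⁺²),

(a Wilcoxon rank-sum score is also available). Scores are compared by
p-value first, then statistic, so unions of different sizes are comparable.

The search is stepwise greedy: start from the best single feature (or a
user-chosen seed), at each step OR the incumbent with every remaining
feature, accept the best strictly improving union, and stop when nothing
improves or the size budget (default 7) is reached. A *top-N* mode restarts
the search from each of the N best single features and keeps the best run,
guarding against local optima.

Significance comes from rerunning the identical search on B randomly
permuted rankings: p = (1 + #{permuted best scores strictly better}) /
(B + 1). The null depends only on the matrix and search settings — not on
the ranking — so null distributions are cached and shared across queries of
the same dataset.

The package also ships the supporting machinery: a simulator of benchmark
datasets with planted mutually exclusive left-skewed features, a TPR/FPR
benchmark harness, sub-sampling Jaccard reproducibility analysis,
hypergeometric reference-list enrichment with Benjamini–Hochberg
correction, and a "meta-plot" visualisation (measure track, member feature
tracks, union, running enrichment score).

## Worked example

```python
from driverscan import (MetaFeatureSearch, SimulationParams,
                        simulate_tp_dataset)

# benchmark dataset: 100 samples, 1000 features, 5 mutually exclusive
# true positives jointly covering the top half of the ranking
ds = simulate_tp_dataset(SimulationParams(N=100, n=1000, p=5, f=0.5), seed=42)

model = MetaFeatureSearch(ds.matrix, ds.ranking, method="ks", max_size=7)
res = model.fit()
res.significance(B=1000, seed=7)
print(res.summary())
```

```
Meta-feature search results
===========================
method: ks    max_size: 7    start_mode: best_single
samples: 100    features searched: 1000

step  feature                  statistic     p-value  events
   1  tp_2                        0.6000   7.466e-04      10
   2  tp_3                        0.5800   1.433e-06      20
   3  tp_4                        0.5600   6.735e-09      30
   4  tp_5                        0.5350   1.136e-10      40
   5  tp_1                        0.5100   5.058e-12      50

final score: statistic=0.5100 p=5.058e-12 (50/100 samples altered)
permutation p-value: 0.000999 (B=1000)
```

The search recovers exactly the five planted true positives and nothing
else: each accepted step adds 10 events within the top 50 samples, the KS
p-value improves monotonically, and the final union (50/100 samples
altered) is better than all 1000 permuted-ranking searches
(p = 1/1001 ≈ 0.001). `res.plot("meta.svg")` renders the corresponding
meta-plot.

The same pipeline is available from the shell:

```sh
driverscan simulate --type tp --N 100 --seed 42 --out m.tsv --ranking-out r.txt
driverscan search --matrix m.tsv --ranking r.txt -B 1000 --seed 7 --out hit.json
driverscan plot --result hit.json --matrix m.tsv --out meta.svg
```

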