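# Methods

This note records the statistical model, the conventions the implementation
commits to, and what the simulation-based tests do and do not establish.

## Problem and model

The data are a binary feature matrix X (features × samples, 1 = alteration
present) and a ranking of the samples induced by a continuous per-sample
measurement, best first. The estimand is a *meta-feature*: an ordered subset
of features whose logical-OR union is maximally left-skewed with respect to
the ranking. The OR captures driver complementarity: samples with the same
phenotype may carry different, often mutually exclusive, alterations.

### Left-skewness scores

For a union with events at ranks r₁ < … < r_m among N samples:

* **KS (default).** One-sided, one-sample statistic against the uniform
  reference on 1..N:

      D⁺ = max_i ( i/m − (rᵢ − 1)/N ),   clipped to [0, 1].

  Implemented with the integer-exact numerator max_i(N·i − m·(rᵢ−1)) and a
  single division, so the scalar API, the vectorised numpy path and the
  compiled kernel agree bit-for-bit. The p-value is the standard one-sided
  asymptotic tail bound p = exp(−2 m D⁺²), clipped to (0, 1]. It is a bound,
  not an exact tail probability; it is used only as a monotone ranking
  device within the search and never as a calibrated significance claim —
  calibration comes from the permutation test.
* **Wilcoxon.** Rank-sum W = Σ rᵢ, one-sided against "events occupy smaller
  ranks", normal approximation with continuity correction. Ranks are a
  permutation so ties cannot arise. The reported statistic is −z (positive =
  left-skewed).

Scores are ordered by p-value first, statistic second. D⁺ alone is not
comparable across unions with different m; the p-value (equivalently m·D⁺²
for KS) is. Equality in both components is a tie, and a tie is never an
improvement.

### Greedy search

Stepwise forward selection: score all single features, start from the best
(or a user seed); at each step score the union of the incumbent with every
remaining feature and accept the best strictly improving candidate; stop at
no improvement or at `max_size` (default 7) members. Conventions:

* Ties among candidates are broken by lowest row index (deterministic and
  stable under reruns; row order therefore matters only for exact ties).
* A candidate whose union equals the incumbent's union scores equally and is
  rejected by strictness, so subsumed features are never added.
* Members are excluded from later candidacy.

Top-N mode reruns the greedy expansion from each of the N best-scoring
single features (same tie rule) and reports all runs, their pairwise member
overlap, and the best final score. The greedy search is a local optimiser;
tests verify against an exhaustive-subset oracle that it never exceeds the
global optimum and attains it on nested-structure instances, and include a
frozen instance where only the multi-restart search reaches the optimum.

### Permutation significance

The null distribution is the final best score of the *identical* search run
on B uniformly permuted rankings (default B = 1000; ≥ 500 recommended;
benchmark runs here use B = 100). The add-one estimator is

    p = (1 + #{permuted best scores strictly better}) / (B + 1),

so p ≥ 1/(B+1) and p never equals 0. **Tie handling is a real decision, not
a technicality.** In small cohorts the greedy maximum over ~10³ features
saturates: many permutations attain exactly the same ceiling score, so at
N ≈ 50 a large fraction of the null distribution can tie with the observed
result. Counting ties against the observed search ("at least as good" in
the numerator) drives the realised type-I error far below the nominal level
(≈0.7% at α = 5%, N = 50) and destroys what little power exists there;
counting only strictly better nulls (ties resolved for the observed result)
reproduces the known benchmark behaviour of this search family — a mildly
anti-conservative N = 50 row (FPR slightly above 5%) and exact calibration
at N ≥ 100, where ties vanish and the two conventions coincide. The package
uses the strictly-better numerator.

Permutation streams: one root seed; iteration b draws from the b-th spawned
child of `numpy.random.SeedSequence(root)`, so serial and parallel
(`n_jobs`) execution are bit-identical and scheduling cannot reorder
results.

**Caching.** The null depends on the matrix and the search parameters, not
on the ranking. The cache key is a SHA-256 digest over the matrix content
with columns canonicalised by sorted sample id (hence ranking- and
column-order-invariant), the feature ids and row order (row order can
matter through tie-breaking), the search configuration, B and the seed.
Entries are self-describing JSON; a corrupted entry is recomputed with a
warning.

## Synthetic benchmark data

`simulate_tp_dataset(N, n, p, f)` plants p mutually exclusive left-skewed
features among n: the first k = round(f·N) ranked columns are partitioned
uniformly at random into p blocks of size ⌊k/p⌋ or ⌈k/p⌉ (remainder on the
first blocks), block i forming feature i's events, so the union of the p
true positives is exactly the indicator of columns 1..k. The remaining
n − p features are nulls; `simulate_null_dataset` generates all-null data.
Each null feature draws its event count from Poisson(λ) with λ = f·N/p —
centred on the true-positive event count, so marginal frequency carries no
label information — redrawn until 1 ≤ c ≤ N (a 0-event feature is
unscorable, > N is unplaceable), with events placed uniformly without
replacement. Rows are shuffled so truth is not encoded in row order, and
the implicit ranking is column order.

Defaults mirror the standard benchmark design: n = 1000, p = 5, f = 0.5,
N ∈ {50 … 500}. Placement of true-positive events within the top block is
random rather than contiguous; only mutual exclusivity and exact union
coverage are structural, and randomisation avoids artifactual within-block
rank structure.

What this emulates — and what it does not: features are independent apart
from the planted exclusivity; real alteration matrices have correlated
features (co-amplified loci, subtype structure), frequency spectra far from
Poisson, and missingness. Passing benchmarks here demonstrates the
machinery's sensitivity/specificity under the stated design, not
performance guarantees on real cohorts.

## Evaluation harness

* **TPR/FPR benchmark.** Per sample size and replicate, one true-positive
  and one null dataset are generated, pre-filtered, searched (KS, top-1
  start, max_size 7) and permutation-tested. A search rejects at p ≤ α
  (α = 0.05). Results are stratified — by number of true-positive members
  for TPR, by meta-feature size for FPR — and the mean rate is the
  weight-average over strata with weights equal to stratum counts
  (algebraically, the overall rejection fraction; the strata are reported
  for composition analysis). FPR strata are treated symmetrically to TPR.
  Benchmark runs in the test suite and acceptance script use 100 replicate
  datasets and B = 100 permutations per condition; these sizes give
  binomial standard errors of a few percentage points, which the tests
  account for with 99% binomial intervals.
* **Sub-sampling reproducibility.** Reference meta-feature from the full
  data; each of 100 iterations re-runs the search on a random 80% of
  samples (order preserved) and records the Jaccard index of member sets
  against the reference. The control repeats the procedure under one fixed
  random permutation of the ranking; distributions are compared with a
  one-sided rank-sum test (original > control) matching the directional
  claim. An iteration whose search fails contributes J = 0 (conservative,
  keeps iteration counts fixed). Permutation significance is not needed for
  J, so B = 0 in these runs.
* **Enrichment.** Upper-tail hypergeometric probability of the observed
  overlap between selected features and a user-supplied reference list,
  with the universe = selected ∪ unselected; Benjamini–Hochberg step-up for
  multiplicity.

## Input handling

Matrices load from TSV/CSV (header = sample ids, first column = feature
ids) or GCT 1.2; cells must be literal 0/1 tokens and missing cells are
rejected — binary event semantics admit no principled imputation. The
frequency pre-filter keeps features with event frequency in [3%, 60%],
bounds inclusive ("below"/"above" exclusion implies the closed interval is
retained). Rankings come from a per-sample measure (ties broken by stable
input order) or a pre-ordered id list; matrix and ranking are aligned to
their shared samples with a logged count of drops on each side.

## Numerical and engineering notes

* The greedy KS path runs through a numba-compiled kernel (~10× the
  vectorised numpy path, which remains as reference and fallback); an
  equivalence test pins the two bit-for-bit. One benchmark condition
  (100 datasets × 101 searches at N = 500) runs in ~3 minutes on one CPU.
* D⁺ comparisons inside the search use the monotone surrogate m·D⁺² instead
  of exp(−2 m D⁺²), avoiding transcendental calls in the hot loop; exact
  equality of keys defines score ties.
* SVG meta-plots fix the matplotlib hash salt and strip the date, so
  identical specs produce byte-identical files.

## Known limitations

* The KS p-value bound is anti-conservative for tiny m; within-search
  ranking is unaffected (monotone), and end-to-end significance is
  permutation-based.
* The greedy search offers no optimality guarantee; top-N restarts mitigate
  but do not eliminate local optima.
* The permutation test's small-N behaviour is tie-dominated (see above):
  at N ≈ 50 with ~10³ features, reported significance is mildly
  anti-conservative by construction of the strictly-better convention.
* Scoring is limited to KS and Wilcoxon; mutual-information-style scores
  are an extension point, not implemented.
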