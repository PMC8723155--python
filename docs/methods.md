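# Methods

## Model and assumptions

The package tests, at every branch point of a hierarchical clustering, whether
the left and right subclusters differ in a clinical outcome. The approach is
assumption-free about the data-generating process: it operates only on a
sample-distance matrix and on two-group tests. Its one structural assumption
is that the dendrogram's splits partition the cohort into cascaded,
non-overlapping groups, which makes the tests at different splits independent
and justifies a Bonferroni family-wise correction whose factor is the number
of tested splits. The correction is deliberately *not* additionally scaled by
the number of outcomes: each outcome is treated as its own family of *m*
independent split tests (an `across_outcomes` flag adds the outcome factor
for users who want a single global family).

## Tree construction and cluster numbering

Clustering uses `scipy.cluster.hierarchy.linkage` on a condensed distance
vector; any scipy metric and the ward/average/complete/single/weighted/
centroid/median linkages are accepted, as are externally computed distance
matrices and merge tables (so similarity-network-fusion-style matrices plug
in without the package implementing them). scipy's nearest-neighbor-chain
agglomeration is deterministic for fixed input, which is the reproducibility
contract; its internal tie-breaking is used as-is. Merge heights are checked
for monotonicity and a violation warns rather than errors, because centroid
and median linkages can legitimately produce inversions.

Splits are ranked by decreasing merge height (ties: the split whose parent
cluster was created later in merge order first). The rank-*k* split's
children are clusters 2*k* and 2*k*+1, the cohort is cluster 1, so the top
split always reads "clusters 2 versus 3" and the next "4 versus 5". The
orientation convention — the side containing the sample with the smallest
input position is "left" — is arbitrary but fixed, so results and plots are
reproducible; no scientific meaning attaches to left vs right.

## Valid pairs and the size threshold

A split is testable when both sides have at least `min_size` samples; the
default is 5% of the sample size. Fractional thresholds are rounded **up**
(ceiling) and the comparison is inclusive (≥), i.e. "at or above the
threshold"; at n = 356 the default resolves to 18. A threshold above n/2
yields zero valid pairs with a warning, not an error. The Bonferroni factor
*m* is fixed by tree + threshold before any testing, and is not reduced when
individual (pair, outcome) tests are skipped for missing data.

## Outcome typing and the tests

Column types are inferred: boolean/text columns and numeric columns with at
most 5 distinct values are categorical (the cutoff is a heuristic for
integer-coded factors such as diabetes status; it is overridable per column),
other numeric columns are continuous, and survival outcomes must be declared
as (time, event) pairs since they cannot be inferred from a single column.
Explicit declarations always win.

* **Categorical — Fisher's exact test** on the levels × {left, right} table.
  2×2 tables use `scipy.stats.fisher_exact` (two-sided). Larger r×2 tables
  are evaluated by exact enumeration of all tables with the observed margins
  (probability mass summed over tables no more probable than the observed
  one, with a 1e-9 relative tie tolerance); when the enumeration would exceed
  5·10⁵ candidate tables the p-value falls back to a Monte-Carlo estimate
  from 20 000 multivariate-hypergeometric draws with a fixed seed that is
  recorded in the result's test name. Levels unobserved after missing-value
  removal are dropped; fewer than 2 remaining levels skips the test.
* **Continuous — two-sample t-test.** Welch (unequal variances,
  Welch–Satterthwaite df) by default, since subclusters have no reason to
  share a variance; a pooled-variance option exists. Both sides constant and
  equal skips the test (the statistic is undefined); fewer than 2 values on a
  side skips.
* **Survival — log-rank test** via `lifelines.statistics.logrank_test`
  (χ² = (O−E)²/V over pooled event times, 1 df). No events in the pooled
  data, or an empty side, skips. The test suite cross-checks lifelines
  against an independent hand-rolled O/E/V accumulator.
* **Custom tests** receive (left member IDs, right member IDs, column) and
  must return (statistic, p); a p outside [0, 1] is an error naming the
  outcome.

Missing outcome values are dropped per (pair, outcome) test and the per-side
n after removal is reported. Every (valid pair, outcome) combination emits
exactly one row, `ok` or `skipped: <reason>`, so downstream code can rely on
the cardinality.

## Multi-omics fusion

Per-block distances are divided by their maximum off-diagonal entry and
summed. Consequences used as test invariants: a single fused block has
maximum exactly 1; the fusion is invariant to positive per-block rescaling
and to block order; max(D) ≤ l with equality iff one sample pair attains the
maximum in every block. Blocks are aligned by sample ID (positional arrays
require an explicit flag), an all-zero block is an error (its maximum cannot
divide), and blocks are unweighted.

## Visualization

The tree is drawn from its own layout (leaf x-positions from the scipy leaf
order, internal nodes at the midpoint of their children) rather than via
`scipy.dendrogram`, so every split's coordinates are known and returned as
metadata; tests assert annotation counts and alignment against that metadata
instead of parsing images. Valid splits carry white circles; associations
with p_adj ≤ `p_threshold` (default 0.05) are labeled at their split. The
overview stacks tree, one track per outcome (continuous: value colormap with
min/max at the endpoints; categorical: discrete color bands; survival: time
colormap with event dots) and the data heatmap, all sharing the leaf order;
red dots in the tracks sit at the x-position of their significant split.
Detail plots are boxplots (continuous), stacked proportion bars
(categorical) and Kaplan–Meier curves (survival — a presentation choice; the
test itself is rank-based). SVG output is byte-reproducible (fixed
`svg.hashsalt`, no timestamp metadata); PNG is available through the same
calls.

## Synthetic cohorts

`fixtures` generates the study conditions for testing: nested binary planted
groups with a per-split mean shift δ_x (in SD units, applied ±δ_x/2 on a
designated feature subset) over unit Gaussian noise, and outcomes tracking a
chosen split — continuous (shift δ_y in SD), categorical (log-odds shift) or
survival (exponential times with the given hazard ratio between sides and
independent uniform censoring, default fraction 20%). A single seed fixes all
randomness. The reference design used by the recovery checks is n = 200,
δ_x = 2 SD on 20 of 100 features, δ_y = 1.5 SD. The generator deliberately
omits features of real omics data — correlated features, batch effects,
heavy tails, informative missingness — so passing tests demonstrate correct
mechanics and calibration under the stated model, not performance on real
cohorts.

## Numerical and scale choices

* Exact-test tie handling: tables with probability within 1e-9 relative of
  the observed table count as "as extreme".
* Fused matrices are symmetrized to machine precision after summation;
  symmetry of inputs is checked at 1e-8.
* Null calibration uses 200 simulations (n = 100, 20 features) and bounds the
  per-outcome family-wise rate by 0.05 + 3 binomial SEs; recovery uses 100
  seeds of the reference design. These sizes give stable rates while keeping
  the default suite quick.
* All exports use the 1-based heap-style cluster IDs described above.

## Limitations

* Inference is two-group and unadjusted: no covariate-adjusted models. The
  joint visualization of outcomes along the tree is the intended way to
  inspect confounding.
* Bonferroni is the documented correction; Benjamini–Hochberg or similar are
  out of scope.
* No bootstrap/consensus assessment of cluster stability, and no
  implementation of similarity network fusion or multiple kernel learning
  (their output matrices are accepted as inputs).
* The r×2 Monte-Carlo Fisher fallback is an estimate, not an exact p; its
  seed is recorded so runs are reproducible.
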