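# Methods

## Model and procedure

`kbinet` analyses group-wise metabolic brain networks. The input for one
diagnostic group is a K × N table of mean standardized uptake values (SUV):
K subjects, N atlas regions (ROIs). The analysis pipeline is:

1. **Network construction.** Edge weight w_ij = 1 − r_ij, where r_ij is the
   across-subject correlation of ROI uptake (Pearson default; Spearman and
   Kendall as rank-based drop-ins). Weights lie in [0, 2]: 0 for perfect
   coupling, 2 for perfect anti-coupling. Each edge carries the two-sided
   p-value of the zero-correlation test; for Pearson this uses the exact
   t-statistic r·√((K−2)/(1−r²)) with K−2 degrees of freedom, and the rank
   methods use their standard approximations (scipy).
2. **Graph filtration.** The distance network induces a nested family of
   binary graphs indexed by λ (admit edges with w ≤ λ). Zeroth persistent
   homology tracks connected components; merge heights equal single-linkage
   dendrogram heights, equivalently sorted minimum-spanning-tree edge
   weights (computed with scipy's hierarchical linkage — O(N²), exactly
   equivalent to sweeping every threshold with union-find, which the test
   suite verifies). λ₀ = 0 is prepended; ties are kept as repeated values.
3. **Indices.** BNP = |OLS slope| of the Betti number plot sampled at the
   distinct critical values (right-continuous step convention); the IPF plot
   applies the definition in the README to the sorted multiset of critical
   values; SIP = |OLS slope| of the IPF plot; KBI compares a network's IPF
   plot to a control-group template with the persistence-weighted Gaussian
   kernel.
4. **Classical indices.** Characteristic path length (mean shortest-path
   distance over connected ordered pairs; disconnected pairs excluded),
   network diameter (max finite distance), and modularity, all computed on
   the network after Bonferroni edge filtering (keep edge iff
   p < α / (N(N−1)/2), strict). Persistence indices deliberately use the
   *unfiltered* network — the filtration already sweeps all thresholds.
5. **Inference.** Group-wise permutation test: pool subjects, reassign to
   pseudo-groups of the original sizes, rebuild both networks, recompute the
   index; p = fraction of permuted absolute differences ≥ the observed one
   (10,000 permutations by default).
6. **Classification.** Per group, resample ⌊K/2⌋ subjects without
   replacement n times (default 5000), rebuild the network each time and
   record the index; classify the resulting univariate features with a
   linear-kernel SVM (C = 1) under leave-one-out cross-validation, features
   standardized on each training fold only. Reported: accuracy,
   sensitivity, specificity, ROC/AUC (macro-averaged one-vs-rest for three
   classes).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| p | 5 | KBI persistence-weight exponent; larger p sharpens the split between long- and short-lived features |
| σ | data-driven | Gaussian bandwidth: median over IPF plots of the within-plot median pairwise point distance |
| C | data-driven | persistence-weight scale: (median over plots of the within-plot median positive λ)^(−p), so a typical λ gets arctan(1) ≈ π/4 |
| α | 0.05 | Bonferroni significance level for edge filtering before CPL/ND/Mod |
| n_perm | 10,000 | permutation count; Monte-Carlo SE of p ≈ √(p(1−p)/n_perm) |
| n, rate | 5000, 0.5 | resample count and retained-subject fraction per resample |

The λ₀ = 0 anchor point is excluded from both kernel medians: it is a
bookkeeping origin, not a topological event, and including it would make C
infinite whenever the median λ is dominated by zeros. Its KBI term
vanishes anyway through arctan(0).

When one analysis compares several networks with KBI, the kernel parameters
are computed once from all IPF plots entering that analysis (template
included) and held fixed — as is the template itself — across permutations
and resamples. Recomputing either inside a permutation would leak group
labels into the null distribution and make index values incomparable
across iterations.

## Numerical conventions

- Correlation distances are clipped into [0, 2] with tolerance 1e−12;
  larger excursions raise an error rather than being silently repaired.
- Permutation p-values count ties as "≥ observed" with a 1e−12 tolerance so
  that a permutation reproducing the observed grouping cannot drop below
  the observed statistic through floating-point noise. An add-one
  smoothed estimator ((count+1)/(n_perm+1)) is available where exact zeros
  are unwanted.
- Slope indices require at least two distinct λ values; an all-tied
  filtration raises an error instead of returning an arbitrary slope.
- KBI pairs points by λ-sorted index; both plots must have equal
  cardinality (always true when both derive from the same atlas).
- Modularity uses the proportion formula Mod = Σ_i [c_ii − (Σ_j c_ij)²],
  where c is the module-level proportion matrix of total edge weight
  (within-module weight counts toward c_ii; cross-module weight splits
  evenly between c_ij and c_ji). Partitions come from two agglomerative
  heuristics — seeded Louvain and greedy CNM (networkx) — plus the trivial
  single-module partition; the best-scoring partition under the proportion
  formula is returned, which is deterministic for a fixed seed. This
  formula is bounded above by 1. Edge weights are used as given (distance
  convention, w = 1 − r); the correlation-as-weight convention can be
  obtained by building the network from r directly, but shortest-path
  indices then lose their interpretation and negative weights are rejected.
- Filtered networks represent removed edges as *absent* (a mask), never as
  zero-length edges; retained weights are unchanged.

## Synthetic cohorts

The generator draws subject rows from a multivariate normal with a
block-structured correlation target and truncates at zero after shifting by
a baseline. Defaults: 280 subjects, 90 ROIs in 15 equal blocks,
within-block correlation 0.7, cross-block correlation 0.5 × coupling_scale,
baseline 5, residual SD 1. The block structure emulates functional
subsystems whose internal coupling is strong and relatively preserved,
while `coupling_scale` modulates *cross-module integration* — the component
of metabolic connectivity that declines along the clinical gradient from
controls through MCI to AD. Weak integration pushes cross-module merge
heights toward their ceiling, which simultaneously flattens the IPF plot
relative to its λ range (lower SIP) and moves the plot away from a
strongly-coupled template (lower KBI); this is the mechanism by which the
generator reproduces the low < mid < high ordering of both indices.
Scaling *all* correlations uniformly cannot reproduce that ordering: a
uniform scaling of merge heights leaves the OLS slope of IPF against λ
invariant, and a uniform downward shift provably lowers mean(λ)/max(λ),
so the slope would move in the opposite direction. Cross-module scaling is
therefore the generator's definition of integration strength.

What the generator does **not** emulate: spatial structure and
partial-volume effects, scanner and reconstruction noise, inter-subject
global-uptake variation (all rows share one baseline), heavy-tailed or
skewed uptake distributions, and hub-like degree heterogeneity. Passing
tests therefore demonstrate that the pipeline recovers the designed
covariance-level group differences at realistic sample sizes — not that it
would detect disease effects in any particular real cohort.

With baseline = 5 and unit residual SD, zero-truncation affects ~10⁻⁷ of
values, so the realized correlations are unbiased for practical purposes.

## Design choices

- **Group-wise networks only.** One network per group, built from all its
  subjects; subject-level networks are out of scope.
- **Template.** The KBI template is the IPF plot of the control group's
  network built from all control subjects, and is held fixed wherever the
  control group itself enters a permutation or resampling scheme.
- **Two-sided statistic.** The permutation statistic is the absolute index
  difference; group order is arbitrary, so a signed test has no natural
  direction.
- **Resampling without replacement.** Each resample removes half the
  subjects; a bootstrap (with replacement) would duplicate subjects and
  distort across-subject correlations.
- **One seed per run.** All CLI randomness flows from a single `--seed`
  through named child streams (simulation, permutation, per-group
  resampling), so any stage can be reproduced independently.

## Problem sizes used in the checks

The validation suite exercises exact oracles at small N (union-find sweeps
at N ≤ 12, Floyd–Warshall at N ≤ 15, exhaustive partition search at N = 8,
exhaustive permutation enumeration at 3+3 subjects) and simulation-based
checks at moderate scale (ordering recovery at 200 subjects/group × 90
ROIs × 100 seeds; null calibration with 200 tests × 500 permutations;
classification with 200 resampled networks per group and 500 samples/class
for the Bayes-rate comparison). These sizes give stable Monte-Carlo
estimates for every asserted tolerance while keeping the default test run
fast enough for routine development.

## Known limitations

- Only zeroth homology (connected components) is analysed; cycles and
  higher-order structure are invisible to all indices here.
- The Bonferroni edge filter can disconnect a network; CPL/ND then silently
  ignore disconnected pairs, matching their definitions, but values are not
  comparable across networks with very different edge counts.
- Kendall networks are O(N² K log K) and noticeably slower than Pearson or
  Spearman at atlas scale.
- The modularity heuristics guarantee no global optimum; the test suite
  bounds their gap (≥ 95% of the exhaustive optimum at N = 8), but larger
  graphs rely on the heuristics' usual behaviour.
- `read_suv_table` loads the whole table into memory; tables are assumed to
  be cohort-sized (hundreds of subjects), not biobank-sized.
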