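# Methods

## Enrichment model

For a ranked gene list of length *N* (descending by the ranking metric,
ties broken by gene identifier so the order is reproducible across
platforms) and a gene set *S* of size *N_H* after intersection with the
dataset, the running sum increases by |r_j|/N_R at members (N_R the sum of
|metric| over members) and decreases by 1/(N − N_H) at non-members. Both
cumulative terms reach 1, so the walk returns to 0 at the end of the list
(asserted to 1e-12 in tests). The enrichment score is the deviation of
maximal absolute value with its sign; when a positive and a negative
extreme tie in magnitude the earlier list position wins. The weight
exponent on |r| is fixed at 1 — no exponent parameter is exposed. If all
member metric values are exactly zero (possible only for degenerate
inputs) the hit weights fall back to the unweighted 1/N_H walk.

Significance uses phenotype permutation by default: the label vector is
shuffled (group sizes preserved automatically), every gene is re-ranked
and the ES of every set recomputed. One matrix of permuted label vectors
is drawn upfront from the run's seed and shared by all gene sets; each
set's null therefore comes from the same permutations, re-ranking is done
once per permutation rather than once per set × permutation, and results
are independent of the order of the collection and of the worker count
(workers partition permutations; chunks are concatenated in order). Gene
permutation (random membership on the fixed observed ranking) is available
but secondary, since it destroys gene-gene correlation.

NES divides ES by the mean magnitude of same-sign null ES — the
convention of the original GSEA implementation, adopted because the size
adjustment is otherwise under-specified; null samples are rescaled
sign-wise the same way. The nominal p-value is computed on the same-sign
portion of the null NES only:
p = (1 + #{|null| ≥ |NES|, same sign}) / (1 + #{same sign}), with add-one
smoothing so p = 0 never occurs. When no null sample shares the observed
sign the NES is undefined and p is reported at the permutation resolution
1/(n_perm + 1) with a flag; when fewer than 10% of permutations share the
sign a warning notes that the p-value is coarse (this regime is typical
for the MSD metric, whose sign distribution collapses under label
permutation, and such metrics need far more permutations for stable
p-values). A gene-set size filter of 15 ≤ N_H ≤ 500 after intersection is
applied by default, mirroring common GSEA practice; it is fully
overridable, and the benchmarking experiments in this package's own tests
run with set sizes that pass it.

## Ranking metrics

With x̄_g, s_g, n_g the mean, sample sd (n−1 denominator) and size of
group g (group 1 = first label encountered in the phenotype file; SoR is
the one metric whose raw value depends on that convention, which is why it
is documented here):

- **T-test**: Welch form (x̄1 − x̄2)/√(s1²/n1 + s2²/n2).
- **MWT, |MWT|** (moderated Welch t): (x̄1 − x̄2)/se_m with
  se_m² = (d0·s0² + dw·sw²)/(d0 + dw), where sw² = s1²/n1 + s2²/n2 is the
  per-gene unpooled squared standard error and dw its Welch–Satterthwaite
  df. The prior (s0², d0) is estimated across genes by the method of
  moments on log variances (digamma/trigamma matching with a Newton
  trigamma-inverse), the standard empirical-Bayes variance-moderation
  estimator. When the across-gene dispersion of log variances does not
  exceed its sampling expectation, d0 = ∞ and se_m² = s0² exactly; the
  d0 → 0 limit recovers the Welch t. At least 10 genes with positive
  variance are required to fit the prior.
- **MSD** (minimum significant difference): the two-sided 95% t-interval
  of the mean difference on the log scale; the metric is CI_left when
  logFC > 0, else −CI_right, so negative values mean the interval contains
  zero. Pooled-variance df (n1 + n2 − 2) by default, Welch df by option;
  the confidence level is configurable.
- **S2N, |S2N|**: (x̄1 − x̄2)/(s1 + s2).
- **WAD, |WAD|**: (x̄1 − x̄2)·w with w = (x̄ − min)/(max − min), x̄ the
  per-gene average of the two group means and min/max taken across genes.
- **Difference / Ratio / log2(Ratio)**: x̄1 − x̄2, x̄1/x̄2 and its log2.
  Ratios with a zero group-2 mean (and log-ratios of non-positive ratios)
  are set to 0 — mid-list — and logged; expression values are assumed
  log-scale, where such cases are rare.
- **FCROS**: per gene, all k = n1·n2 pairwise log fold changes
  (group-1 sample minus group-2 sample) are formed and their symmetric
  10%-truncated mean taken (total 10%, i.e. 5% per tail — the trimmed-mean
  convention of the numerical environment the statistic is usually run
  in). With k < 3 truncation is skipped with a warning. A
  `variant="rank"` switch provides the rank-averaging form of the original
  fold-change rank-ordering statistic (per-comparison gene ranks averaged
  and scaled to (0, 1)).
- **SoR**: sum of combined-sample midranks over group-1 samples.
- **BWS** (Baumgartner–Weiss–Schindler): B = (B1 + B2)/2 where B_g
  averages the squared deviations of the group's sorted combined-sample
  ranks from their null expectation, weighted by the null variance term.
  Midranks handle ties; the statistic is nonnegative and invariant to
  strictly monotone transforms of the data.
- **ReliefF, ReliefF_ranked**: deterministic full pass over all samples
  (t = n, no instance sampling, for reproducibility); per instance the K
  nearest same-class and other-class neighbours under Manhattan distance
  on range-normalised features; each gene's weight accumulates
  (miss − hit) normalised distance contributions scaled by 1/(tK) and the
  miss-class prior P(c)/(1 − P(class)), which is 1 for two classes.
  Weights lie in [−1, 1]. K defaults to 10 capped at (smallest group − 1);
  an explicit K at or past the group size is rejected with a suggestion.
  The ranked variant takes tied ranks of the weights after snapping them
  to 12 decimals, so weights that differ only by floating-point
  cancellation noise rank as ties. Constant genes have zero range and are
  excluded from distances (contribution 0).

**Degenerate variances.** Constant genes would put a zero in several
denominators. Rather than dropping them — which would change N between
metrics and break comparability of the enrichment walk — a floor of
1e-8 × sd(all values) replaces zero denominators, keeping every gene in
the list with a finite value.

A user-supplied callable `(matrix, labels) -> per-gene values` plugs into
the same dispatcher and enrichment pipeline unchanged.

## Evaluation framework

- **Surrogate sensitivity** is the nominal p of a designated target set;
  across datasets, overall sensitivity = 1 − π̂0 of those p-values.
  Storey's π̂0 uses the fixed-λ counting form #{p > λ}/((1 − λ)m) with
  λ = 0.5 (deterministic and conservative); the cubic-smoother
  extrapolation to λ → 1 is available as an option.
- **FPR**: each replicate collection permutes the phenotype labels of the
  original dataset, runs the full GSEA (with its own, nested permutation
  null seeded independently) and records the fraction of sets with
  p < α = 0.05; the overall score is |mean FPR − 0.05|. Collection
  permutations are drawn with replacement from the permutation space —
  collisions are negligible at realistic sample sizes.
- **Clustering**: each score column is min-max normalised across metrics;
  k-means (Euclidean, 50 restarts, seeded) is run for k = 2..8 and the k
  with the largest Dunn index (minimal inter-cluster distance over
  maximal intra-cluster diameter) is kept, ties towards fewer clusters.
  Scorecards are processed in metric-name order so the outcome cannot
  depend on input order. Compute time can be excluded to cluster on the
  two statistical criteria alone. Timing numbers are wall-clock seconds
  of the ranking step only and are explicitly non-portable; no test
  asserts them.
- **Robustness**: stratified subsampling (group proportions preserved
  within one sample, at least two samples per group) at a grid of sizes,
  repeated with independent sub-streams per size × replicate; each
  replicate records target p and optionally an FPR estimate.
- **Normality diagnostics**: Lilliefors test per gene per group; a gene
  counts as non-normal when either group rejects (configurable to a
  pooled-residual single test). Groups of fewer than 4 samples are
  skipped and logged.

## Synthetic data

The generator emulates a preprocessed two-group microarray study: per-gene
baselines uniform on [4, 14] log2 units (the plausible intensity range of
log-scale arrays), i.i.d. noise of sd 1.0 by default, and gene sets drawn
at random. Defaults (1,000 genes, 15 + 15 samples, 100 sets of 20, effect
size 2.0 log-units) are the fixture scale used throughout the tests: large
enough for stable rank statistics, small enough that full
permutation-GSEA benchmarks run in seconds. A `contamination` fraction of
genes receives standardised shifted log-normal noise (right-skewed, mean
0, sd 1) to emulate the non-normally distributed genes that real arrays
show; `rho` adds exchangeable within-set correlation via a shared
per-set factor (sets sharing genes share the first set's factor — an
approximation adequate for the low-overlap collections generated here).
Signal fixtures shift target-set genes by +δ in group 2, with a
configurable fraction shifted −δ to emulate pathways containing both up-
and down-regulated genes; target sets use disjoint genes and null sets
draw from the remaining pool, so non-target sets stay exactly null. Every
generative shift is returned in a truth table. The RNG is split into
independent noise/set/shift streams, so a zero-effect signal fixture is
bitwise identical to the null fixture of the same seed.

What the generator does **not** emulate: probe-level structure, batch and
platform artifacts, mean-variance dependence, heavy-tailed sample
outliers, and realistic pathway overlap topology. Passing benchmarks on
these fixtures therefore demonstrates the statistical correctness and
calibration of the machinery under its stated assumptions, not
performance on any particular real dataset.

## Numerical and design choices

- Permutation p-values use add-one smoothing; ties (|null| equal to the
  observed value) count towards the numerator, which is conservative.
- Sorting is stable everywhere; gene-list ties break by identifier,
  neighbour-distance ties in ReliefF by sample index.
- The trigamma inverse for the MWT prior uses Newton iterations to a
  relative tolerance of 1e-10.
- π̂0 is clipped to [0, 1]; FPR replicates are plain binomial fractions.
- Probe collapsing keeps the chosen probe's values verbatim (no
  averaging); the `min_pvalue` strategy defaults to Welch t p-values
  computed across all samples' phenotypes, not the ranking metric's own
  permutation p, which would be circular and expensive.
- The "custom gene set database from a spreadsheet" pathway is supported
  as delimited text (CSV/TSV export, two columns set_id/gene) rather than
  binary spreadsheet parsing.

## Known limitations

- Two-phenotype designs only: no multi-class, continuous-phenotype
  (correlation) or paired rankings.
- No FDR q-values across sets (nominal p is the benchmarked quantity) and
  no leading-edge extraction.
- MSD's p-values under label permutation are coarse at ordinary
  permutation counts (see above); the engine warns rather than corrects.
- ReliefF cost grows with samples² × genes; it is the slowest metric by a
  wide margin, which the scorecard's timing column is designed to expose.
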