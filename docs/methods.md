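# Methods

`mirmeta` implements an integrated multi-step selection pipeline for
multi-miRNA cancer biomarkers: heterogeneous per-study ranked lists are
combined by robust rank aggregation, fragile candidates are removed by a
leave-one-out stability filter, survivors are validated on an independent
tumor/normal expression cohort, screened for a pan-cancer sign-pattern
that is unique to the index cancer, tested for clinical associations and
diagnostic value, and finally linked to target genes supported by several
prediction sources, experimental (CLIP-derived) evidence, differential
expression and expression correlation.  Because the pipeline's original
inputs are external repositories, every stage here runs against synthetic
generators with planted ground truth; the generators reproduce the
statistical structure of those inputs, not their content.

## Rank aggregation

Each study contributes an ordered significant-miRNA list drawn from a
platform of N probes.  Lists are first prioritized by their evidence:
ascending p-value when every entry carries one, otherwise descending
|log2 FC|, otherwise the list is taken as pre-ranked; ties break by input
order (stable sort) for determinism.  A miRNA at 1-based position k gets
normalized rank r = k/N.  The platform size, not the truncated list
length, is the denominator, because significant lists are the top of a
larger assayed ranking (a list-length denominator is available as an
option).

For a miRNA with sorted normalized ranks r(1) <= ... <= r(n) over the n
lists where it appears, the score compares each r(j) with the j-th order
statistic of n independent uniforms:

    p_j = P(U(j) <= r(j)) = sum_{i=j}^{n} C(n,i) r(j)^i (1-r(j))^{n-i}
        = I_{r(j)}(j, n-j+1)            (regularized incomplete beta)

    rho = min_j p_j,   corrected p = min(1, n * rho).

The Bonferroni factor n accounts for minimizing over the n order
statistics.  By default n is the number of lists where the miRNA is
present (the rank vector is defined only on those lists); a strict mode
instead treats absences as worst-rank 1.0 with n equal to the total list
count.  The two conventions differ in how severely they punish absence;
the default follows the rank-vector definition, the strict mode is kept
for sensitivity analysis.

Calibration caveat: with complete lists (every list ranks the whole
platform) the corrected p is a conservative p-value, and the null
calibration checks run in exactly that regime.  With truncated
significant lists the present-only convention is anticonservative — a
miRNA appearing once near the top of a short list is nominally
significant.  That is intrinsic to aggregating truncated lists and is
precisely why the pipeline does not stop at aggregation: the stability
filter and the independent expression validation exist to strip such
single-study artifacts.

An optional permutation test re-draws every list uniformly over its
platform (same lengths).  Conditional on a miRNA being present in a list
of length L from platform N, its null rank is uniform on {1..L}/N; rho is
recomputed per replicate from independent draws per miRNA and
p = (1 + #{null rho <= observed}) / (B + 1).

## Leave-one-out stability

With K lists, each iteration drops one list and re-aggregates; a miRNA's
final stability p is the mean of its corrected p over iterations, and it
is kept when that mean stays below alpha = 0.05.  A miRNA absent from
every remaining list scores p = 1 for that iteration — the harshest
choice that keeps the mean a probability, which is what makes the filter
lethal for single-study signals: a signal carried by one of 11 lists has
mean at best (10 * p_small + 1)/11 ~ 0.09 > 0.05.  `enumerate` mode
weights the K configurations equally and is the exact expectation of
`sampled` mode (T uniform drops, default T = 10,000); tests and drivers
use `enumerate` where determinism matters.  The sampled estimator's
Monte-Carlo error is sqrt(Var_config / T), so for candidates whose
per-configuration p's are nearly constant (every robust signal) the two
modes agree to well under 0.005 at T = 10,000; for miRNAs whose
configuration p's mix values near 0 and 1 the standard error is ~0.003
and occasional larger gaps are expected — the convergence checks
therefore assert tight gaps for the planted signature miRNAs and the
mean gap across all miRNAs.

The meta-signature is the intersection: aggregate-significant AND stable.

## Expression validation

Normalized (RPM/RPKM) values are log2(x + 1)-transformed for testing;
fold changes are ratios of group medians on the normalized scale
(stabilizer epsilon = 0 by default, with explicit warnings for zero
medians).  Candidates are tested tumor vs normal with the two-sided
Wilcoxon rank-sum test (exact enumeration for pooled n <= 20 without
ties, tie-corrected normal approximation with continuity correction
otherwise; an all-identical pooled sample returns p = 1), corrected by
Benjamini-Hochberg across the candidate panel.  The joint rule is
symmetric: a candidate validates as up when FDR < 0.05 and FC >= 2, as
down when FDR < 0.05 and FC <= 0.5.  The symmetric reading of the "FC
cutoff 2" is deliberate — it is what rejects a down candidate at FC 0.52
while accepting one at 0.41.  Setting both cutoffs to 1 disables the
filter.

## Negative-binomial differential expression

Raw counts are modeled as NB with variance mu + alpha mu^2.  Sample
depths are removed by median-of-ratios size factors.  Per-gene
dispersions are estimated by method of moments on normalized counts
(pooled within-group variance), then shrunk geometrically (weight 0.3 on
the per-gene estimate) toward a mean-dispersion trend fitted by linear
regression in log-log space.  The trend-plus-shrinkage step is this
package's deterministic, desk-scale take on the mean-variance smoothing
idea used by count-based DE tools; it is an approximation, not a
re-implementation of any published tool's numerics.  Group equality is
tested by a two-sided Wald statistic on the difference of group log-means
with delta-method standard errors; a pseudo-mean of 0.5 is added only
when a group mean is zero, which keeps log2 fold changes exactly
invariant to library-size rescaling otherwise.  Significance is
|log2FC| > 1 and BH FDR < 0.1.  All-zero genes are excluded with a
warning.

## Pan-cancer pattern uniqueness

Per cancer type, each panel miRNA is tested tumor vs normal by rank-sum
on the log2 scale, BH-corrected across the panel within that cancer
(the paper-scale panel has 3 members; no cross-cancer correction is
applied), and called up/down by the same symmetric FC-2 rule, otherwise
flat.  Panel members missing from a matrix are called flat with a
warning; cancers with fewer than two normals are flagged low-power but
still called.  A cancer matches a target sign pattern when its calls
equal the pattern on every target miRNA; the pattern is unique when
exactly one cancer matches.

## Clinical associations and diagnostics

Continuous covariates (age, PSA, positive-node count) are tested by
tie-aware Spearman correlation with the two-tailed t-approximation;
two-level strata (Gleason low 6-7 vs high >= 8, node-positive vs
negative, pN0 vs pN1) by rank-sum; covariates with >= 3 observed levels
(race, pT, histology) by tie-corrected Kruskal-Wallis.  Covariates
collapsing to one observed level are skipped with a note.

ROC analysis counts concordant score pairs (ties half):
AUC = (concordant + 0.5 ties) / (n_pos * n_neg), identical to the
trapezoidal area under the full threshold sweep — both routes are
computed and compared in the tests.  Confidence intervals default to
DeLong's asymptotic variance from placement values; a stratified
percentile bootstrap (B = 2000) backs up degenerate AUCs of exactly 0 or
1.  Markers are combined by a maximum-likelihood logistic model fitted
with iteratively reweighted least squares (convergence when the largest
coefficient change < 1e-8, cap 100 iterations); under perfect separation
the fit warns and returns the last iterate, whose score ordering is
still valid for ROC use.  The optimal cutoff maximizes
sensitivity + specificity, with ties broken toward higher specificity
(then the higher threshold) for deterministic output.  The combined
model is evaluated in-sample, mirroring the original procedure; this is
optimistically biased, and an out-of-sample mode is deliberately out of
scope.

## Target integration

Per miRNA: genes predicted by at least 2 of the supplied sources, then
intersected with the validated set and the DE gene set, then filtered by
two-tailed Spearman significance (alpha = 0.05, the conventional default;
the original threshold is unstated) against matched expression.  The
filter is sign-agnostic by default since both correlation signs are
informative in the clustered heatmap; a negative-only mode implements the
canonical miRNA-represses-target expectation.  The retained-genes x
miRNAs Spearman matrix is clustered on both axes by average linkage with
distance 1 - correlation; ids are pre-sorted lexicographically so leaf
orders are reproducible.  Shared targets are the intersection of
retained sets across the panel.  The chain
retained ⊆ overlap ⊆ consensus is asserted structurally on every result.

## Synthetic generators

All generators are pure functions of (spec, seed); a seed is mandatory.

- **Ranked lists**: each study assays a platform-size subset of the
  miRNA universe (planted signal ids are always on the platform, so
  penetrance is the sole absence mechanism); background probes are a
  uniform shuffle.  A signal that penetrates a study (probability =
  penetrance) lands at a position drawn from a Beta distribution with
  mean rank_strength and concentration 20 — small strength means sharply
  top-ranked.  The emitted list is the top fraction of the platform; the
  default significant fraction is 5% of probes (at least 10), since the
  real list lengths are not published.  Platform sizes and per-study
  sample counts follow the 11-study design table.
- **Counts**: NB with variance mu + alpha mu^2, dispersion 0.2 (typical
  bulk RNA-seq), per-feature log-normal baselines around 200, tumor
  means shifted by planted log2 FCs.  The RPM twin rescales every sample
  to 10^6.
- **Clinical**: a Gaussian copula (latent Pearson rho = 2 sin(pi rho_s /
  6)) plants pairwise Spearman targets among markers and continuous
  covariates so they survive the monotone marginal transforms (rounded
  age ~ 60.4 +/- 7, log-normal PSA, Poisson-quantile node counts).
  Categorical strata get configurable location shifts in marker SD.
- **Pan-cancer**: log-normal RPM matrices per cancer; planted calls add
  +/- effect_lfc (default 2.0; the drivers use 2.5 with noise sigma 0.8
  and 60/25 samples per cancer so that flat cancers essentially never
  cross the joint cutoff by chance) to tumor samples, flat plants add 0.
- **Targets**: per miRNA a true pool of 60 genes from a 1000-gene
  universe; each source keeps pool genes with probability source_overlap
  (default 0.8) plus (1-source_overlap)*pool private noise genes, so
  overlap 1 makes sources identical.  Planted anti-correlated genes and
  the optional shared gene are forced into every source, the validated
  set and the DE truth, and their expression is generated at latent
  anti-correlation -0.4 with their miRNA (the shared gene against the
  panel mean).  The returned truth record carries the pools and the DE
  gene set, and the miRNA marker matrix is returned alongside the
  spec'd set collection and mRNA matrix, because the correlation filter
  needs sample-aligned miRNA expression.

What the generators do not emulate: batch effects, platform-specific
probe biases, non-NB overdispersion structure, censored or missing
clinical fields beyond simple absence, and any real dataset's actual
content.  Passing tests therefore demonstrate the pipeline's statistical
correctness and recovery behavior under its own model assumptions, not
performance on real cohorts.

## Problem sizes and numerical choices

The standard scenarios use a 300-miRNA universe for the 11-study
meta-analysis (500 for null calibration), 200 replicates for recovery
rates, B = 1000 permutations, T = 10,000 LOOCV iterations, 2,000 genes x
30+30 samples for DE calibration (50 seeds for power), 19 cancers x 85
samples for the pattern scan, and a 498 tumor / 52 normal cohort for
validation and diagnostics.  Beta tails are evaluated with the
regularized incomplete beta function; Monte-Carlo cross-checks of the
order-statistic tails use 10^5 draws and allow the binomially expected
number of 3-SE exceedances (hard cap 5 SE).  BH adjustment, rank tests
and Spearman p-values come from statsmodels/scipy.

## Known limitations

- Corrected aggregation p-values are not calibrated for truncated lists
  (see above); interpret them as ranking scores there.
- The NB Wald test is asymptotic; for very small groups an exact-style
  test is not provided.
- DeLong intervals are Wald-type on the AUC scale and clip at [0, 1];
  near-degenerate AUCs fall back to the bootstrap.
- In-sample evaluation of the combined logistic score overstates
  out-of-sample diagnostic accuracy.
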