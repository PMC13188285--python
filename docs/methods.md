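# Methods

This note documents the statistical models implemented in `preservstat`,
their assumptions, the defaults and why, the synthetic-data model behind the
test suite, and the numerical choices made where the design was open.

## Study model

A study is a set of samples, each with a *material* (blocking factor: the
source the sample was taken from) and a *treatment* (one of two preservation
methods). The canonical design is M materials × 2 treatments × R replicates;
the defaults throughout are M = 6, R = 5 (60 samples), the typical scale of a
paired-preservation experiment. Treatments are arbitrary strings; every test
takes an explicit (numerator, denominator) pair, with the numerator playing
the "dried" role. Metric cells may be missing (NaN); tests drop samples
missing the tested metric and report how many were dropped, rather than
failing on ragged metadata.

Feature tables are features × samples (classic OTU-table orientation), either
`counts` or `proportions`. Proportion columns sum to 1 (tolerance 1e-9);
abundance-filtered tables are *subcompositions* whose columns may sum to less
than 1, because filtering deliberately does **not** renormalize — retained
values stay interpretable as proportions of the original community.

## Stratified ratio test

Statistic: per-material ratio of treatment means, averaged across materials.
Assumptions: metric values are positive (the statistic and its two-sided
log-scale extremity are undefined otherwise) and the per-material denominator
mean is nonzero. The null permutes treatment labels independently within each
material, preserving group sizes; this breaks any metric–treatment
association while conditioning on material differences and the design.

Choices:

* **Averaging** of per-material ratios is arithmetic by default (the plain
  reading of "average of ratios"); a geometric option is provided because it
  is symmetric under numerator/denominator swap. Only the per-material
  reciprocal identity holds for the arithmetic average.
* **Sidedness** defaults to two-sided on the log scale
  (|ln R_null| ≥ |ln R_obs|); `less`/`greater` one-sided variants are
  available. Ties count as extreme (conservative).
* **Exhaustive mode**: when the number of distinct stratified assignments
  Π_m C(n_m, k_m) is ≤ 1e5, the full null is enumerated and p is the exact
  tail fraction (the observed assignment is one of the enumerated ones, so
  p ≥ 1/N > 0). Otherwise Monte-Carlo assignments are drawn uniformly and
  independently per material, and p uses the add-one estimator
  (b+1)/(N+1), which is always positive and valid.

## Composition consistency (log-r² test)

Within one material, per-feature mean proportions are computed for each
treatment; the statistic is the squared Pearson correlation of the
log-transformed means across features. The null reshuffles treatment labels
among that material's samples only. Extremity is *strictly lower tail*: p is
the probability of a lower r² under the null, so ties (e.g. the degenerate
all-duplicates case where every assignment yields r² = 1) do not count
against the observed value. In exhaustive mode this exact fraction can be 0
(the observed split never counts against itself); the Monte-Carlo estimator
keeps p > 0. This is an intentional property of a strict-tail exact test, not
a bug.

Zero handling: a feature can pass the abundance threshold yet have mean 0 in
one treatment, making log undefined. Default policy `half_min_pseudocount`
replaces zero means by half the smallest nonzero mean of the compared pair of
vectors; `drop` excludes such features instead. The policy used is recorded
in the result. At least 3 usable features and nonzero log-variance in both
vectors are required.

Abundance threshold: default `min_prop = 1e-4` (0.01 %), applied
per-sample — a feature is kept if any compared sample reaches the threshold.
For gene-level tables the convention is `min_prop = 1e-5` (0.001 %) assessed
on *treatment-mean* proportions; both rules are exposed via the
`threshold_filter` mode switch (`per_sample` / `per_group_mean`). Filtered
tables are never renormalized (see above). The same machinery serves
ASV/OTU/genus and KO/KEGG-C tables; feature semantics are opaque to the test.

## Bray-Curtis, PERMANOVA, MMDS

Bray-Curtis: BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on proportion vectors; count
tables are normalized per sample first. Values lie in [0, 1]; both-zero
vector pairs are an error.

PERMANOVA (one-way): SS_total = (1/N) Σ_{i<j} d²ᵢⱼ;
SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²ᵢⱼ; SS_between = SS_total − SS_within;
pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a)); R² = SS_between/SS_total.
Labels are permuted uniformly within the analyzed sample subset (one factor
at a time; per-material or per-treatment questions are asked by subsetting
samples first, not by restricted permutations). Distinct label arrangements
≤ 1e5 trigger exact enumeration. The standardized effect size is defined as
SES = (F_obs − mean F_null)/sd F_null, computed from the same null draws.
Groups of size < 2 are rejected; SS_within = 0 yields F = +∞ with p still
from the permutation count. Default `n_perm = 10 000`.

Metric MDS: the optimization target is raw stress Σ_{i<j}(dᵢⱼ − δ̂ᵢⱼ)²,
minimized by SMACOF iterative majorization (Guttman transform), which makes
raw stress non-increasing across iterations. The first start is classical
scaling (PCoA, negative eigenvalues clipped); the remaining
`n_restarts − 1 = 9` starts are random with scale set to the mean input
dissimilarity. Convergence: relative raw-stress decrease ≤ `tol = 1e-9`
(`max_iter = 1000`). The reported stress is Kruskal stress-1,
sqrt(Σ(d−δ̂)² / Σd²). The embedding is unique only up to rotation,
reflection and translation; tests compare stress and recovered distances,
never raw coordinates.

## Gene-centric profiles

Inputs are declared post-filter: read counts per contig are assumed already
restricted to MAPQ ≥ 30, and PCG→KO hits to E ≤ 1e-10, keeping this module
pure arithmetic (no SAM/HMM parsing). Coverage = count/length; contig
proportions normalize coverage to sum 1 per sample; each PCG inherits its
host contig's proportion and the PCG vector is renormalized to 1; a KO sums
the proportions of its PCGs (no renormalization, so unannotated PCGs make the
KO total fall below 1); a KEGG level-C group sums its member KOs. A PCG with
multiple KO hits contributes its full proportion to each (`all_hits`,
default) or only to its top-ranked hit (`best_hit`); a KO in several groups
contributes to each. The eight non-functional catch-all groups ("brite
hierarchies", "enzymes with ec numbers", "not included in pathway or brite",
"poorly characterized", "general function prediction only", "others",
"unclassified viral proteins", "function unknown") are excluded from group
profiles, matched case-insensitively. The whole pipeline is scale-free in
each sample's read counts.

MAG quality filtering keeps records with completeness ≥ 50 % and
contamination ≤ 10 % (both boundaries inclusive) by default — the standard
medium-quality cut.

## Synthetic-data model

Scalar metrics: value = baseline_m · (δ if dried else 1) · exp(σ·z),
z ~ N(0,1). Metrics are positive and effects multiplicative, matching what
the ratio statistic estimates; with σ = 0 the observed average ratio equals δ
exactly (parameter recovery), and δ = 1 is the exact null. Default baselines
spread over two orders of magnitude (`logspace(1, 3)` across materials),
emulating strong between-material heterogeneity; default σ = 0.3.

Communities: per-taxon base log-abundance ~ N(0,1); per-(material, taxon)
offset ~ N(0, material_divergence); dried samples add `effect_log_fc` to a
fixed random subset (`affected_fraction`) of taxa — fixed per simulation so
the effect is a coherent community-level signal; per-sample replicate noise
~ N(0, 0.1); counts ~ multinomial(depth, softmax). Defaults: 6 materials ×
5+5 samples, 500 taxa, depth 1e5 — the design of the motivating experiment
with richness and depth scaled to desk size. `affected_fraction = 0` with
`material_divergence = 0` makes all of a material's samples exchangeable,
the exact null for all three permutation tests.

What the generator does **not** emulate: PCR/chimera artifacts, taxon-specific
extraction biases, overdispersion beyond the log-normal layer, spatial
sample heterogeneity, or sequencing error. Passing calibration on this model
shows the tests are valid and powered under clean compositional sampling; it
does not certify behavior under real-data artifacts.

## Calibration (computed by tests and scripts/acceptance.py)

Under the null model the three tests are calibrated: rejection rate at
α = 0.05 within [0.035, 0.065] over 1000 replicates (ratio test), and null
p-value KS distance from uniform < 0.08 over 500 replicates for all three.
Power checks: a 4-fold effect on half the taxa is detected (p ≤ 0.05) in
≥ 90 % of replicates by the consistency test; material divergence 3 is
detected in ≥ 95 % by PERMANOVA. Exhaustive and Monte-Carlo modes agree
within binomial error. Simulation sizes in the suite (e.g. 3 materials × 3+3
for null replicates, 50–100 taxa at depth 1e4–1e5) were chosen as the
smallest designs at which these properties are stable.

## Known limitations

* One-way PERMANOVA only; no PERMDISP, so a significant pseudo-F can reflect
  dispersion as well as location differences.
* The consistency test's exact (exhaustive) p can be 0 by construction of the
  strict lower tail.
* No compositional transforms (CLR/ALR) or per-feature differential-abundance
  testing; the consistency statistic is community-level.
* No multiple-testing correction is applied by default across metrics; a
  Benjamini–Hochberg helper is available (`adjust=True` in
  `metric_ratio_summary`).
* Exhaustive enumeration thresholds (1e5 assignments) trade exactness for
  memory/time; above them p-values inherit Monte-Carlo error.
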