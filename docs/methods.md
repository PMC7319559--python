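# Methods

This note documents the statistical models behind `trailkit`, the default
parameters and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions that make runs
reproducible.

## Over-representation analysis

ORA models the overlap $k$ between a test set of size $n$ and a category
of size $K$ inside a universe of $N$ genes as
$X \sim \mathrm{Hypergeom}(N, K, n)$. The reported p-value is the exact
tail: $P(X \ge k)$ for over-representation, $P(X \le k)$ for
under-representation, and the doubled smaller tail capped at 1 for the
two-sided test (a simple, conventional two-sided rule; the doubling choice
matters only for strongly asymmetric nulls). The test set must be a subset
of the universe; categories are intersected with the universe before
testing, so the invariant $0 \le k \le \min(K, n) \le N$ always holds.
The `statistic` column reports $k - nK/N$, the excess over the expected
overlap, purely as a descriptive effect direction.

Assumptions: sampling without replacement from a fixed, correctly
specified universe; genes exchangeable under the null. The choice of
universe is the analyst's single most consequential decision — all
workflows therefore fix it explicitly (all genes with chromatin calls; all
post-filter genes; all matrix genes) rather than defaulting to a genome.

## Running-sum set enrichment

For a ranked list of $N$ genes, the unweighted running sum adds $1/K$ at
each category hit and subtracts $1/(N-K)$ at each miss; the enrichment
score ES is the value at the maximum absolute deviation, so
$\mathrm{ES} \in [-1, 1]$ with $+1$ iff all hits lead the list. Ties in
the maximum deviation resolve to the earliest position. Note one
consequence: when the positive and negative extrema tie exactly in
magnitude (possible on short discrete lists), the sign of ES depends on
that positional tie-break, so the identity ES(reversed list) = −ES holds
exactly only off such ties (the magnitude is always preserved).

The p-value permutes gene labels (equivalently, hit positions)
`n_permutations` times (≥ 100 enforced) and uses the add-one estimator
$(1 + \#\{|ES^*| \ge |ES|\})/(1 + n_\mathrm{perm})$, which is never zero
and slightly conservative. A seed is a required argument of every
stochastic operation. The leading edge is defined as the category hits at
or before the extremum, for both signs of ES — a deliberate
simplification of the sign-dependent convention, recorded here because
tools differ on it.

Weighted (signal-to-noise) increments and sample-label permutation are out
of scope; the unweighted KS-like statistic is the lineage of this tool
family.

## Multiple-testing correction

Bonferroni, Holm (step-down), Benjamini–Hochberg (step-up), and
Benjamini–Yekutieli are computed directly from the textbook order
statistics in vectorized numpy (a microbenchmark showed a general-purpose
library implementation dominated by per-call overhead at this call
volume; the test suite cross-checks all four against statsmodels).
Outputs preserve input order and are clipped at 1; inputs must lie in
(0, 1]. Correction families are always explicit in the workflows:
across categories within a transition edge, within a (super-)cluster,
within a cell, and within a cell group.

## Chi-square group test

The 2×2 test uses the closed form
$\chi^2 = N(ad-bc)^2/((a{+}b)(c{+}d)(a{+}c)(b{+}d))$ with 1 df and **no
continuity correction** — the plain Pearson test. Odds ratios use the
Haldane–Anscombe +0.5-per-cell correction only when a cell is zero. A zero
row or column margin makes the statistic undefined; the low-level function
raises, while the group-characterization workflow records such tables as
non-significant (p = 1) with a warning, since an all-enriched or
never-enriched category is uninformative rather than erroneous there.
The χ² approximation is poor for very small expected counts (< 5); with
typical single-cell group sizes (hundreds of cells) this is not a
practical constraint, and no small-sample fallback is provided.

## Epigenome workflow

Regions per gene: promoter = 2000 bp upstream to 500 bp downstream of the
TSS in transcription direction (a common promoter-window convention),
clipped at coordinate 0; gene body = TSS..TES; enhancers are optional
pass-through intervals. All coordinates are BED-style 0-based half-open,
and a mark is "present" in a region if any merged peak overlaps it by
≥ 1 bp (a configurable minimum).

State assignment uses an ordered rule table, first match wins:

1. promoter H3K4me3 ∧ promoter H3K27me3 → **poised** (bivalent)
2. promoter H3K4me3 ∧ (promoter/enhancer H3K27ac ∨ body H3K36me3) → **active**
3. promoter H3K4me3 alone → **active**
4. (promoter ∨ body) (H3K27me3 ∨ H3K9me3) → **repressed**
5. otherwise → **no_signal**

This encodes the canonical bivalent/active/repressed logic of the five
marks H3K4me3, H3K9me3, H3K27ac, H3K27me3, H3K36me3. Real chromatin
grammar is richer (DNA methylation, open chromatin, signal strength), so
the table is data: users can supply their own ordered rules, and enhancer
clauses can only ever add activating evidence — genes without enhancer
annotation are never penalized.

Transition graphs require both groups to cover the same gene universe
(asymmetric inputs are an error, not silently intersected — an asymmetry
is almost always an upstream bug). Two conservation laws are asserted in
tests: per-group vertex counts sum to the universe size, and outgoing edge
weights sum to their source vertex count. Per-edge ORA uses all genes with
calls as the universe; edges with fewer than 2 members are skipped with a
warning.

## Time-series workflow

The range filter (max − min over time ≥ 1.0 by default, on assumed
log-scale values) implements "remove genes with limited expression
change"; a variance-quantile alternative was considered and rejected as
less transparent for the default.

The default distance is Euclidean between **gradients**
$g_i = (v_{i+1}-v_i)/(t_{i+1}-t_i)$ — parallel curves at different
baselines are distance 0, which matches the biological intent of grouping
co-regulated genes. Euclidean and 1 − Pearson distances and average
linkage are available alternatives; complete linkage is the default
because strict stage-1 clusters should have small diameters.

Cut heights are deliberately **required** parameters: they live on the
data's distance scale, and no universal default exists. The
`linkage_heights` helper exposes the merge-height distribution for
choosing them; the fixture generator additionally derives suggested cuts
analytically from its own planted geometry and noise level (see below).

Two-stage clustering: stage 1 cuts the gene dendrogram at the strict
height; clusters smaller than `min_cluster_size` (default 5 — ORA on
smaller sets is uninformative) are discarded with their genes reported as
unassigned, never silently dropped. Stage 2 clusters the surviving
clusters' mean curves at the super height with the same metric/linkage.
Determinism: genes are sorted lexicographically before clustering so equal
merge heights resolve identically across runs; cluster ids are numbered by
each cluster's lexicographically smallest member.

Super-cluster ordering: "most active point in time" is read as the peak of
the z-scored mean curve (z-scoring prevents amplitude from dominating
timing); ties break by larger membership, then id. This is one reasonable
reading of a loosely specified notion — the ordering is presentational,
not inferential.

Enrichment uses all post-filter genes (assigned + unassigned) as the
universe, per cluster and per super-cluster.

## Single-cell workflow

Cell filtering provides two proxies: cells with fewer than `min_genes`
(default 200) detected genes approximate empty droplets/wells, and cells
whose total count exceeds median + 3 MAD approximate doublets
(`max_count_mads=inf` disables). These are declared, simple substitutes
for the richer QC menus of dedicated single-cell suites. Normalization is
log-CPM-style: $\log(1 + c \cdot s / \mathrm{total})$ with scale
$s = 10^4$, depth-invariant by construction.

A cell's "expressed set" is its nonzero genes by default (the least
arbitrary reading of per-cell activity in sparse count data); a `top_k`
alternative on normalized values (ties lexicographic) is exposed. Per-cell
ORA tests each category against the **global** background (all matrix
genes) — a cell-specific background would conflate detection depth with
biology; this choice is documented rather than claimed canonical.
Enrichment calls use BH-adjusted p ≤ α (default 0.05) within each cell.

Group characterization fills, per (group, category), the table
a = enriched in group, b = not enriched in group, c = enriched outside,
d = not enriched outside — so a+b+c+d is always the number of cells — and
applies the χ² test, BH across categories within each group; significant
categories are called predominantly active (OR > 1) or inactive (OR < 1).
Dimensionality reduction, graph clustering, and pseudotime are consumed as
precomputed annotation columns only.

## Synthetic fixtures

All generators flow their randomness from one seed through named
substreams (CRC-32 of the stream name mixes into the generator seed), so
adding an output never shifts another's bytes; fixed seed ⇒ byte-identical
output files.

**Epigenome**: genes on one chromosome, 20 kb apart, alternating strands;
per gene and group a uniform target state; marks placed as 100 bp promoter
peaks exactly as the default rule table requires (active: H3K4me3+H3K27ac;
poised: H3K4me3+H3K27me3; repressed: H3K27me3; no_signal: nothing). By
construction, state assignment recovers the truth exactly — this fixture
validates plumbing and the conservation laws, not rule-table robustness to
ambiguous mark combinations.

**Time series**: grid 0–24 h in 2 h steps (13 timepoints, the sampling
density of an activated T-cell time course). Super-group templates are
Gaussian bumps (amplitude 5, width 1.5 h, peaks evenly spaced across the
grid); sub-cluster variants scale amplitude by 1 + 0.25·j, because an
additive offset would be invisible to the gradient metric; gene rows add
i.i.d. Gaussian noise, default sd 0.5 = 10% of amplitude. Suggested cuts
come from the planted geometry and the noise model, not from clustering
output: a gradient component has noise variance $2\sigma^2/\Delta t^2$,
giving a typical same-cluster distance
$d_w = (\sqrt2\,\sigma/\Delta t)\sqrt{2(T-1)}$; the strict cut is
$1.8\,d_w$ (complete-linkage diameter allowance), floored at half the
smallest within-super template distance so the noiseless case still
separates sub-clusters; the super cut is the midpoint between the strict
cut and the smallest between-super template distance. If noise is too
large for that window to exist, the generator refuses rather than emitting
an unrecoverable fixture.

**Single cell**: default composition mirrors a three-age-group microglia
atlas (3 mo: 2219, 18 mo: 1998, 24 mo: 4113 cells — 8330 total); each
group gets one disjoint planted category (25 of 500 genes) expressed per
cell with probability 0.9 in its group and 0.1 elsewhere; background genes
at 0.1; expressed entries draw 1 + Poisson(1) counts. Bernoulli expression
with a single background rate does **not** emulate real scRNA-seq
overdispersion, library-size gradients, batch effects, or
dropout-expression coupling — recovery results on this fixture demonstrate
the statistical machinery, not robustness to those artifacts.

## Problem sizes used in the standard checks

The repository's verification runs use: exhaustive ORA enumeration up to
N = 12 (3094 tail comparisons); 1000 random 2×2 tables; 10⁴ random
p-vectors; 5000 genes × 2 groups for chromatin-state recovery; 3 super
× 2 sub × 30 genes for time-series recovery (ARI vs planted labels); and
3 × 100 cells × 500 genes for single-cell recovery. These sizes give
stable results at interactive runtimes.

## Known limitations

- Only ORA and the unweighted running-sum statistic are implemented; the
  correction and enrichment registries are the extension points.
- The chromatin rule table is knowledge-based and coarse; no signal-level
  (bigWig) or HMM-based state inference.
- No missing-value handling in time-series matrices; no spline/ANOVA
  differential time-course testing.
- Per-cell ORA treats genes as independent; co-expression inflates
  significance for correlated categories, as in all ORA-based per-cell
  scoring.
- Identifier handling is a single optional mapping table; no automatic
  namespace detection.
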