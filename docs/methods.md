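# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage of the pipeline, what the synthetic cohort
does and does not emulate, and the known limitations.

## Coordinates and conventions

All intervals are 0-based half-open `[start, end)` in memory and BED-style
on disk. Touching intervals (`a.end == b.start`) merge into one union
locus; this keeps "union regions" well defined and the Jaccard coefficient
free of zero-length artifacts. Two-sided p-values double the smaller tail
and cap at 1.

## Enhancer calling

**Binarization.** Each sample's 200-bp bin counts are tested against a
single global Poisson rate λ̂ (the mean bin count of that sample). A bin is
flagged iff the upper-tail probability P(X ≥ count) < 10⁻⁴. At λ̂ = 2 the
smallest flagged count is 10 (P(X ≥ 10 | 2) ≈ 4.6 × 10⁻⁵). A per-sample
global rate is the simplest background model consistent with the
Poisson-count simulation; it ignores local mappability/copy-number
variation (see Limitations).

**Segmentation.** A two-state Bernoulli-emission HMM is fitted to the
binarized sequence by Baum–Welch (at most 200 iterations, stopping when
the log-likelihood gain drops below 10⁻⁶; the likelihood trace is recorded
and is non-decreasing by construction of EM). Initial parameters are
persistent-state priors with a small seeded jitter, so fits are
reproducible; after fitting, states are relabeled so state 1 always has
the higher probability of emitting a flagged bin. Decoding uses Viterbi
rather than posterior thresholding because it yields deterministic,
contiguous segments. Degenerate inputs (all 0 or all 1) return fixed
trivial parameters with a warning.

**Promoter filter.** A region is removed iff it overlaps any window
[TSS − 2500, TSS + 2500) by at least 1 bp, strand-independent. The
any-overlap rule is the strictest reading of "within ±2.5 kb of TSS" and
the easiest to test at boundaries.

**Stitching** of nearby enhancers is supported (`stitch_gap`) but off by
default; the SE workflow here calls SEs from the ranked size curve, not
from ROSE-style stitched-signal scoring.

**Quantification.** Region signal sums bin counts with proportional
allocation for partially covered bins, normalized to reads per million
mapped reads (rpm); density divides by region length (rpm/bp).

## Super-enhancer calling

Enhancers are ranked ascending by a size metric — genomic length by
default, total rpm optionally ("size" is ambiguous between the two; both
are supported and the choice is recorded in every output header). Ranks
and values are min-max scaled to [0, 1], which makes the call invariant to
affine transforms of the metric. The scaled curve is LOESS-smoothed and
its slope taken by central finite differences (`numpy.gradient`).

LOESS here is a one-pass tricube-weighted local *linear* fit: at each
point the ⌈span·n⌉ nearest neighbours define the window, weights are
tricube in distance scaled by the window radius, and the local weighted
least-squares line is evaluated at the point. No robustness iterations —
the curve is monotone by construction, and one pass keeps the fit exactly
reproducible by a per-point WLS oracle (which the tests assert).

The cut sits at the **rightmost upward crossing of the smoothed slope
through 1** (slope ≤ 1 just before, > 1 at the crossing, with a 10⁻⁸ guard
so an exactly linear curve — slope identically 1 — yields zero SEs). The
cutoff is the smoothed curve *value* at the crossing mapped back to metric
units: the tangent-line rule of hockey-stick ranking. Using the raw metric
value at the crossing rank instead would systematically undershoot,
because smoothing smears the hockey-stick corner leftward; on a 900/100
two-component length mixture the tangent rule separates the components
with recall and precision ≥ 0.97 in 20/20 seeds, while the raw-value rule
dropped precision to ≈ 0.5. The rightmost crossing (rather than the
first) is conservative — fewest SEs — and stable against slope noise at
the low end of the curve. If multiple enhancers tie at the cutoff, all of
them fall on the typical side (SEs require metric strictly above the
cutoff).

## SE similarity network

"Number of overlapped SEs" is operationalized symmetrically: the two
samples' SEs are merged into union loci, and a locus counts as shared when
intervals from *both* samples hit it. Per-set counting (A-intervals
hitting B) is asymmetric and double-counts split loci. The hypergeometric
co-occurrence test uses as its universe the merged union of SEs over all
samples (the methods that inspired this never define N; the cohort-wide
union is the natural exchangeable universe). Edges require both
Jaccard > 0.1 and BH-adjusted p < 0.001; samples with no retained edge are
reported as excluded, mirroring how weakly connected lines drop out of the
published network.

MCL runs on the retained graph with edge weight = Jaccard (matching the
convention that edge width encodes similarity), self-loops at each node's
maximum incident weight, expansion 2, inflation 2.0, pruning at 10⁻⁵,
convergence when the matrix changes by < 10⁻⁸. Every node is assigned to
the attractor row holding the largest share of its column mass, which also
resolves the rare overlapping-attractor case deterministically.

## Subtype-specific SEs

Union loci are extended by 200 bp on both sides (clipped at chromosome
bounds) before density quantification. Fold enrichment uses group *means*
(per the source convention "average signal") with an ε = 10⁻⁴ rpm/bp
stabilizer so zero-density loci stay finite; ε is far below any planted
signal density and only matters for empty loci.

The between-group test is the unpaired Wilcoxon rank-sum test by default.
The original description names a signed-rank test, but a signed-rank test
requires paired observations and the two cell-line groups are unpaired and
unequal; a strict signed-rank mode is retained for equal-size groups.
The exact distribution is used for combined n ≤ 25 without ties, the
normal approximation with tie and continuity corrections otherwise. BH
correction spans all union loci (no pre-filtering). Group-specific labels
need |log₂FE| > 1 *and* adjusted p < 0.05.

## Target genes and enrichment

Differential expression is a rank-sum test on the log₂ matrix with
log₂FC = difference of group means. This deliberately replaces moderated
linear-model machinery (limma-style empirical Bayes): with dozens of
samples per group the rank test is calibrated and assumption-free, and the
difference only affects borderline genes. Constant rows get p = 1.

SE→gene assignment is strand-aware and upstream-only: for a + gene the
candidate window is [TSS − 500 kb, TSS), for a − gene [TSS, TSS + 500 kb);
an SE pairs on ≥ 1 bp overlap with the window, many-to-many pairings are
kept, and the recorded distance is the gap from the TSS to the nearest SE
base. An SE overlapping only the gene body does not pair (the source says
"upstream" and nothing more).

Overrepresentation uses the hypergeometric upper tail with universe = all
genes in the expression matrix, genesets intersected with the universe,
BH across sets. The preranked enrichment score is the standard weighted
Kolmogorov–Smirnov running sum (hit steps ∝ |score|^weight, miss steps
1/(N − |S|)); its permutation p randomizes gene labels (same-size random
genesets) with add-one smoothing, because this stage consumes only the
ranking, not the sample-level matrix.

## Regulatory network and master regulators

Regulators are TFs appearing as targets of group-A-specific SEs
(SE log₂FE > 1, adjusted p < 0.05) whose own expression shows log₂FC > 1
at adjusted p < 0.05.

Pairwise dependence is scored by copula-Gaussian mutual information:
Spearman ρ is mapped to the Gaussian-equivalent ρ_g = 2 sin(πρ/6) and
MI = −½ ln(1 − ρ_g²), capped at ρ_g² = 1 − 10⁻¹². This estimator has a
closed-form oracle, no bandwidth, and is exactly symmetric; a binned
plug-in estimator (equal-frequency bins, B = ⌊√(n/5)⌋) is provided as an
alternative.

Edge significance is a permutation test on the regulator's vector with BH
across all TF×gene pairs. When subtype labels are supplied, permutations
are **stratified within subtype**. This matters in a two-group cohort:
a shared subtype mean shift induces rank correlation between every
differential gene and every differential TF, so an unstratified null calls
all such pairs edges, and TF–TF MI is too noisy at cohort scale for DPI to
remove them all (demo-cohort precision ≈ 0.5). Stratified permutation
keeps the group-shift component in the null, so an edge must reflect
within-subtype covariation; demo-cohort precision and recall both rise
above 0.9.

DPI pruning considers triplets (TF₁, TF₂, gene) where both TF→gene edges
survived significance; the TF–TF MI is computed on demand as scaffolding.
The smallest MI in the triplet is marked indirect when it falls below
min(other two) × (1 − 0.01); only TF→gene edges are removable, and all
marks are applied after the full scan, so the result is order-independent.
Master-regulator analysis tests each inferred regulon for signature
overrepresentation (hypergeometric, BH across TFs), ranking by adjusted p
then overlap.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
a desk scale chosen so the full pipeline runs in well under a minute:

| parameter | default | why |
|---|---|---|
| genome | 1 chromosome × 5 Mb, 200-bp bins | smallest scale at which 80+ loci and 300 genes fit without crowding |
| genes | 300, TSS ≥ 10 kb apart, 10% TFs | gene density ≈ 1/16 kb, enough upstream targets for every planted SE |
| ChIP samples | 6 + 6 | matches the two-subtype cell-line panel scale |
| background | Poisson(2) per bin | low-coverage ChIP-like background |
| typical enhancers | 80 shared, 1–2 kb, fold 8 | the body of the hockey stick |
| SEs | clusters of 6 × 1 kb constituents, 400-bp gaps (8 kb span), fold 16 | SEs as clusters of strong constituents; gaps are bridged by Viterbi, so SEs decode as large regions without stitching |
| SE sharing | 6 shared + 8 A-specific + 8 B-specific | shared SEs give a realistic similarity baseline; group SEs drive clustering and differential calls |
| expression cohort | 20 + 20 samples, Normal(5, 1) log₂ values | a scaled-down tumor cohort |
| DE genes | near A-specific SEs, effect 1.5 | planted SE→target pairs |
| regulator TFs | 9, effect 2.0 | planted as *notably* upregulated: the selection rule is observed log₂FC > 1, and at n = 40 the sampling error of the mean difference is ≈ 0.32, so the planted effect must clear the rule with margin |
| regulons | 9 disjoint × 20 genes, β = 0.8, noise 0.5 | member = β·(standardized TF) + noise; ρ ≈ 0.85 |
| signature | 50% of the master regulon + 30 background genes | makes exactly one TF a master regulator |

Counts are Poisson with no overdispersion knob — matching the
binarization model and keeping oracles analytic. Planted loci avoid
promoter windows by construction so the promoter filter never removes
truth. One global seed drives per-sample substreams, so cohorts are
byte-reproducible.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level noise, fragment-length and GC
effects, mappability and copy-number structure, overdispersed counts,
input/IgG background, correlated enhancer landscapes beyond the planted
block structure, and expression heterogeneity beyond a two-group shift
plus linear TF→target effects.

## Numerical choices

- Per-stage sub-seeds derive from the global seed via a CRC32 of the
  stage name, so stages are independently reproducible.
- The exact rank-sum/signed-rank distributions are used up to combined
  n = 25 without ties; beyond that, normal approximation with tie and
  continuity corrections.
- BH adjustment ignores NaNs and returns them in place.
- All tabular outputs are TSV with `# key=value` header comments recording
  the parameters used, so stage outputs are auditable in isolation.

## Limitations

- The global-Poisson binarization has no local background correction; on
  real data a control track or local λ estimate would be needed.
- The length-ranked SE call differs from ROSE's stitched signal-minus-input
  score; on real data the `signal` metric plus `stitch_gap` approximates
  the ROSE geometry, but constituent scoring is out of scope.
- The stratified MI null requires subtype labels; in unlabeled cohorts the
  unstratified null over-connects differential genes to differential TFs,
  which is a property of all mixed-cohort co-expression inference.
- Master-regulator ranking is overrepresentation-based; no mode-of-action
  signs or VIPER-style activity scores.
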