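# Methods

This note documents the models, conventions and design choices behind
`gliakit`, in the order of the pipeline.

## Synthetic atlas model (`synthgen`)

Cells are drawn from a per-type multinomial read-allocation model: each cell
of type *t* receives a library size `d ~ round(LogNormal(mu, sigma))`
(truncated to ≥ 1; defaults `mu = 7.6`, `sigma = 0.35`, i.e. a median of
roughly 2,000 reads with realistic right skew), and its reads are allocated
over genes with probabilities proportional to per-type weights: baseline
weight `baseline_mean` for generic and mitochondrial genes, multiplied by
`marker_fold` for the type's own exclusive markers. Because every type has
the same number of markers at the same fold, the normalization constants
cancel and the expected own-type/other-type marker count ratio equals
`marker_fold` exactly — which is what makes the law-of-large-numbers
recovery tests exact.

The multinomial model (rather than per-gene negative binomial) was chosen
deliberately: it is the same read-allocation model the pseudo-cell
annotation step assumes, so the oracle arithmetic for both stages is shared
and exact. The cost is that the generator does not emulate per-gene
overdispersion beyond what multinomial sampling plus lognormal depth
variation produces; tests passing on this data say nothing about robustness
to strongly overdispersed real counts, batch-specific expression shifts, or
doublet kinetics. Batch labels are assigned independently of expression
(default 95/5), which is exactly the situation the batch-contribution filter
assumes after integration has already removed batch effects.

**Planted contamination.** Flagged contaminated cells co-express a
three-gene "neuronal" program; flagged hemocytes express a dedicated marker
gene (`Hml-like`). For these program genes the read mass is placed
deterministically — `ceil(f * d)` reads per program gene, with the remaining
`d − extras` reads drawn multinomially over the non-program genes (program
genes carry probability 0 for unflagged cells). The fraction *f* is solved
analytically from the normalization: `ln(1 + f * 10^4) = v` gives
`f = (e^v − 1)/10^4`, with target value `v = 1.5` by default, 50% above the
gating threshold of 1. A purely stochastic allocation cannot guarantee that
every flagged cell clears the gate and no unflagged cell does; the
deterministic placement makes the planted gating ground truth exact
(sensitivity = specificity = 100% by construction), at the cost of removing
sampling noise from exactly those genes. Library-size conservation still
holds: row sums equal drawn depths.

Default study conditions: 4 types × 200 cells, 500 genes, 20 markers/type at
8-fold, 5% mitochondrial genes, 10% contaminated cells, 2% hemocytes, 95/5
batches. ROI tables plant positives by drawing scaled intensities uniformly
from (2.9, 6.0) versus (0.2, 1.8) for negatives — both ranges clear the 2.25
threshold with ≥ 20% margin so planted flags are exactly recoverable.

## QC, normalization and gating (`preprocess`)

Boundary semantics are literal and frozen:

* mitochondrial fraction: cells kept **strictly below** `mito_max = 0.10`;
* detected genes (count > 0): kept in the **inclusive** band [50, 3000];
* gating comparators applied exactly as written (`Rdl ≤ 1` keeps a cell at
  exactly 1; `Hml ≤ 0` on nonnegative data keeps exactly-zero cells);
* batch-contribution filter: clusters dropped when the minority batch
  contributes **strictly fewer** than `min_frac = 0.01` of cells.

Normalization is `v = ln(1 + c/C * s)` with scale factor `s = 10,000`
(natural log, pseudo-count 1), so `Σ_g (e^v − 1) = s` per cell — an identity
the tests assert to 1e-9 relative. Zero-total cells are an error, never
silently dropped.

Highly variable genes are ranked by plain sample variance of the normalized
values with lexical tie-break. A variance-stabilizing fit would rank
moderately expressed genes differently; plain variance was chosen as the
simplest auditable definition, and callers can pass any gene list downstream.

`keep_if_all` and `remove_if_any` gating modes induce the same partition
(removal on any failed rule ≡ keeping on all rules); both are offered so
call sites read naturally for negative (contamination) and positive
(midline-glia) selection.

## Pseudo-cell label transfer (`annotate`)

Depths are `round(Normal(mean, sd))` truncated to ≥ 1 — rounding/truncation
are needed because read counts are positive integers. 900 cells per bulk
type is the default. Correlations are computed over **all** shared genes
between the bulk table and the single-cell matrix (not an HVG subset), on
average log-normalized expression with the single-cell scale factor.
Zero-variance average vectors yield NaN, reported as missing rather than 0.
Best-match ties break toward the larger cluster, then lexically, making the
assignment deterministic. One generator seeded once drives all types in
table order, so the full assignment is reproducible from a single seed.

The cluster dendrogram uses Euclidean distance between cluster-average
expression vectors with complete linkage (configurable); leaves are
lexically sorted before linkage so merge order is deterministic under ties.

## Clustering and the over-clustering criterion (`heterogeneity`)

`cluster_cells` is a deterministic, dependency-light graph clustering:
per-gene z-scores capped at ±10, full-SVD PCA, a k = 20 nearest-neighbour
graph (Euclidean in PC space), and greedy modularity community detection
with a resolution parameter. At resolution 0.5 this yields one community on
a homogeneous expression blob and exactly recovers two planted types — the
two behaviours the downstream criterion depends on. The criterion is
deliberately label-agnostic: verdicts depend on DEG counts between the two
largest subclusters, not on matching any particular labelling.

Differential expression is the Wilcoxon rank-sum test on normalized values
(tie-corrected normal approximation; identical groups return p = 1), with
fold change `log2((mean(e^x − 1 over A) + 1) / (mean(e^x − 1 over B) + 1))`
— the back-transformed-mean convention with pseudo-count 1. Genes expressed
in < 10% of both groups are not tested; BH adjustment runs over tested genes
only.

The split criterion: > 20 genes at ≥ 4-fold (|log2FC| ≥ 2) → "split";
< 15 → "artifact"; the stated bounds leave a gap (15–20), and counts in the
gap return "indeterminate" rather than guessing. The DEG count additionally
requires BH-adjusted p < 0.05 by default (`adj_p_max=None` disables it);
with planted effects of this size the gate changes nothing, but it prevents
noise genes from crossing the fold cutoff in tiny subclusters.
`split_cluster` gives fresh ids from (max numeric id + 1) upward, the
largest subcluster keeping the original id, so a 15-cluster labelling split
once yields ids 0–15.

## Enrichment (`enrichment`)

Upper-tail hypergeometric `P(X ≥ k)` per term, BH across all tested terms,
rows below adjusted p 0.05 reported. Term similarity is the Jaccard index of
annotated gene sets; the similarity function is a pluggable argument, so an
ontology-graph-based measure can be substituted where an ontology is
available. The simplify cutoff is strict (similarity must exceed 0.7 to
prune) and processing order is ascending adjusted p with deterministic
tie-breaks, which makes the operation idempotent and its output a subset of
its input. Grouping takes the top 20 terms by adjusted p and applies Ward
linkage on 1 − similarity; the heat-table carries −log10(FDR).

## Imaging and clone statistics (`quantify`)

The normalization value is the grand mean of an average-intensity
projection (background subtraction, when used, is rolling-ball with radius
50 px applied before projection). Positivity is strict: scaled intensity
2.25 is negative, 2.26 positive. The regional test is a goodness-of-fit
chi-square (no continuity correction) of positive counts against expected
`total positives × region share of all nuclei`, df = regions − 1; regions
with zero nuclei raise an error instructing a merge.

Nuclei detection is Laplacian-of-Gaussian blob detection; `scale_px` is the
approximate nucleus diameter and sensitivity (0–100) maps linearly to a
relative peak threshold (1.0 down to 0.0). This is a documented stand-in
parameterization for interactive spot-detection tools whose internal
threshold mapping is unpublished; the tests pin its behaviour on synthetic
Gaussian nuclei only.

Layer-binned volumes assign voxel centres to half-open layer intervals
[lower, upper), combine `bin_width = 2` consecutive layers per bin, and
count an explicit "outside" bin so that total volume is conserved exactly.

Fisher's exact test is two-sided by summation of table probabilities ≤ the
observed table's probability; Mann–Whitney U uses exact enumeration when
both samples have ≤ 20 observations and no ties, otherwise the
tie-corrected normal approximation (mid-ranks), so identical samples give
U = n₁n₂/2 and p = 1. Both are verified in the tests against independent
exhaustive-enumeration oracles (all 2×2 tables with margins ≤ 12; all
hypergeometric configurations with universe ≤ 12).

## Problem sizes and verification scope

The test-suite and acceptance-script problem sizes are the package's
standard study conditions: planted atlases of 800 cells × 500 genes (4
types), two-type mixtures of 200 cells × 300 genes for the over-clustering
criterion (20 seeds per condition), 900 pseudo-cells per bulk type, ROI
tables of 500–600 nuclei, and exhaustive statistics oracles at small margins.
These sizes make every recovery property exact or high-margin while keeping
a full run in tens of seconds. What passing shows: the implementations
compute the documented quantities correctly and recover planted structure
under the generator's assumptions. What it does not show: performance on
real atlases with overdispersion, ambient RNA, batch-correlated expression,
or imaging noise beyond the synthetic intensity model.

## Known limitations

* The generator's contamination is binary (flagged/unflagged) with exact
  margins; real neuronal contamination is a continuum crossing the gate.
* HVG selection is raw variance, not a variance-stabilized dispersion.
* Community detection is greedy modularity, not Louvain/Leiden; criterion
  behaviour, not label identity, is the supported contract.
* Gene-set similarity is Jaccard on annotations; no ontology propagation.
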