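# Methods

## The hypergraph model

A hypergraph generalizes a graph by letting an edge (hyperedge) connect any
number of nodes. Here the nodes are a panel of differentially expressed
genes (DEGs) and each remaining transcriptome gene defines one hyperedge:
the set of node genes whose expression it is strongly correlated with
across the selected cells. Two representations are used throughout:

- the **incidence matrix** B (nodes × edges, binary), and
- the **clique reduction** M = B·Bᵀ (nodes × nodes), whose entry M[i, j]
  counts hyperedges shared by node genes i and j and whose diagonal is each
  node's hyperedge degree.

Degree centrality — the row sum of B, or the off-diagonal row sum of M —
measures a gene's connectivity to the rest of the transcriptome; the
clique-reduction variant additionally captures how much of that
connectivity is shared with other DEGs, i.e. higher-order coordination.

### Assumptions

- Co-expression (linear correlation on log-normalized values, Pearson by
  default; Spearman available) is an adequate proxy for functional
  association within a cell subset.
- The comparison is cross-sectional within one cell subset at a time;
  hypergraphs from different subsets (tissues) are compared only through
  their central clusters and gene ranks, never by direct matrix
  comparison.
- Both strong positive and strong negative correlation count as
  connectivity: binarization uses |r|, since negative co-regulation still
  implies coordination.

### Numerical choices

- **Threshold.** τ is the population SD (ddof = 0) of *all* entries of the
  node × edge correlation matrix, and membership requires strict
  inequality |r| > τ. With a constant correlation matrix τ = 0 and the
  incidence matrix is empty rather than full.
- **Degenerate genes.** Zero-variance genes get correlation 0 and are
  flagged, never dropped silently.
- **Ranks.** Descending (rank 1 = most connected), average for split
  ranks, so rank sums always equal n(n+1)/2.
- **Central cluster.** Ward linkage on the rows of M (Euclidean distance),
  tree cut into k clusters (default k = 2, matching one dominant block;
  k = "auto" scans 2–6 by silhouette). "Central" is operationalized as the
  cluster with the highest mean off-diagonal row sum. If all clusters tie
  (constant M) the largest cluster is returned with a `degenerate` flag.
- **Null model.** Randomization permutes the multiset of
  strictly-upper-triangle entries of M and mirrors them (diagonal fixed,
  because row sums are defined off-diagonal). This preserves the global
  weight distribution and total sum while destroying node identity —
  exactly what a per-gene centrality null requires; degree-preserving
  rewiring would preserve the signal under test. Z-scores use the
  empirical null mean and sample SD (ddof = 1) over iterations (default
  1000); genes with zero null SD are flagged and their Z reported as
  undefined rather than inf.
  Note a calibration fact about this scheme: for a matrix with i.i.d.
  entries, each node's observed row sum is marginally one draw from its
  own permutation null, so Z is asymptotically standard normal and the
  expected mean |Z| over genes is √(2/π) ≈ 0.80 — not 0. The null is
  centred (mean Z ≈ 0); |Z| itself is not small under pure noise. Planted
  hubs separate cleanly (Z ≫ 3 versus a non-hub median |Z| < 1).

## Differential expression and node selection

Two-sided Wilcoxon/Mann-Whitney rank-sum per gene on the normalized layer.
For min(n_A, n_B) ≤ 8 and tie-free data the exact null distribution of U
is used; otherwise a tie-corrected, continuity-corrected normal
approximation (the z-value is always reported). P-values are BH-adjusted
across genes; ties in p are broken lexicographically by symbol so tables
and node sets are deterministic.

Node selection: `fixed_n` takes the n smallest-p genes (the main pipeline
uses n = 600); `inflection` documents how such an n can be chosen — on the
descending ranked −log10(p) curve it cuts at the rank with maximal
*vertical* deviation below the chord from the first to the last point
(vertical rather than perpendicular deviation: simple, deterministic, and
dependent only on the plotted axes).

## QC and normalization

Cells failing any of: < 200 expressed genes, > 8000 expressed genes,
> 850 000 total counts, > 30% mitochondrial counts (symbol prefix `MT-`,
computed on raw counts of the unfiltered cell) are removed as a union;
the report attributes each removed cell to the first failing rule in the
fixed order min_genes → max_genes → max_counts → mito, so reports are
deterministic and never double-count. Genes expressed in fewer than 3
*surviving* cells are then removed. Normalization scales each cell to
10 000 counts and applies log1p, stored as a separate layer (raw counts
are kept; normalizing twice is an error).

## Velocity metrics

Velocity vectors are an input; estimating them from spliced/unspliced
counts is out of scope. Magnitude is the Euclidean norm ("differentiation
speed"). Confidence is the mean cosine similarity between a cell's
velocity and those of its k = 30 nearest neighbours (Euclidean in the
embedding, self excluded); zero-magnitude cells get confidence 0 with a
flag. Both metrics are invariant to rigid rotation and confidence is
invariant to positive rescaling of all velocities. A population that is
simultaneously fastest and least coherent is the progenitor signature.

## GWAS/eQTL integration

The n lowest-p variants (default 10 000, ties at the boundary included)
are mapped through an offline variant → gene eQTL table (tissues in an
exclusion list — by default the nervous system — are filtered out, an
unknown excluded label is a warning only), genes are matched to the node
set by uppercase symbol (no alias resolution — a declared limitation), and
membership in each tissue's central cluster, per-tissue ranks in both
hypergraph representations, and null Z-scores are attached. Duplicate
rsIDs keep the smallest p; gene counts are invariant to input row order.

## The synthetic-data generator

The generator stands in for the multi-study two-tissue atlas the analysis
is designed for, reproducing its statistical structure only (no real
marker genes or cluster identities):

- **Counts.** Negative binomial with gene-level log-normal baseline means
  (median `nb_mean` = 2 counts), dispersion θ = 1.5, per-cluster log-mean
  offsets, and independent dropout (rate 0.1). A dedicated `MT-` block is
  scaled per cell to hit a target mitochondrial fraction (1–15%) so QC is
  exercisable.
- **DE genes.** A planted block shifted by `de_log2fc` (alternating sign)
  between the two tissues.
- **Modules.** Each module's genes share a per-cell latent factor added to
  the log-mean with loading α = σ·√(ρ/(1−ρ)), σ = 1.6 being the empirical
  log-scale noise of the count model at the default mean/dispersion. Count
  sampling plus log1p compress high targets, so realized within-module
  correlations saturate below ρ (≈ 0.56 at ρ = 0.8) while remaining
  monotone in ρ — as in real data. Hub genes load on a second module's
  factor at 0.6α. A fraction of each module (`module_de_fraction`, default
  0.25) also receives the tissue shift so that module genes can reach the
  DEG node set while the rest of the module stays on the edge side — this
  is what makes planted modules recoverable as central clusters, mirroring
  data where central clusters are DEGs coordinated with the transcriptome.
  A module can be scoped to one tissue (`module_scopes`) to produce
  partially overlapping central clusters across tissues.
- **Velocity.** Gaussian blobs in 2-D; each population has a planted mean
  speed (per-cell speeds log-normal around it) and an angular-noise SD
  around a shared direction; the progenitor population gets isotropically
  random directions with planted speed 12.47, so its expected confidence
  is ≈ 0 — deliberately the extreme of the fast-but-incoherent signature
  rather than a partially coherent one.
- **GWAS tables.** rsIDs with p-values uniform on a log scale over
  (1e−8, 1]; exactly `n_overlap` eQTL genes are drawn from the node genes
  (optionally partly from a preferred set such as a central cluster, to
  emulate a mostly-clustered overlap), each supported by 10–110 rsIDs
  drawn from the lowest decile of p-values so they survive the lowest-n
  selection; all other eQTL genes are novel symbols.

All stages draw from independent substreams keyed by (global seed, stage
name), so outputs are bitwise reproducible and stages can be re-run in
isolation.

### What passing tests do and do not show

The generator has no batch effects, no ambient RNA, no UMI saturation, no
gene-length bias, and modules are cleanly block-structured. Tests
demonstrate that the implementation recovers planted structure under the
model's own assumptions and that its statistics are calibrated (type-I
rate of the rank-sum test within [0.03, 0.07] under the null generator);
they do not demonstrate robustness to real-data artefacts the generator
does not emulate.

## Problem sizes

The bundled demo configurations run the complete stage list at two sizes:
`small` (240 cells, 600 genes, 150 nodes, 200 null iterations) for the
test suite, and `full` (1200 cells, 2000 genes, 600 nodes, 1000 null
iterations, 100 000 GWAS variants with the lowest-10 000 selection) for
`scripts/acceptance.py`. Cell subset sizes were chosen so that each
per-tissue hypergraph has ≥ 200 cells, keeping correlation noise
(≈ 1/√n_cells) well below typical planted-module correlations.

## Known limitations

- Exact symbol matching only in the GWAS report; no LD clumping or
  gene-based tests.
- The central-cluster size is sensitive to k and to correlation noise in
  small cell subsets; k is exposed (fixed or silhouette-selected) rather
  than inferred from a tree-cut height.
- Weighted (non-binary) hypergraphs and edge-side centralities are not
  implemented.
- The permutation null destroys all node structure; it tests "is this
  gene's centrality exceptional given the global weight distribution",
  not "given the degree sequence".
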