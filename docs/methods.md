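# Methods

## Problem and model

Tissue EVs are a pooled signal: LC-MS/MS quantifies each EV protein's
abundance (peak area) for a whole tissue, while scRNA-seq resolves the
tissue's cells. The tracer connects the two by assuming that a cell's
contribution to an EV protein's pool is proportional to how strongly that
cell expresses the encoding gene. For protein *i* with group-mean peak area
`Area_i` and encoding-gene expression `Exp_ij` in cell *j*:

```
Protein_ij% = Area_i · Exp_ij / Σ_j' Exp_ij'
s-EV_j%     = 100 · Σ_i Protein_ij% / Σ_i Area_i
t-EV_c%     = Σ_{j: label_j = c} s-EV_j%
```

The allocation is mass-conserving by construction (each protein's shares
sum to `Area_i`, cells' s-EV% sum to 100, clusters' t-EV% sum to 100), and
is invariant to a global rescaling of all areas and to a per-protein
rescaling of its expression row. These invariances are the model's
essential sanity properties and are enforced by tests.

Assumptions worth stating plainly: transcript abundance is taken as a
proxy for secreted-protein output (no translation/secretion kinetics); a
protein's pool is attributed through a single encoding gene; and the
scRNA-seq cell composition is taken at face value (no correction for
sorting enrichment upstream of the atlas).

## Pipeline stages and parameters

**Cell QC.** A cell is kept iff `min_genes ≤ detected genes ≤ max_genes`
and `mito fraction < max_mito_fraction`. Defaults 500 / 6,000 / 0.25 with
the mouse mitochondrial prefix `mt-` (case-sensitive). Removal bounds are
strict — a cell with exactly 500 detected genes is kept, a cell at exactly
25% mitochondrial counts is removed. Cells violating several rules are
attributed to one rule (low genes → high genes → high mito) so report
counts always reconcile with the input count.

**Normalization.** CP10K-log: `log(1 + 1e4·count/cell_total)`. Tracing
uses this normalized expression by default (`expression_mode: raw`
switches to raw counts); normalization removes per-cell sequencing-depth
artifacts from the allocation.

**Marker detection.** One-vs-rest two-sided Wilcoxon rank-sum per gene and
cluster on normalized values. Pre-filters: fraction of expressing in-cluster
cells ≥ 0.10 and `log2fc ≥ 0.25`, where
`log2fc = log2((mean_in + ε)/(mean_out + ε))` on expm1-transformed values
with ε = 1e-9 (the ε only guards division by zero). p-values are
BH-adjusted within each cluster's tested set; a marker is a tested row with
adjusted p < 0.05 and positive log2fc. Clusters with fewer than 3 cells are
excluded with a warning. For total sample size ≤ 20 the p-value is an
exact enumeration over group assignments (midranks for ties); above that,
the tie-corrected normal approximation with continuity correction. The
threshold trades exactness at fixture scale for speed at data scale; both
paths are validated against an exhaustive-enumeration oracle in the tests.

**EV-protein filters.** Per group: (1) keep proteins with peak area > 0 in
every replicate of the group; (2) keep proteins whose encoding gene has
total count > 0 in the group's post-QC cells (this also guarantees nonzero
allocation denominators). `Area_i` is the arithmetic mean over the group's
replicates. Multi-protein-group symbols (`A;B`) resolve to the first
';'-separated member found in the gene universe; the area is never split
across genes. Each dropped protein is attributed to exactly one rule
(detection first), and the retained set is identical in either filter
order.

**Classification.** EV proteins passing the detection filter are
classified against the marker table: `cluster_marker` (gene is a
significant marker of ≥ 1 cluster, clusters recorded), `noncluster_marker`
(gene in the transcriptome universe but never a marker), `not_detected`
(gene absent from the universe). Tracing uses all filtered proteins by
default; `protein_scope: markers_only` restricts it to cluster-marker
proteins.

**Differential abundance** (plumbing for volcano plots): Welch's t-test on
`log2(area + 1)`, IRI vs sham, BH-adjusted; significance at adjusted
p < 0.05 and |log2fc| ≥ 1. Proteins detected in exactly one group are
flagged `group-exclusive` without a p-value; zero variance in both groups
with equal means yields p = 1 by convention.

**Groups.** Sham and IRI analyses are fully separate (markers, gene
universe, protein filters, areas, and cells are all group-specific); a
`both` run is byte-identical to the two single-group runs.

## Synthetic data generator

The generator emulates the study conditions with known ground truth.
Defaults: 3 clusters × 100 cells, 600 genes of which 10 are mitochondrial
and 10 per cluster are planted markers, negative-binomial counts (gene
means lognormal around 0.5, dispersion 2 — the standard overdispersed count
model), marker up-shift log2FC = 2, 200 EV proteins with per-cluster EV
output fractions 0.6/0.3/0.1, 3 replicates per group, 20% replicate CV on
peak areas, 5% leakage.

Choices that matter:

* **Dedicated protein genes.** Each EV protein gets its own gene
  (`EVG####`, appended after the background genes) expressed in its source
  cluster (NB mean 5), so the mapping protein → gene → cluster is exact and
  controllable.
* **Leakage** is defined as the expected fraction of a protein gene's
  *normalized-expression mass* lying outside its source cluster, spread
  uniformly over all cells — an ambient-background reading. It is
  implemented by a calibrated second pass that adds off-cluster counts
  until the target mass is reached (stopping at the closest point, so the
  realized leakage sits marginally below target). With leakage 0 the gene
  is exactly cluster-exclusive and recovery is exact to floating-point.
  Under this definition, leakage L biases the largest cluster's t-EV% by
  about `L·(fraction − weighted off-share)`; at the default 5% and
  fractions 0.6/0.3/0.1 the worst-case bias is ≈ 1.3–1.6 percentage
  points.
* **Deterministic ground truth.** Replicate areas are rescaled per
  (group, cluster) so the realized group-mean per-cluster area fractions
  equal the configured fractions exactly. The tracer's target is therefore
  a fixed number, not a sampling-noise-laden estimate.
* **Marker means floored at 0.3** before the up-shift: planted markers
  emulate robustly expressed cell-type genes, so marker-recovery checks
  measure the detector, not the lognormal tail.
* **Cells alternate between sham and IRI** within each cluster and cycle
  over replicate samples, so both groups contain every cluster.

What the generator does **not** emulate: ambient RNA and doublets, batch
effects, cell-type-specific library sizes, sorting enrichment of immune
cells, peptide-level quantification artifacts, or shared genes between
proteins. Passing tests therefore demonstrate correctness of the
computation and recoverability under the stated model, not robustness to
every artifact of real tissue data.

One interaction deserves note: cluster-exclusive protein genes add counts
to their source cluster's cells, so after depth normalization *background*
genes become genuinely (compositionally) differential between clusters.
Marker power/calibration checks therefore run on a generator configuration
without protein genes, where null genes are exchangeable; the measured
null false-positive rate at α = 0.05 then falls within the 99% binomial
band (~0.04–0.07 across seeds).

## Numerical choices and degenerate inputs

* Share row sums are validated against `Area_i` at relative tolerance
  1e-9; conservation checks use 1e-6 on percentage sums.
* A cell expressing none of the traced genes receives s-EV% 0, with no
  special casing.
* A protein whose expression row sums to zero is a validation error (the
  gene-universe filter makes this unreachable in the pipeline).
* Zero-total-count cells get mito fraction 0 and are flagged; they fail
  the min-genes rule.
* Missing peak-area cells read as 0 (peptide not observed), matching the
  "nonzero in all replicates" detection semantics; counts of missing cells
  are logged.
* Cluster summaries and marker tables are emitted in sorted, stable order,
  and no output file carries a wall-clock timestamp, so identical inputs
  and seed give byte-identical output trees.

## Problem sizes

The bundled demo and the acceptance script run the generator at its default
scale (300 cells, ~800 genes, 200 proteins; the determinism check uses a
120-cell variant), where the full pipeline completes in seconds; brute-force
oracle comparisons use 100 random instances up to 50 proteins × 50 cells.
The tracing core is vectorized (sparse-aware), so atlas-scale inputs are
limited by memory on the dense marker blocks, not the tracer.

## Known limitations

* The allocation attributes a protein's whole pool through transcript
  abundance; post-transcriptional regulation of secretion is invisible.
* Multi-gene protein groups resolve to a single gene; splitting areas
  across paralogs is deliberately not attempted.
* QC boundary fixtures assume the default 25% mitochondrial bound when
  constructing exact-boundary cells.
* The Wilcoxon exact path enumerates permutations only up to total n = 20;
  beyond that the continuity-corrected approximation is used, which is
  mildly conservative at moderate sample sizes.
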