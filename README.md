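# evtrace

Trace tissue-derived extracellular-vesicle (EV) proteins back to the single
cells and cell clusters that secreted them, by integrating a label-free
LC-MS/MS EV proteome with a single-cell RNA-seq atlas of the same tissue.

The package targets studies of the mouse kidney ischemia-reperfusion injury
(IRI) model — EVs are purified from dissociated kidney, their proteins
quantified as peak areas in sham and IRI groups, and the kidney's cells are
profiled by scRNA-seq and clustered — but the method applies to any paired
tissue-EV proteome / single-cell transcriptome design.

## The model

For each EV protein *i* with group-mean peak area `Area_i`, the protein's
abundance is allocated across the group's single cells *j* in proportion to
the expression `Exp_ij` of the gene that encodes it:

```
Protein_ij% = Area_i · Exp_ij / Σ_j' Exp_ij'
s-EV_j%     = 100 · Σ_i Protein_ij% / Σ_i Area_i
t-EV_c%     = Σ_{j ∈ cluster c} s-EV_j%
```

`s-EV_j%` scores the EV-secretion ability of cell *j* (cells sum to 100);
`t-EV_c%` is cluster *c*'s share of the tissue's EV output, reported beside
`cell%`, the cluster's share of profiled cells. A cluster whose t-EV% far
exceeds its cell% is a disproportionate EV producer.

Upstream of the tracing, the package provides the required plumbing:

* **Cell QC** — remove cells with < 500 or > 6,000 detected genes or ≥ 25%
  mitochondrial counts (strict bounds, `mt-` prefix, all configurable),
  then CP10K-log normalization.
* **Cluster markers** — one-vs-rest two-sided Wilcoxon rank-sum per gene
  with Benjamini-Hochberg adjustment per cluster (pre-filters
  `min_pct = 0.10`, `min_log2fc = 0.25`).
* **EV-protein filters** — keep proteins with nonzero peak area in **every**
  replicate of a group and whose encoding gene is detected in that group's
  post-QC transcriptome; compute group-mean areas; classify each EV protein
  as a cluster marker, noncluster marker, or not detected; Welch-t
  differential abundance (IRI vs sham) for volcano plots.
* **Synthetic data** — negative-binomial count matrices with planted
  markers and EV peak-area tables generated from known per-cluster EV
  output fractions, so the whole pipeline is testable with ground truth.

Sham and IRI are analysed fully separately: sham-filtered proteins and sham
mean areas are traced over sham cells, and likewise for IRI.

## Worked example

Simulate the default synthetic study (3 clusters × 100 cells, 200 EV
proteins drawn from EV-output fractions 0.6/0.3/0.1 with 5% ambient
leakage, 3 replicates per group) and run the full pipeline:

```
$ evtrace demo --out out --seed 1
[sham] t-EV%: C0=58.56, C1=30.10, C2=11.34
[IRI] t-EV%: C0=58.62, C1=30.43, C2=10.96
```

Each cluster holds a third of the cells (cell% ≈ 33.3), yet cluster C0 is
traced as the source of ~59% of EV protein mass and C2 of only ~11% —
recovering the planted 60/30/10 ground truth within ~1.5 percentage points
(the residual bias comes from the simulated 5% ambient leakage of
protein-gene expression). `out/run/<group>/cluster_summary.tsv` holds these
numbers:

```
cluster  cell_pct            tev_pct
C0       33.333333333333336  58.55866571957553
C1       33.333333333333336  30.10010997050779
C2       33.333333333333336  11.341224309916694
```

with per-cell scores in `sev_per_cell.tsv`, marker and classification
tables, a per-protein drop report, the IRI-vs-sham differential table, and
a manifest with per-stage counts and the config hash. Reruns with the same
config and seed are byte-identical.

Library use mirrors the CLI: see `evtrace.pipeline.run_trace_pipeline`, or
call the stages directly (`compute_qc_metrics`/`filter_cells`,
`normalize_cp10k_log`, `find_all_markers`, `build_filtered_protein_set`,
`build_trace_input`, `trace`).

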