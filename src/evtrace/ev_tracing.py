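"""Cell-of-origin tracing of tissue-EV proteins.

The core model: each EV protein i carries a group-mean peak area Area_i from
label-free LC-MS/MS. That abundance is allocated across single cells j in
proportion to the expression Exp_ij of the gene that encodes the protein,

    Protein_ij% = Area_i * Exp_ij / sum_j' Exp_ij'            (share matrix)

so each protein's shares sum back to its Area_i. A cell's EV-secretion score
is its share of all allocated protein mass,

    s-EV_j% = 100 * sum_i Protein_ij% / sum_i Area_i,

which sums to 100 over cells; a cluster's score t-EV% is the sum of its
cells' s-EV%, reported next to the cluster's share of cells (cell%).

Proteins are additionally classified against the cluster-marker table as
cluster markers, noncluster markers, or not detected in the transcriptome.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .ev_proteomics import resolve_gene

REL_TOL = 1e-9

CLASS_CLUSTER_MARKER = "cluster_marker"
CLASS_NONCLUSTER_MARKER = "noncluster_marker"
CLASS_NOT_DETECTED = "not_detected"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TraceInput:
    """Mean peak areas plus the proteins x cells expression of the encoding
    genes, with per-cell cluster labels."""

    area: np.ndarray
    exp: object  # dense ndarray or scipy sparse, proteins x cells
    labels: np.ndarray
    protein_ids: np.ndarray | None = None
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n_prot, n_cells = self.exp.shape
        if len(self.area) != n_prot:
            raise ValidationError("area length does not match exp rows")
        if len(self.labels) != n_cells:
            raise ValidationError("labels length does not match exp columns")
        if self.protein_ids is None:
            self.protein_ids = np.asarray([f"P{i}" for i in range(n_prot)], dtype=object)
        if self.cell_ids is None:
            self.cell_ids = np.asarray([f"cell{j}" for j in range(n_cells)], dtype=object)
        if len(self.area) and self.area.min() <= 0:
            raise ValidationError("Area_i must be strictly positive")
        dat = self.exp.data if sp.issparse(self.exp) else np.asarray(self.exp)
        if dat.size and np.asarray(dat).min() < 0:
            raise ValidationError("expression must be non-negative")


@dataclasses.dataclass
class ShareMatrix:
    """Per-protein allocation of Area_i over cells (Protein_ij%)."""

    shares: object  # proteins x cells, dense or sparse
    area: np.ndarray
    protein_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        row_sums = np.asarray(self.shares.sum(axis=1)).ravel()
        if not np.allclose(row_sums, self.area, rtol=REL_TOL, atol=0):
            raise ValidationError("share rows do not reproduce Area_i")


@dataclasses.dataclass
class TraceResult:
    """s-EV% per cell, t-EV% and cell% per cluster."""

    cell_ids: np.ndarray
    labels: np.ndarray
    sev: np.ndarray
    tev: pd.Series
    cell_pct: pd.Series
    n_proteins_used: int
    shares: ShareMatrix | None = None


# ---------------------------------------------------------------------------
# Core computation
# ---------------------------------------------------------------------------

def allocate_protein_shares(trace_input: TraceInput) -> ShareMatrix:
    """Distribute each protein's Area_i over cells proportionally to the
    expression of its encoding gene.

    Raises :class:`ValidationError` for any protein whose expression row sums
    to zero — such proteins must have been removed by the transcriptome
    filter upstream.
    """
    exp = trace_input.exp
    row_sums = np.asarray(exp.sum(axis=1)).ravel().astype(float)
    if (row_sums <= 0).any():
        bad = np.flatnonzero(row_sums <= 0)
        raise ValidationError(
            f"{bad.size} proteins have zero total expression "
            f"(first: {trace_input.protein_ids[bad[0]]}); "
            "they should have been dropped by the gene-universe filter"
        )
    scale = trace_input.area / row_sums
    if sp.issparse(exp):
        shares = sp.diags(scale) @ exp.tocsr()
    else:
        shares = scale[:, None] * np.asarray(exp, dtype=float)
    return ShareMatrix(
        shares=shares,
        area=trace_input.area,
        protein_ids=trace_input.protein_ids,
        cell_ids=trace_input.cell_ids,
    )


def compute_sev(share_matrix: ShareMatrix) -> np.ndarray:
    """Per-cell s-EV%: each cell's percentage of total allocated EV protein
    mass. Sums to 100 over cells."""
    if len(share_matrix.area) == 0:
        raise ValidationError("no proteins in share matrix")
    col_sums = np.asarray(share_matrix.shares.sum(axis=0)).ravel()
    return 100.0 * col_sums / share_matrix.area.sum()


def compute_tev(sev: np.ndarray, labels) -> tuple[pd.Series, pd.Series]:
    """Per-cluster t-EV% (sum of member cells' s-EV%) and cell% (share of
    cells). Clusters are reported in sorted label order."""
    labels = np.asarray(labels, dtype=object)
    sev = np.asarray(sev, dtype=float)
    if len(labels) != len(sev):
        raise ValidationError("labels length does not match sev length")
    clusters = sorted(set(labels))
    tev = pd.Series(
        [float(sev[labels == c].sum()) for c in clusters], index=clusters, name="tev_pct"
    )
    cell_pct = pd.Series(
        [100.0 * float((labels == c).sum()) / len(labels) for c in clusters],
        index=clusters,
        name="cell_pct",
    )
    return tev, cell_pct


def trace(trace_input: TraceInput, keep_shares: bool = False) -> TraceResult:
    """Run allocation, s-EV% and t-EV% in one call."""
    shares = allocate_protein_shares(trace_input)
    sev = compute_sev(shares)
    tev, cell_pct = compute_tev(sev, trace_input.labels)
    return TraceResult(
        cell_ids=trace_input.cell_ids,
        labels=trace_input.labels,
        sev=sev,
        tev=tev,
        cell_pct=cell_pct,
        n_proteins_used=len(trace_input.area),
        shares=shares if keep_shares else None,
    )


# ---------------------------------------------------------------------------
# Building a TraceInput from pipeline objects
# ---------------------------------------------------------------------------

def build_trace_input(
    filtered_set,
    expression,
    gene_ids,
    labels,
    cell_ids=None,
) -> TraceInput:
    """Assemble Area_i and Exp_ij for one group.

    ``filtered_set`` is an ``ev_proteomics.FilteredProteinSet``;
    ``expression`` is a genes x cells matrix (normalized by default in the
    pipeline, raw counts when configured) restricted to the group's cells.
    """
    gene_pos = {g: i for i, g in enumerate(np.asarray(gene_ids, dtype=object))}
    missing = [g for g in filtered_set.genes if g not in gene_pos]
    if missing:
        raise ValidationError(f"genes missing from expression matrix: {missing[:3]}")
    rows = np.asarray([gene_pos[g] for g in filtered_set.genes], dtype=int)
    exp = expression[rows, :] if sp.issparse(expression) else np.asarray(expression)[rows, :]
    return TraceInput(
        area=filtered_set.areas,
        exp=exp,
        labels=labels,
        protein_ids=filtered_set.protein_ids,
        cell_ids=cell_ids,
    )


# ---------------------------------------------------------------------------
# Marker-overlap classification
# ---------------------------------------------------------------------------

def classify_ev_proteins(
    protein_ids,
    gene_symbols,
    markers: pd.DataFrame,
    gene_universe: set,
) -> pd.DataFrame:
    """Three-way classification of EV proteins against the marker table.

    A protein whose resolved gene is a significant marker of >= 1 cluster is
    a ``cluster_marker`` (with those clusters listed); a gene present in the
    transcriptome universe but never a marker is a ``noncluster_marker``; a
    gene absent from the universe is ``not_detected``. The classes partition
    the protein list.
    """
    sig = markers[markers["is_marker"]] if len(markers) else markers
    by_gene: dict = {}
    for _, row in sig.iterrows():
        by_gene.setdefault(row["gene"], []).append(row["cluster"])

    records = []
    for pid, sym in zip(protein_ids, gene_symbols):
        gene = resolve_gene(sym, gene_universe)
        if gene is None:
            records.append((pid, "", CLASS_NOT_DETECTED, ""))
        elif gene in by_gene:
            clusters = ";".join(sorted(set(by_gene[gene])))
            records.append((pid, gene, CLASS_CLUSTER_MARKER, clusters))
        else:
            records.append((pid, gene, CLASS_NONCLUSTER_MARKER, ""))
    return pd.DataFrame(
        records, columns=["protein_id", "gene", "ev_class", "marker_clusters"]
    )
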