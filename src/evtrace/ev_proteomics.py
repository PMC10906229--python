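"""Detection filtering, gene mapping, group-mean peak areas and differential
abundance for the tissue-EV protein quantification table.

A protein enters a group's tracing set only if (1) its peak area is nonzero
in every replicate of that group and (2) the gene encoding it is detected in
the same group's post-QC scRNA-seq matrix (total count > 0). Group analyses
are fully separate: sham tracing uses sham-filtered proteins with sham mean
areas on sham cells, and likewise for IRI.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import ExpressionMatrix, ProteinQuantTable

#: Drop-rule identifiers used in drop reports (exactly one rule per drop).
RULE_DETECTION = "not_detected_in_all_replicates"
RULE_TRANSCRIPTOME = "gene_not_in_transcriptome"


@dataclasses.dataclass
class FilteredProteinSet:
    """Proteins retained for one group's tracing, with resolved genes and
    group-mean peak areas (Area_i)."""

    group: str
    protein_ids: np.ndarray
    genes: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.protein_ids) == len(self.genes) == len(self.areas)):
            raise ValidationError("filtered-set field lengths differ")
        if len(self.areas) and (np.asarray(self.areas) <= 0).any():
            raise ValidationError("retained mean peak areas must be > 0")

    def __len__(self) -> int:
        return len(self.protein_ids)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_detected_in_all_replicates(table: ProteinQuantTable, group: str) -> np.ndarray:
    """Protein IDs whose peak area is > 0 in every replicate of ``group``."""
    cols = table.replicate_columns(group)
    mask = (table.areas[:, cols] > 0).all(axis=1)
    return table.protein_ids[mask]


def gene_universe_from_matrix(matrix: ExpressionMatrix, cell_mask=None) -> set:
    """Genes with total count > 0 across the (optionally masked) cells.

    This is the "detected in the scRNA-seq data" universe used by the
    transcriptome filter; it also guarantees nonzero denominators when a
    protein's area is allocated over cells.
    """
    counts = matrix.counts if cell_mask is None else matrix.counts[:, np.flatnonzero(np.asarray(cell_mask))]
    totals = np.asarray(counts.sum(axis=1)).ravel()
    return {g for g, t in zip(matrix.gene_ids, totals) if t > 0}


def resolve_gene(symbol, gene_universe: set):
    """Resolve a possibly ';'-separated protein-group symbol to a single gene.

    Returns the first ';'-separated symbol present in ``gene_universe``, or
    None if no member resolves. The peak area is never split across genes.
    """
    if symbol is None or (isinstance(symbol, float) and np.isnan(symbol)):
        return None
    for part in str(symbol).split(";"):
        part = part.strip()
        if part and part in gene_universe:
            return part
    return None


def map_proteins_to_genes(
    protein_ids,
    gene_symbols,
    gene_universe: set,
    mapping: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve each protein to a transcriptome gene, dropping the unmappable.

    ``mapping`` (protein_id -> symbol) overrides the quant table's
    gene_symbol column where present. Returns ``(mapped, dropped)`` frames;
    ``dropped`` has one row per protein with the rule column set to
    :data:`RULE_TRANSCRIPTOME`.
    """
    rows, drops = [], []
    for pid, sym in zip(protein_ids, gene_symbols):
        if mapping is not None and pid in mapping:
            sym = mapping[pid]
        gene = resolve_gene(sym, gene_universe)
        if gene is None:
            drops.append({"protein_id": pid, "rule": RULE_TRANSCRIPTOME})
        else:
            rows.append({"protein_id": pid, "gene": gene})
    mapped = pd.DataFrame(rows, columns=["protein_id", "gene"])
    dropped = pd.DataFrame(drops, columns=["protein_id", "rule"])
    return mapped, dropped


def mean_peak_area(table: ProteinQuantTable, group: str, protein_ids) -> np.ndarray:
    """Arithmetic mean peak area (Area_i) over ``group``'s replicates for the
    given proteins, in the given order."""
    index = {p: i for i, p in enumerate(table.protein_ids)}
    missing = [p for p in protein_ids if p not in index]
    if missing:
        raise KeyError(f"proteins absent from quant table: {missing[:3]}")
    rows = np.asarray([index[p] for p in protein_ids], dtype=int)
    cols = table.replicate_columns(group)
    return table.areas[np.ix_(rows, cols)].mean(axis=1)


def build_filtered_protein_set(
    table: ProteinQuantTable,
    group: str,
    gene_universe: set,
    mapping: dict | None = None,
) -> tuple[FilteredProteinSet, pd.DataFrame]:
    """Apply both printed filters for one group and compute Area_i.

    Returns the retained set and a drop report with exactly one rule per
    dropped protein (detection rule takes precedence for proteins failing
    both).
    """
    detected = set(filter_detected_in_all_replicates(table, group))
    drops = [
        {"protein_id": pid, "rule": RULE_DETECTION}
        for pid in table.protein_ids
        if pid not in detected
    ]
    keep_mask = np.asarray([p in detected for p in table.protein_ids])
    mapped, map_drops = map_proteins_to_genes(
        table.protein_ids[keep_mask],
        table.gene_symbols[keep_mask],
        gene_universe,
        mapping,
    )
    drop_report = pd.concat(
        [pd.DataFrame(drops, columns=["protein_id", "rule"]), map_drops],
        ignore_index=True,
    )
    areas = mean_peak_area(table, group, mapped["protein_id"].to_numpy())
    subset = FilteredProteinSet(
        group=group,
        protein_ids=mapped["protein_id"].to_numpy(dtype=object),
        genes=mapped["gene"].to_numpy(dtype=object),
        areas=areas,
    )
    return subset, drop_report


# ---------------------------------------------------------------------------
# Differential abundance (IRI vs sham)
# ---------------------------------------------------------------------------

def differential_abundance(
    table: ProteinQuantTable,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Welch's t-test on log2(area + pseudocount), IRI vs sham, per protein.

    Proteins detected (all replicates nonzero) in exactly one group are
    flagged ``group-exclusive`` with no p-value. The rest are tested and
    BH-adjusted; status is ``up``/``down`` when adjusted p < alpha and
    |log2fc| >= min_abs_log2fc, otherwise ``ns``. Zero variance in both
    groups with equal means yields p = 1 by convention.
    """
    sham_cols = table.replicate_columns("sham")
    iri_cols = table.replicate_columns("IRI")
    if len(sham_cols) < 2 or len(iri_cols) < 2:
        raise ValidationError("differential abundance needs >= 2 replicates per group")

    log_sham = np.log2(table.areas[:, sham_cols] + pseudocount)
    log_iri = np.log2(table.areas[:, iri_cols] + pseudocount)
    log2fc = log_iri.mean(axis=1) - log_sham.mean(axis=1)

    det_sham = (table.areas[:, sham_cols] > 0).all(axis=1)
    det_iri = (table.areas[:, iri_cols] > 0).all(axis=1)
    exclusive = det_sham ^ det_iri

    pvals = np.full(table.n_proteins, np.nan)
    test_idx = np.flatnonzero(~exclusive)
    if test_idx.size:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(
                log_iri[test_idx], log_sham[test_idx], axis=1, equal_var=False
            )
        p = np.asarray(res.pvalue, dtype=float)
        # zero variance in both groups: equal means -> p=1; unequal -> p=0
        p = np.where(np.isnan(p), np.where(log2fc[test_idx] == 0, 1.0, 0.0), p)
        pvals[test_idx] = p

    padj = np.full(table.n_proteins, np.nan)
    if test_idx.size:
        padj[test_idx] = multipletests(pvals[test_idx], method="fdr_bh")[1]

    status = np.full(table.n_proteins, "ns", dtype=object)
    sig = (~exclusive) & (padj < alpha) & (np.abs(log2fc) >= min_abs_log2fc)
    status[sig & (log2fc > 0)] = "up"
    status[sig & (log2fc < 0)] = "down"
    status[exclusive] = "group-exclusive"

    return pd.DataFrame(
        {
            "protein_id": table.protein_ids,
            "gene_symbol": table.gene_symbols,
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adj": padj,
            "status": status,
        }
    )
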