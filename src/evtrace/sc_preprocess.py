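"""Cell quality control, library-size normalization and cluster-marker
detection on the raw count matrix.

QC removes low-quality droplets by the standard criteria for mouse kidney
atlases: fewer than 500 or more than 6,000 detected genes (empty droplets or
doublets) and >= 25% mitochondrial counts (dying cells). Removal bounds are
strict as printed: ``< min_genes``, ``> max_genes``, ``>= max_mito_fraction``.

Marker detection is a one-vs-rest two-sided Wilcoxon rank-sum test per gene
and cluster on log-normalized expression, with Benjamini-Hochberg adjustment
within each cluster's tested set — the behaviour of the widely used
"find all markers" convention (pre-filters min_pct = 0.10 and
min_log2fc = 0.25, significance at adjusted p < 0.05 with positive
enrichment).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import ExpressionMatrix

log = logging.getLogger("evtrace")

#: Total sample size at or below which the Wilcoxon p-value is computed by
#: exact enumeration of group assignments rather than the tie-corrected
#: normal approximation with continuity correction.
EXACT_TEST_MAX_N = 20

#: Pseudocount used in the log2 fold-change ratio of group means.
LOG2FC_EPS = 1e-9


# ---------------------------------------------------------------------------
# QC metrics and filtering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QCThresholds:
    """Cell-level QC bounds; defaults follow the kidney-atlas convention."""

    min_genes: int = 500
    max_genes: int = 6000
    max_mito_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValidationError("min_genes must be < max_genes")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must lie in [0, 1]")


@dataclasses.dataclass
class QCReport:
    """Per-rule removal counts for one QC pass.

    A cell violating several rules is attributed to exactly one rule using
    the priority low genes > high genes > high mito, so
    ``n_input == n_kept + removed_low_genes + removed_high_genes +
    removed_high_mito``.
    """

    n_input: int
    n_kept: int
    removed_low_genes: int
    removed_high_genes: int
    removed_high_mito: int
    kept_mask: np.ndarray

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed_low_genes": self.removed_low_genes,
            "removed_high_genes": self.removed_high_genes,
            "removed_high_mito": self.removed_high_mito,
        }


def compute_qc_metrics(matrix: ExpressionMatrix, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, total counts, mitochondrial
    fraction.

    Mitochondrial genes are identified by a case-sensitive symbol prefix
    (``mt-`` for mouse). Cells with zero total counts receive
    ``mito_fraction`` 0 and are flagged in the ``zero_total`` column.
    """
    counts = matrix.counts
    n_genes_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)

    mito_mask = np.array(
        [str(g).startswith(mito_prefix) for g in matrix.gene_ids], dtype=bool
    )
    if not mito_mask.any():
        warnings.warn(
            f"no gene symbol starts with {mito_prefix!r}; "
            "all mito_fraction values are 0",
            stacklevel=2,
        )
        mito_totals = np.zeros_like(totals)
    else:
        mito_totals = np.asarray(counts[mito_mask].sum(axis=0)).ravel().astype(float)

    zero_total = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(zero_total, 0.0, mito_totals / np.where(zero_total, 1.0, totals))

    return pd.DataFrame(
        {
            "n_genes_detected": n_genes_detected.astype(int),
            "total_counts": totals,
            "mito_fraction": mito_fraction,
            "zero_total": zero_total,
        },
        index=list(matrix.cell_ids),
    )


def filter_cells(
    matrix: ExpressionMatrix,
    metrics: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove low-quality cells by the strict printed bounds.

    A cell is kept iff ``min_genes <= n_genes_detected <= max_genes`` and
    ``mito_fraction < max_mito_fraction``. The gene set is unchanged. Raises
    :class:`ValidationError` if no cell survives.
    """
    thresholds = thresholds or QCThresholds()
    if len(metrics) != matrix.n_cells:
        raise ValidationError("metrics were not computed on this matrix")

    n = metrics["n_genes_detected"].to_numpy()
    mito = metrics["mito_fraction"].to_numpy()

    low = n < thresholds.min_genes
    high = n > thresholds.max_genes
    himito = mito >= thresholds.max_mito_fraction
    kept = ~(low | high | himito)

    # Attribution priority keeps the counts additive.
    attr_low = low
    attr_high = high & ~low
    attr_mito = himito & ~low & ~high

    report = QCReport(
        n_input=matrix.n_cells,
        n_kept=int(kept.sum()),
        removed_low_genes=int(attr_low.sum()),
        removed_high_genes=int(attr_high.sum()),
        removed_high_mito=int(attr_mito.sum()),
        kept_mask=kept,
    )
    if report.n_kept == 0:
        raise ValidationError(
            "QC removed every cell; review thresholds "
            f"(min_genes={thresholds.min_genes}, max_genes={thresholds.max_genes}, "
            f"max_mito_fraction={thresholds.max_mito_fraction})"
        )
    return matrix.subset_cells(kept), report


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_cp10k_log(matrix: ExpressionMatrix) -> sp.csr_matrix:
    """Library-size normalization to 10,000 counts per cell followed by
    log1p: entry = log(1 + 1e4 * count / cell_total). Zero counts stay zero.

    Raises :class:`ValidationError` for cells with zero total counts (such
    cells must have been removed by QC).
    """
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        bad = int((totals == 0).sum())
        raise ValidationError(f"{bad} cells have zero total counts; run QC first")
    X = matrix.counts.tocsc().astype(float)
    X = X.multiply(1e4 / totals[None, :]).tocsr()
    X.data = np.log1p(X.data)
    return X


# ---------------------------------------------------------------------------
# One-vs-rest marker detection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MarkerParams:
    """Pre-filters and significance level for marker detection."""

    min_log2fc: float = 0.25
    min_pct: float = 0.10
    alpha: float = 0.05


def _wilcoxon_pvalues(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values, one per row of the two value blocks.

    Exact enumeration (permutation over all group assignments, midranks for
    ties) for small samples; tie-corrected normal approximation with
    continuity correction otherwise.
    """
    n = x_in.shape[1] + x_out.shape[1]
    if n <= EXACT_TEST_MAX_N:
        method = stats.PermutationMethod(n_resamples=500_000, rng=0)
        pvals = np.empty(x_in.shape[0])
        for i in range(x_in.shape[0]):
            res = stats.mannwhitneyu(
                x_in[i], x_out[i], alternative="two-sided", method=method
            )
            pvals[i] = res.pvalue
        return pvals
    res = stats.mannwhitneyu(
        x_in, x_out, axis=1, alternative="two-sided",
        method="asymptotic", use_continuity=True,
    )
    return np.atleast_1d(res.pvalue)


def find_all_markers(
    normalized: sp.csr_matrix,
    gene_ids,
    labels,
    params: MarkerParams | None = None,
) -> pd.DataFrame:
    """One-vs-rest cluster markers on a log-normalized genes x cells matrix.

    For every cluster with at least 3 cells, genes passing the pre-filters
    (``pct_in >= min_pct`` and ``log2fc >= min_log2fc``) are tested with a
    two-sided Wilcoxon rank-sum against all other cells; p-values are
    BH-adjusted within the cluster's tested set. The log2 fold change is
    ``log2((mean_in + eps) / (mean_out + eps))`` on expm1-transformed
    normalized values (eps = 1e-9).

    Returns a DataFrame with one row per tested (gene, cluster):
    ``gene, cluster, log2fc, pct_in, pct_out, p_value, p_adj, is_marker``,
    where ``is_marker = p_adj < alpha and log2fc > 0``.
    """
    params = params or MarkerParams()
    labels = np.asarray(labels, dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)
    X = sp.csr_matrix(normalized)
    if X.shape[1] != len(labels):
        raise ValidationError("labels length does not match matrix columns")
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ValidationError("marker detection requires >= 2 clusters")

    expm1 = X.copy()
    expm1.data = np.expm1(expm1.data)
    detected = X.copy()
    detected.data = np.ones_like(detected.data)

    frames = []
    for cluster in clusters:
        in_mask = labels == cluster
        n_in = int(in_mask.sum())
        n_out = len(labels) - n_in
        if n_in < 3:
            warnings.warn(
                f"cluster {cluster!r} has {n_in} cells (< 3); excluded",
                stacklevel=2,
            )
            continue

        in_idx = np.flatnonzero(in_mask)
        out_idx = np.flatnonzero(~in_mask)
        mean_in = np.asarray(expm1[:, in_idx].sum(axis=1)).ravel() / n_in
        mean_out = np.asarray(expm1[:, out_idx].sum(axis=1)).ravel() / n_out
        pct_in = np.asarray(detected[:, in_idx].sum(axis=1)).ravel() / n_in
        pct_out = np.asarray(detected[:, out_idx].sum(axis=1)).ravel() / n_out
        log2fc = np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))

        tested = np.flatnonzero(
            (pct_in >= params.min_pct) & (log2fc >= params.min_log2fc)
        )
        if tested.size == 0:
            continue
        x_in = X[tested][:, in_idx].toarray()
        x_out = X[tested][:, out_idx].toarray()
        pvals = _wilcoxon_pvalues(x_in, x_out)
        padj = multipletests(pvals, method="fdr_bh")[1]

        frames.append(
            pd.DataFrame(
                {
                    "gene": gene_ids[tested],
                    "cluster": cluster,
                    "log2fc": log2fc[tested],
                    "pct_in": pct_in[tested],
                    "pct_out": pct_out[tested],
                    "p_value": pvals,
                    "p_adj": padj,
                    "is_marker": (padj < params.alpha) & (log2fc[tested] > 0),
                }
            )
        )

    if not frames:
        return pd.DataFrame(
            columns=[
                "gene", "cluster", "log2fc", "pct_in", "pct_out",
                "p_value", "p_adj", "is_marker",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        ["cluster", "p_value", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def marker_gene_sets(markers: pd.DataFrame) -> dict:
    """Map cluster -> set of its significant positive marker genes."""
    sig = markers[markers["is_marker"]]
    return {c: set(sub["gene"]) for c, sub in sig.groupby("cluster")}
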