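"""Readers and writers for the on-disk formats shared by all pipeline stages.

Conventions
-----------
* Count matrices are Matrix Market triplet files (1-based indices) with
  companion ``genes.tsv`` / ``barcodes.tsv`` (one entry per line, no header),
  or a dense tab-separated genes x cells table.
* All delimited tables are tab-separated with a header row.
* Gene symbols are compared case-sensitively (mouse nomenclature, e.g. the
  mitochondrial prefix ``mt-``).
* Missing peak-area cells are stored as 0 (peptide not observed), never NA,
  so the downstream "detected in all replicates" rule reads them as absent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import io as spio

from .errors import FormatError, ValidationError

log = logging.getLogger("evtrace")

#: The two experimental arms: control surgery and ischemia-reperfusion injury.
VALID_GROUPS = ("sham", "IRI")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x cells raw count matrix with per-cell metadata.

    Parameters
    ----------
    counts
        Sparse CSR matrix of non-negative integer counts, genes in rows.
    gene_ids
        Unique gene symbols, one per row of ``counts``.
    cell_ids
        Unique cell barcodes, one per column of ``counts``.
    cell_meta
        DataFrame indexed by barcode with columns ``sample_id`` and
        ``group`` (each group in ``{"sham", "IRI"}``).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene_ids contain duplicates (case-sensitive)")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("cell_ids contain duplicate barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts contain negative entries")
        if list(self.cell_meta.index) != list(self.cell_ids):
            raise ValidationError("cell_meta index does not match cell_ids")
        missing = {"sample_id", "group"} - set(self.cell_meta.columns)
        if missing:
            raise ValidationError(f"cell_meta lacks columns {sorted(missing)}")
        bad = set(self.cell_meta["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels {sorted(bad)}")

    # -- conveniences ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given cell mask/indices."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            counts=self.counts[:, keep].tocsr(),
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[keep],
            cell_meta=self.cell_meta.iloc[keep],
        )


@dataclasses.dataclass
class ProteinQuantTable:
    """Label-free LC-MS/MS protein quantification (peak areas) with design.

    ``areas`` holds one row per protein and one column per replicate sample,
    ordered as in ``replicate_ids``; ``design`` maps replicate -> group.
    """

    protein_ids: np.ndarray
    gene_symbols: np.ndarray
    areas: np.ndarray
    replicate_ids: np.ndarray
    design: pd.Series

    def __post_init__(self) -> None:
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.areas = np.asarray(self.areas, dtype=float)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_prot, n_rep = self.areas.shape
        if len(self.protein_ids) != n_prot or len(self.gene_symbols) != n_prot:
            raise ValidationError("protein id / gene symbol length mismatch")
        if len(self.replicate_ids) != n_rep:
            raise ValidationError(
                f"{n_rep} area columns but {len(self.replicate_ids)} replicates"
            )
        if len(set(self.protein_ids)) != n_prot:
            raise ValidationError("protein_id values are not unique")
        if not np.all(np.isfinite(self.areas)) or (self.areas < 0).any():
            raise ValidationError("areas must be finite and >= 0")
        if list(self.design.index) != list(self.replicate_ids):
            raise ValidationError("design index does not match replicate_ids")
        bad = set(self.design) - set(VALID_GROUPS)
        if bad:
            raise ValidationError(f"unknown groups in design: {sorted(bad)}")
        for group in set(self.design):
            if (self.design == group).sum() < 1:
                raise ValidationError(f"group {group} has no replicates")

    @property
    def n_proteins(self) -> int:
        return self.areas.shape[0]

    def replicate_columns(self, group: str) -> np.ndarray:
        """Column indices of the replicates belonging to ``group``."""
        if group not in set(self.design):
            raise ValidationError(f"group {group!r} absent from design")
        return np.flatnonzero((self.design == group).to_numpy())


# ---------------------------------------------------------------------------
# Count-matrix I/O
# ---------------------------------------------------------------------------

def _read_single_column(path) -> np.ndarray:
    items = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                items.append(line.split("\t")[0])
    return np.asarray(items, dtype=object)


def read_count_matrix(matrix_path, genes_path, barcodes_path,
                      meta_path=None) -> ExpressionMatrix:
    """Read a genes x cells count matrix with its companion files.

    ``matrix_path`` may be a Matrix Market triplet file (``.mtx``) or a dense
    tab-separated table without headers. ``meta_path`` is a TSV with columns
    ``cell_id``, ``sample_id``, ``group``; if omitted, all cells are assigned
    sample ``sample1`` in group ``sham``.
    """
    gene_ids = _read_single_column(genes_path)
    cell_ids = _read_single_column(barcodes_path)

    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        try:
            counts = sp.csr_matrix(spio.mmread(matrix_path))
        except ValueError as exc:
            raise FormatError(f"cannot parse MTX file {matrix_path}: {exc}") from exc
    else:
        try:
            dense = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy()
        except ValueError as exc:
            raise FormatError(f"cannot parse matrix {matrix_path}: {exc}") from exc
        counts = sp.csr_matrix(dense)

    if counts.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix header declares shape {counts.shape} but companion files "
            f"list {len(gene_ids)} genes and {len(cell_ids)} barcodes"
        )
    if len(set(cell_ids)) != len(cell_ids):
        raise ValidationError("duplicate barcodes in barcode file")
    if counts.nnz and counts.data.min() < 0:
        raise ValidationError("negative counts in matrix file")
    counts = counts.astype(np.int64)

    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        required = {"cell_id", "sample_id", "group"}
        if not required <= set(meta.columns):
            raise FormatError(
                f"cell-meta file must have columns {sorted(required)}"
            )
        if meta["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell_id rows in cell-meta file")
        meta = meta.set_index("cell_id")
        missing = [b for b in cell_ids if b not in meta.index]
        if missing:
            raise FormatError(
                f"cell-meta file lacks {len(missing)} barcodes "
                f"(first: {missing[0]})"
            )
        cell_meta = meta.loc[list(cell_ids), ["sample_id", "group"]]
    else:
        cell_meta = pd.DataFrame(
            {"sample_id": "sample1", "group": "sham"}, index=list(cell_ids)
        )
    cell_meta.index.name = "cell_id"

    return ExpressionMatrix(counts, gene_ids, cell_ids, cell_meta)


def write_count_matrix(matrix: ExpressionMatrix, out_dir) -> dict:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + cell_meta.tsv.

    Returns a dict of the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "cell_meta": out_dir / "cell_meta.tsv",
    }
    spio.mmwrite(str(paths["matrix"]), matrix.counts.tocoo(), field="integer")
    paths["genes"].write_text("\n".join(matrix.gene_ids) + "\n")
    paths["barcodes"].write_text("\n".join(matrix.cell_ids) + "\n")
    meta = matrix.cell_meta.reset_index()
    meta.columns = ["cell_id", "sample_id", "group"]
    meta.to_csv(paths["cell_meta"], sep="\t", index=False)
    return paths


def read_cluster_labels(path, cell_ids: Sequence) -> np.ndarray:
    """Read a TSV of columns ``cell_id``, ``cluster`` aligned to ``cell_ids``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "cluster"} <= set(df.columns):
        raise FormatError("labels file must have columns cell_id, cluster")
    mapping = dict(zip(df["cell_id"], df["cluster"]))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValidationError(
            f"labels file lacks {len(missing)} cells (first: {missing[0]})"
        )
    return np.asarray([mapping[c] for c in cell_ids], dtype=object)


def write_cluster_labels(cell_ids, labels, path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "cluster": labels}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Protein-quant I/O
# ---------------------------------------------------------------------------

def read_protein_quant(path, design_path) -> ProteinQuantTable:
    """Read a protein peak-area TSV and its replicate design.

    The quant table has columns ``protein_id``, ``gene_symbol`` and one
    numeric column per replicate; the design TSV has columns ``replicate``,
    ``group``. Empty area cells are read as 0 (not observed) and counted in a
    logged warning; any other non-numeric cell is a format error.
    """
    design_df = pd.read_csv(design_path, sep="\t", dtype=str)
    if not {"replicate", "group"} <= set(design_df.columns):
        raise FormatError("design file must have columns replicate, group")
    design = pd.Series(
        design_df["group"].to_numpy(), index=design_df["replicate"].to_numpy()
    )

    quant = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein_id", "gene_symbol"} <= set(quant.columns):
        raise FormatError("quant table must have protein_id and gene_symbol columns")
    area_cols = [c for c in quant.columns if c not in ("protein_id", "gene_symbol")]
    if list(area_cols) != list(design.index):
        raise FormatError(
            f"area columns {area_cols} do not match design replicates "
            f"{list(design.index)}"
        )

    n_missing = 0
    areas = np.empty((len(quant), len(area_cols)), dtype=float)
    for j, col in enumerate(area_cols):
        for i, raw in enumerate(quant[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                areas[i, j] = 0.0
                n_missing += 1
                continue
            try:
                areas[i, j] = float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"non-numeric area {raw!r} at row {i + 1} column {col!r}"
                ) from exc
    if n_missing:
        log.warning("read_protein_quant: %d missing area cells stored as 0", n_missing)

    return ProteinQuantTable(
        protein_ids=quant["protein_id"].to_numpy(dtype=object),
        gene_symbols=quant["gene_symbol"].to_numpy(dtype=object),
        areas=areas,
        replicate_ids=np.asarray(area_cols, dtype=object),
        design=design,
    )


def write_protein_quant(table: ProteinQuantTable, path, design_path) -> None:
    df = pd.DataFrame(table.areas, columns=list(table.replicate_ids))
    df.insert(0, "gene_symbol", table.gene_symbols)
    df.insert(0, "protein_id", table.protein_ids)
    df.to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {"replicate": table.replicate_ids, "group": table.design.to_numpy()}
    ).to_csv(design_path, sep="\t", index=False)


def read_protein_gene_mapping(path) -> dict:
    """Read an optional protein -> gene-symbol mapping TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein_id", "gene_symbol"} <= set(df.columns):
        raise FormatError("mapping file must have columns protein_id, gene_symbol")
    return dict(zip(df["protein_id"], df["gene_symbol"]))


# ---------------------------------------------------------------------------
# Trace report output
# ---------------------------------------------------------------------------

def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_trace_report(result, out_dir, manifest: Mapping | None = None) -> dict:
    """Write the per-cell s-EV% table, the per-cluster t-EV%/cell% table and
    a plain-text run manifest.

    ``result`` is an ``evtrace.ev_tracing.TraceResult``. Raises
    :class:`ValidationError` on an empty result before anything is written.
    """
    if len(result.cell_ids) == 0:
        raise ValidationError("trace result contains no cells; nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sev_path = out_dir / "sev_per_cell.tsv"
    pd.DataFrame(
        {
            "cell_id": result.cell_ids,
            "cluster": result.labels,
            "sev_pct": result.sev,
        }
    ).to_csv(sev_path, sep="\t", index=False)

    cluster_path = out_dir / "cluster_summary.tsv"
    pd.DataFrame(
        {
            "cluster": result.tev.index,
            "cell_pct": result.cell_pct.to_numpy(),
            "tev_pct": result.tev.to_numpy(),
        }
    ).to_csv(cluster_path, sep="\t", index=False)

    manifest_path = out_dir / "manifest.txt"
    entries = dict(manifest or {})
    entries.setdefault("n_proteins_used", result.n_proteins_used)
    entries.setdefault("n_cells", len(result.cell_ids))
    entries.setdefault("n_clusters", len(result.tev))
    lines = [f"{k}\t{entries[k]}" for k in sorted(entries)]
    manifest_path.write_text("\n".join(lines) + "\n")

    return {"sev": sev_path, "clusters": cluster_path, "manifest": manifest_path}
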