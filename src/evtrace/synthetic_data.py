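"""Synthetic scRNA-seq count matrices and EV protein-quant tables with known
ground truth, so every pipeline stage is testable without external data.

The generator emulates:

* cluster-structured negative-binomial counts with planted per-cluster marker
  genes (base means lognormal around ``nb_mean``; markers up-shifted by
  ``marker_log2fc`` in their cluster, base means floored at 0.3 so planted
  markers behave like robustly expressed cell-type genes);
* a small set of mitochondrial genes (``mt-`` prefix) so QC metrics are
  exercised;
* one dedicated "protein gene" per EV protein, expressed in the protein's
  source cluster. ``leakage`` is the expected fraction of a protein gene's
  normalized-expression mass lying outside its source cluster, spread
  uniformly over all cells like ambient background: with leakage = 0 the
  gene is exactly cluster-exclusive;
* replicate peak areas with lognormal noise of coefficient of variation
  ``replicate_cv``, rescaled per (group, cluster) so the realized group-mean
  per-cluster area fractions equal ``true_tev_fractions`` exactly — the
  ground truth the tracer must recover is therefore deterministic.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .io_formats import ExpressionMatrix, ProteinQuantTable
from .sc_preprocess import QCThresholds

log = logging.getLogger("evtrace")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _nb_draw(rng, mean, dispersion, size=None):
    """Negative binomial with mean/dispersion (size r): var = mu + mu^2/r."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the synthetic kidney dataset.

    Defaults: 3 clusters x 100 cells, 600 genes (10 mitochondrial, 10 planted
    markers per cluster at log2FC 2), 200 EV proteins drawn from per-cluster
    EV-output fractions 0.6/0.3/0.1 with 5% ambient leakage, 3 replicates per
    group with 20% replicate CV on peak areas.
    """

    n_clusters: int = 3
    cells_per_cluster: int = 100
    n_genes: int = 600
    n_marker_genes_per_cluster: int = 10
    marker_log2fc: float = 2.0
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    n_mito_genes: int = 10
    n_proteins: int = 200
    true_tev_fractions: tuple = (0.6, 0.3, 0.1)
    leakage: float = 0.05
    protein_gene_mean: float = 5.0
    n_replicates_per_group: int = 3
    replicate_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_tev_fractions) != self.n_clusters:
            raise ValidationError(
                "true_tev_fractions length must equal n_clusters"
            )
        if abs(sum(self.true_tev_fractions) - 1.0) > 1e-9:
            raise ValidationError("true_tev_fractions must sum to 1")
        if min(self.true_tev_fractions) < 0:
            raise ValidationError("true_tev_fractions must be non-negative")
        if not 0.0 <= self.leakage < 1.0:
            raise ValidationError("leakage must lie in [0, 1)")
        for field in (
            "n_clusters", "cells_per_cluster", "n_genes",
            "n_marker_genes_per_cluster", "n_replicates_per_group",
        ):
            if getattr(self, field) <= 0:
                raise ValidationError(f"{field} must be positive")
        if self.n_proteins < 0:
            raise ValidationError("n_proteins must be >= 0")
        needed = self.n_mito_genes + self.n_clusters * self.n_marker_genes_per_cluster
        if needed > self.n_genes:
            raise ValidationError(
                f"mito + marker genes ({needed}) exceed n_genes ({self.n_genes})"
            )


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth recorded alongside the generated data."""

    labels: np.ndarray
    marker_genes: dict            # cluster -> list of planted marker genes
    protein_genes: np.ndarray     # dedicated gene per protein
    protein_source_cluster: np.ndarray
    true_tev_fractions: pd.Series
    realized_tev_fractions: dict | None = None  # group -> per-cluster Series


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------

def generate_expression(
    config: SyntheticConfig, seed=None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the cluster-structured count matrix and its ground truth.

    Cells are split evenly over clusters; within each cluster they alternate
    between the sham and IRI groups and cycle over the replicate samples, so
    both groups see every cluster. Protein genes (one per EV protein, named
    ``EVG####``) are appended after the ``n_genes`` background/marker genes.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    K = config.n_clusters
    n_cells = K * config.cells_per_cluster
    clusters = [f"C{k}" for k in range(K)]
    labels = np.repeat(clusters, config.cells_per_cluster).astype(object)

    # cell metadata: alternate groups, cycle replicates within each cluster
    groups, samples = [], []
    for k in range(K):
        for i in range(config.cells_per_cluster):
            g = "sham" if i % 2 == 0 else "IRI"
            r = (i // 2) % config.n_replicates_per_group + 1
            groups.append(g)
            samples.append(f"{g}_{r}")
    cell_ids = np.asarray([f"cell{j:05d}" for j in range(n_cells)], dtype=object)
    cell_meta = pd.DataFrame(
        {"sample_id": samples, "group": groups}, index=list(cell_ids)
    )
    cell_meta.index.name = "cell_id"

    # gene names: mitochondrial first, then background
    gene_ids = [f"mt-Sim{i + 1}" for i in range(config.n_mito_genes)]
    gene_ids += [f"G{i:04d}" for i in range(config.n_genes - config.n_mito_genes)]

    # base means, lognormal around nb_mean
    mu = rng.lognormal(mean=np.log(config.nb_mean), sigma=1.0, size=config.n_genes)

    # plant markers among non-mito genes
    candidates = np.arange(config.n_mito_genes, config.n_genes)
    marker_idx = rng.choice(
        candidates, size=K * config.n_marker_genes_per_cluster, replace=False
    )
    marker_genes: dict = {}
    mean_matrix = np.tile(mu[:, None], (1, n_cells))
    for k, cluster in enumerate(clusters):
        idx = marker_idx[
            k * config.n_marker_genes_per_cluster:(k + 1) * config.n_marker_genes_per_cluster
        ]
        # floor keeps planted markers robustly expressed
        mean_matrix[idx, :] = np.maximum(mu[idx], 0.3)[:, None]
        in_cells = labels == cluster
        mean_matrix[np.ix_(idx, in_cells)] *= 2.0 ** config.marker_log2fc
        marker_genes[cluster] = [gene_ids[i] for i in idx]

    counts = _nb_draw(rng, mean_matrix, config.nb_dispersion)

    # protein genes: in-cluster NB counts; off-cluster mass added below
    src_idx = rng.choice(K, size=config.n_proteins, p=list(config.true_tev_fractions))
    protein_source = np.asarray([clusters[k] for k in src_idx], dtype=object)
    protein_gene_names = np.asarray(
        [f"EVG{i:04d}" for i in range(config.n_proteins)], dtype=object
    )
    prot_counts = np.zeros((config.n_proteins, n_cells), dtype=np.int64)
    group_arr = np.asarray(groups, dtype=object)
    for i in range(config.n_proteins):
        in_cells = np.flatnonzero(labels == protein_source[i])
        row = _nb_draw(rng, config.protein_gene_mean, config.nb_dispersion,
                       size=in_cells.size)
        # guarantee the gene is detected within each group's cells
        for g in ("sham", "IRI"):
            gmask = group_arr[in_cells] == g
            while gmask.any() and row[gmask].sum() == 0:
                row[np.flatnonzero(gmask)] = _nb_draw(
                    rng, config.protein_gene_mean, config.nb_dispersion,
                    size=int(gmask.sum()),
                )
        prot_counts[i, in_cells] = row

    all_counts = np.vstack([counts, prot_counts])

    if config.leakage > 0 and config.n_proteins > 0:
        _add_ambient_leakage(
            all_counts, config, labels, protein_source, clusters, rng
        )

    matrix = ExpressionMatrix(
        counts=sp.csr_matrix(all_counts),
        gene_ids=np.asarray(gene_ids + list(protein_gene_names), dtype=object),
        cell_ids=cell_ids,
        cell_meta=cell_meta,
    )
    truth = SyntheticTruth(
        labels=labels,
        marker_genes=marker_genes,
        protein_genes=protein_gene_names,
        protein_source_cluster=protein_source,
        true_tev_fractions=pd.Series(
            list(config.true_tev_fractions), index=clusters
        ),
    )
    return matrix, truth


def _add_ambient_leakage(all_counts, config, labels, protein_source, clusters, rng):
    """Add off-cluster counts to each protein gene until the off-cluster
    share of its normalized-expression mass reaches the leakage target.

    The target off-share is ``leakage * n_off / n_total`` (ambient mass
    spread uniformly over all cells). Cell totals are taken before the
    additions; the added counts are small relative to library sizes, so the
    achieved shares are approximate but unbiased slightly below target (the
    closest-stop rule never overshoots by more than the last cell's mass).
    """
    n_cells = all_counts.shape[1]
    n_background = all_counts.shape[0] - config.n_proteins
    totals = all_counts.sum(axis=0).astype(float)
    for i in range(config.n_proteins):
        g = n_background + i
        in_cells = labels == protein_source[i]
        off_cells = np.flatnonzero(~in_cells)
        norm_row = np.log1p(1e4 * all_counts[g] / totals)
        in_mass = norm_row[in_cells].sum()
        off_share = config.leakage * off_cells.size / n_cells
        target = off_share / (1.0 - off_share) * in_mass
        if target <= 0:
            continue
        order = rng.permutation(off_cells)
        cum = 0.0
        for j in order:
            c = int(_nb_draw(rng, config.protein_gene_mean, config.nb_dispersion))
            if c == 0:
                c = 1
            mass = np.log1p(1e4 * c / totals[j])
            if cum + mass - target > target - cum:
                break
            all_counts[g, j] = c
            cum += mass
            if cum >= target:
                break


# ---------------------------------------------------------------------------
# EV quantification generator
# ---------------------------------------------------------------------------

def generate_ev_quant(
    expression: ExpressionMatrix,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    seed=None,
) -> tuple[ProteinQuantTable, pd.DataFrame]:
    """Generate replicate peak areas and the protein -> gene mapping.

    Base areas are lognormal (median 1e6, like label-free peak areas);
    replicates multiply lognormal noise with CV ``replicate_cv``. Replicate
    areas are then rescaled per (group, cluster) so the realized group-mean
    per-cluster fractions equal ``true_tev_fractions`` exactly; the realized
    fractions are recorded in ``truth.realized_tev_fractions``.
    """
    rng = _as_rng(config.seed + 1 if seed is None else seed)
    if config.n_proteins == 0:
        raise ValidationError("config.n_proteins is 0; nothing to quantify")
    n = config.n_proteins
    protein_ids = np.asarray([f"P{i:05d}" for i in range(n)], dtype=object)

    base = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=n)
    sigma = np.sqrt(np.log(1.0 + config.replicate_cv**2))
    n_rep = config.n_replicates_per_group
    replicate_ids = [f"sham_{r + 1}" for r in range(n_rep)] + [
        f"IRI_{r + 1}" for r in range(n_rep)
    ]
    design = pd.Series(
        ["sham"] * n_rep + ["IRI"] * n_rep, index=replicate_ids
    )
    areas = base[:, None] * rng.lognormal(mean=0.0, sigma=sigma, size=(n, 2 * n_rep))
    n_resampled = 0
    while (areas == 0).any():  # lognormal draws are > 0; guard for safety
        zero = areas == 0
        areas[zero] = base[np.where(zero)[0]] * rng.lognormal(
            0.0, sigma, size=int(zero.sum())
        )
        n_resampled += int(zero.sum())
    if n_resampled:
        log.warning("generate_ev_quant: resampled %d zero areas", n_resampled)

    # rescale so realized per-cluster group-mean fractions match truth exactly
    clusters = list(truth.true_tev_fractions.index)
    realized: dict = {}
    for g, cols in (("sham", range(n_rep)), ("IRI", range(n_rep, 2 * n_rep))):
        cols = np.asarray(list(cols))
        means = areas[:, cols].mean(axis=1)
        total = means.sum()
        for cluster in clusters:
            members = truth.protein_source_cluster == cluster
            if not members.any():
                log.warning(
                    "cluster %s received no proteins; its fraction is unrealizable",
                    cluster,
                )
                continue
            frac = truth.true_tev_fractions[cluster]
            scale = frac * total / means[members].sum()
            areas[np.ix_(members, cols)] *= scale
        means = areas[:, cols].mean(axis=1)
        realized[g] = pd.Series(
            [means[truth.protein_source_cluster == c].sum() / means.sum()
             for c in clusters],
            index=clusters,
        )
    truth.realized_tev_fractions = realized

    table = ProteinQuantTable(
        protein_ids=protein_ids,
        gene_symbols=truth.protein_genes,
        areas=areas,
        replicate_ids=np.asarray(replicate_ids, dtype=object),
        design=design,
    )
    mapping = pd.DataFrame(
        {"protein_id": protein_ids, "gene_symbol": truth.protein_genes}
    )
    return table, mapping


# ---------------------------------------------------------------------------
# QC fixture generator
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QCViolationSpec:
    """Counts of planted QC violations in a fixture.

    ``n_boundary_genes`` cells sit exactly at the min-genes bound (kept under
    the strict ``< min_genes`` removal rule); ``n_boundary_mito`` cells sit
    exactly at the mito bound (removed under ``>= max_mito_fraction``).
    """

    n_low_genes: int = 0
    n_high_genes: int = 0
    n_high_mito: int = 0
    n_boundary_genes: int = 0
    n_boundary_mito: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.n_low_genes + self.n_high_genes + self.n_high_mito
            + self.n_boundary_mito
        )

    @property
    def n_special(self) -> int:
        return self.n_removed + self.n_boundary_genes


def generate_qc_fixture(
    n_cells: int,
    violations: QCViolationSpec,
    seed=None,
    thresholds: QCThresholds | None = None,
) -> tuple[ExpressionMatrix, int]:
    """Build a count matrix with exactly the planted QC violations.

    Returns the matrix and the expected survivor count under ``thresholds``
    (defaults). Violating and boundary cells are placed at random positions.
    """
    thresholds = thresholds or QCThresholds()
    rng = _as_rng(seed)
    if violations.n_special > n_cells:
        raise ValidationError(
            f"{violations.n_special} special cells exceed n_cells={n_cells}"
        )
    n_genes = thresholds.max_genes + 50
    # q non-mito genes at count 1 for unremarkable cells; q is a multiple of 3
    # inside (min_genes, max_genes) so a boundary-mito cell can carry mito
    # count q/3 over non-mito total q, i.e. mito fraction exactly 1/4 (the
    # boundary constructions assume the default 0.25 mito bound).
    q = 3 * ((min(thresholds.min_genes + 702, thresholds.max_genes - 2)) // 3)
    if not thresholds.min_genes <= q + 1 <= thresholds.max_genes:
        raise ValidationError("thresholds too narrow for fixture construction")

    kinds = (
        ["low"] * violations.n_low_genes
        + ["high"] * violations.n_high_genes
        + ["mito"] * violations.n_high_mito
        + ["bgene"] * violations.n_boundary_genes
        + ["bmito"] * violations.n_boundary_mito
        + ["ok"] * (n_cells - violations.n_special)
    )
    kinds = [kinds[i] for i in rng.permutation(n_cells)]

    rows, cols, vals = [], [], []

    def put(cell, gene_indices, counts):
        rows.extend(gene_indices)
        cols.extend([cell] * len(gene_indices))
        vals.extend(counts)

    for j, kind in enumerate(kinds):
        if kind == "ok":
            # q+1 detected genes incl. one low mito count
            put(j, [0], [1])
            put(j, list(range(1, q + 1)), [1] * q)
        elif kind == "low":
            put(j, list(range(1, thresholds.min_genes)), [1] * (thresholds.min_genes - 1))
        elif kind == "bgene":
            # exactly min_genes detected -> kept under the strict "<" rule
            put(j, list(range(1, thresholds.min_genes + 1)), [1] * thresholds.min_genes)
        elif kind == "high":
            put(j, list(range(1, thresholds.max_genes + 2)), [1] * (thresholds.max_genes + 1))
        elif kind == "mito":
            # mito fraction q/(2q+... ) ~ 0.5, clearly above any sane bound
            put(j, [0], [q])
            put(j, list(range(1, q + 1)), [1] * q)
        elif kind == "bmito":
            # mito q/3 over non-mito q -> fraction exactly 0.25 -> removed
            put(j, [0], [q // 3])
            put(j, list(range(1, q + 1)), [1] * q)

    gene_ids = ["mt-Fix1"] + [f"Q{i:05d}" for i in range(1, n_genes)]
    cell_ids = [f"qc_cell{j:04d}" for j in range(n_cells)]
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_genes, n_cells), dtype=np.int64
    )
    meta = pd.DataFrame(
        {"sample_id": "fixture", "group": "sham"}, index=cell_ids
    )
    meta.index.name = "cell_id"
    matrix = ExpressionMatrix(counts, np.asarray(gene_ids, dtype=object),
                              np.asarray(cell_ids, dtype=object), meta)
    expected_survivors = n_cells - violations.n_removed
    return matrix, expected_survivors
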