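import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from evtrace.io_formats import ExpressionMatrix, ProteinQuantTable


def make_matrix(dense, gene_ids=None, groups=None, samples=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a dense genes x cells array."""
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{j}" for j in range(n_cells)]
    groups = groups or ["sham"] * n_cells
    samples = samples or ["s1"] * n_cells
    meta = pd.DataFrame({"sample_id": samples, "group": groups}, index=cell_ids)
    meta.index.name = "cell_id"
    return ExpressionMatrix(sp.csr_matrix(dense), np.asarray(gene_ids, dtype=object),
                            np.asarray(cell_ids, dtype=object), meta)


def make_quant(areas, genes=None, n_sham=3) -> ProteinQuantTable:
    """Build a ProteinQuantTable from a proteins x replicates array; the
    first ``n_sham`` columns are sham replicates, the rest IRI."""
    areas = np.asarray(areas, dtype=float)
    n_prot, n_rep = areas.shape
    genes = genes or [f"g{i}" for i in range(n_prot)]
    reps = [f"sham_{i+1}" for i in range(n_sham)] + [
        f"IRI_{i+1}" for i in range(n_rep - n_sham)
    ]
    design = pd.Series(["sham"] * n_sham + ["IRI"] * (n_rep - n_sham), index=reps)
    return ProteinQuantTable(
        protein_ids=np.asarray([f"P{i}" for i in range(n_prot)], dtype=object),
        gene_symbols=np.asarray(genes, dtype=object),
        areas=areas,
        replicate_ids=np.asarray(reps, dtype=object),
        design=design,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
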