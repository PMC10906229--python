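import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from evtrace import sc_preprocess as sc
from evtrace.errors import ValidationError
from evtrace.synthetic_data import SyntheticConfig, generate_expression

from conftest import make_matrix


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------

def test_qc_metrics_direct_arithmetic():
    """A cell with counts {geneA: 3, mt-Nd1: 1} has 2 detected genes and
    mitochondrial fraction 1/4."""
    m = make_matrix([[3], [1]], gene_ids=["geneA", "mt-Nd1"])
    metrics = sc.compute_qc_metrics(m)
    assert metrics["n_genes_detected"].iloc[0] == 2
    assert metrics["mito_fraction"].iloc[0] == pytest.approx(0.25)


def test_qc_metrics_zero_count_cell_flagged():
    m = make_matrix([[3, 0], [1, 0]], gene_ids=["geneA", "mt-Nd1"])
    metrics = sc.compute_qc_metrics(m)
    assert metrics["n_genes_detected"].iloc[1] == 0
    assert metrics["mito_fraction"].iloc[1] == 0.0
    assert bool(metrics["zero_total"].iloc[1])


def test_qc_metrics_no_mito_gene_warns_not_errors():
    m = make_matrix([[1, 2]], gene_ids=["geneA"])
    with pytest.warns(UserWarning, match="mt-"):
        metrics = sc.compute_qc_metrics(m)
    assert (metrics["mito_fraction"] == 0).all()


def test_qc_metrics_match_per_cell_loop_oracle(rng):
    dense = rng.poisson(0.8, size=(40, 100))
    gene_ids = [f"mt-{i}" if i < 5 else f"g{i}" for i in range(40)]
    m = make_matrix(dense, gene_ids=gene_ids)
    metrics = sc.compute_qc_metrics(m)
    for j in range(100):
        col = dense[:, j]
        assert metrics["n_genes_detected"].iloc[j] == int((col > 0).sum())
        total = col.sum()
        expected = col[:5].sum() / total if total else 0.0
        assert metrics["mito_fraction"].iloc[j] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Cell filtering
# ---------------------------------------------------------------------------

def boundary_matrix():
    """Six cells around the QC bounds: 499 / 500 / 6001 / 6000 detected
    genes, mito exactly 0.25 and just below."""
    n_genes = 6050
    dense = np.zeros((n_genes, 6), dtype=int)
    dense[1:500, 0] = 1              # 499 detected -> removed (min_genes)
    dense[1:501, 1] = 1              # 500 detected -> kept
    dense[1:6002, 2] = 1             # 6001 detected -> removed (max_genes)
    dense[1:6001, 3] = 1             # 6000 detected -> kept
    dense[1:601, 4] = 1              # mito 200/800 = 0.25 -> removed
    dense[0, 4] = 200
    dense[1:601, 5] = 1              # mito 199/799 = 0.249 -> kept
    dense[0, 5] = 199
    gene_ids = ["mt-X"] + [f"g{i}" for i in range(1, n_genes)]
    return make_matrix(dense, gene_ids=gene_ids)


def test_filter_cells_strict_boundary_semantics():
    m = boundary_matrix()
    metrics = sc.compute_qc_metrics(m)
    filtered, report = sc.filter_cells(m, metrics)
    kept = set(filtered.cell_ids)
    assert kept == {"c1", "c3", "c5"}
    assert report.removed_low_genes == 1
    assert report.removed_high_genes == 1
    assert report.removed_high_mito == 1
    assert report.n_input == report.n_kept + report.removed_low_genes \
        + report.removed_high_genes + report.removed_high_mito


def test_filter_cells_matches_brute_force(rng):
    thresholds = sc.QCThresholds(min_genes=5, max_genes=20, max_mito_fraction=0.25)
    dense = rng.poisson(0.6, size=(30, 50))
    gene_ids = [f"mt-{i}" if i < 3 else f"g{i}" for i in range(30)]
    m = make_matrix(dense, gene_ids=gene_ids)
    metrics = sc.compute_qc_metrics(m)
    filtered, report = sc.filter_cells(m, metrics, thresholds)

    survivors = []
    for j in range(50):
        col = dense[:, j]
        n = int((col > 0).sum())
        total = col.sum()
        mito = col[:3].sum() / total if total else 0.0
        if thresholds.min_genes <= n <= thresholds.max_genes and mito < 0.25:
            survivors.append(f"c{j}")
    assert list(filtered.cell_ids) == survivors
    assert report.n_kept == len(survivors)


def test_filter_cells_idempotent(rng):
    dense = rng.poisson(1.0, size=(30, 40))
    m = make_matrix(dense)
    thresholds = sc.QCThresholds(min_genes=5, max_genes=25, max_mito_fraction=0.25)
    with pytest.warns(UserWarning):
        once, _ = sc.filter_cells(m, sc.compute_qc_metrics(m), thresholds)
        twice, report = sc.filter_cells(
            once, sc.compute_qc_metrics(once), thresholds
        )
    assert report.n_kept == once.n_cells
    assert (twice.counts != once.counts).nnz == 0


def test_filter_survivors_invariant_under_cell_permutation(rng):
    dense = rng.poisson(1.0, size=(30, 40))
    gene_ids = [f"mt-{i}" if i < 2 else f"g{i}" for i in range(30)]
    thresholds = sc.QCThresholds(min_genes=5, max_genes=25, max_mito_fraction=0.25)
    m = make_matrix(dense, gene_ids=gene_ids)
    perm = rng.permutation(40)
    mp = make_matrix(dense[:, perm], gene_ids=gene_ids)
    f1, _ = sc.filter_cells(m, sc.compute_qc_metrics(m), thresholds)
    f2, _ = sc.filter_cells(mp, sc.compute_qc_metrics(mp), thresholds)
    # same surviving columns of the original matrix, up to reordering
    kept1 = {tuple(np.asarray(f1.counts[:, j].todense()).ravel()) for j in range(f1.n_cells)}
    kept2 = {tuple(np.asarray(f2.counts[:, j].todense()).ravel()) for j in range(f2.n_cells)}
    assert f1.n_cells == f2.n_cells
    assert kept1 == kept2


def test_filter_cells_all_removed_is_error():
    m = make_matrix([[1, 1], [0, 1]], gene_ids=["g1", "g2"])
    with pytest.warns(UserWarning):
        metrics = sc.compute_qc_metrics(m)
    with pytest.raises(ValidationError, match="threshold"):
        sc.filter_cells(m, metrics, sc.QCThresholds(min_genes=10, max_genes=20))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def test_normalize_closed_forms():
    dense = np.zeros((2, 1), dtype=int)
    dense[0, 0] = 1
    dense[1, 0] = 9999
    m = make_matrix(dense)
    X = sc.normalize_cp10k_log(m)
    # cell total 10000, count 1 -> log(2); count 0 stays 0
    assert X[0, 0] == pytest.approx(np.log(2.0))
    dense2 = np.array([[0, 3], [5, 1]])
    X2 = sc.normalize_cp10k_log(make_matrix(dense2))
    assert X2[0, 0] == 0.0


def test_normalize_matches_per_entry_loop_oracle(rng):
    dense = rng.poisson(2.0, size=(15, 12)) + np.eye(15, 12, dtype=int)
    m = make_matrix(dense)
    X = np.asarray(sc.normalize_cp10k_log(m).todense())
    totals = dense.sum(axis=0)
    for i in range(15):
        for j in range(12):
            expected = np.log1p(1e4 * dense[i, j] / totals[j])
            assert X[i, j] == pytest.approx(expected, abs=1e-12)


def test_normalize_rejects_zero_total_cell():
    m = make_matrix([[1, 0], [1, 0]])
    with pytest.raises(ValidationError):
        sc.normalize_cp10k_log(m)


# ---------------------------------------------------------------------------
# Marker detection
# ---------------------------------------------------------------------------

def two_cluster_norm(values_a, values_b):
    """One-gene normalized matrix over two labelled cell groups."""
    import scipy.sparse as sp
    X = sp.csr_matrix(np.asarray([list(values_a) + list(values_b)], dtype=float))
    labels = np.asarray(
        ["A"] * len(values_a) + ["B"] * len(values_b), dtype=object
    )
    return X, labels


def enumeration_rank_p(x, y):
    """Exhaustive two-sided rank-sum p: fraction of group assignments whose
    U deviates from its mean at least as much as observed (midranks)."""
    vals = np.concatenate([x, y])
    ranks = stats.rankdata(vals)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(vals)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    return count / total


def test_small_sample_rank_test_equals_enumeration_oracle():
    """8 cells, one gene, cluster A = {3,3,3,3}, cluster B = {0,0,0,0}."""
    X, labels = two_cluster_norm([3.0] * 4, [0.0] * 4)
    markers = sc.find_all_markers(
        X, ["gene1"], labels, sc.MarkerParams(min_log2fc=0.0, min_pct=0.0)
    )
    row = markers[markers.cluster == "A"].iloc[0]
    oracle = enumeration_rank_p(np.array([3.0] * 4), np.array([0.0] * 4))
    assert row["p_value"] == pytest.approx(oracle, abs=1e-12)
    assert oracle == pytest.approx(2 / 70)


@pytest.mark.parametrize("seed", [0, 1])
def test_small_sample_rank_test_random_values_match_oracle(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(1, 1, 6), rng.normal(0, 1, 5)
    X, labels = two_cluster_norm(np.abs(a), np.abs(b))
    markers = sc.find_all_markers(
        X, ["gene1"], labels, sc.MarkerParams(min_log2fc=-np.inf, min_pct=0.0)
    )
    for cluster, x, y in (("A", np.abs(a), np.abs(b)), ("B", np.abs(b), np.abs(a))):
        row = markers[markers.cluster == cluster].iloc[0]
        assert row["p_value"] == pytest.approx(enumeration_rank_p(x, y), abs=1e-12)


def test_constant_gene_is_no_marker():
    """A gene identical in every cell has log2fc 0 and fails the pre-filter."""
    import scipy.sparse as sp
    X = sp.csr_matrix(np.full((1, 30), 2.0))
    labels = np.asarray(["A"] * 10 + ["B"] * 20, dtype=object)
    markers = sc.find_all_markers(X, ["gene1"], labels)
    assert len(markers) == 0


def test_planted_marker_recovered_in_three_clusters():
    """A gene expressed only in cluster A of a 3-cluster, 100-cells-per-
    cluster dataset is an A marker at adjusted p < 0.05."""
    cfg = SyntheticConfig(n_proteins=0, seed=11)
    matrix, truth = generate_expression(cfg, seed=11)
    norm = sc.normalize_cp10k_log(matrix)
    markers = sc.find_all_markers(norm, matrix.gene_ids, truth.labels)
    found = {
        (r.gene, r.cluster)
        for r in markers[markers.is_marker].itertuples()
    }
    planted = {(g, c) for c, gs in truth.marker_genes.items() for g in gs}
    assert planted <= found


def test_small_cluster_excluded_with_warning():
    import scipy.sparse as sp
    X = sp.csr_matrix(np.ones((1, 10)))
    labels = np.asarray(["A"] * 8 + ["B"] * 2, dtype=object)
    with pytest.warns(UserWarning, match="excluded"):
        markers = sc.find_all_markers(
            X, ["gene1"], labels, sc.MarkerParams(min_log2fc=-np.inf, min_pct=0.0)
        )
    assert "B" not in set(markers["cluster"])


def test_padj_monotone_and_at_least_pvalue(rng):
    dense = rng.poisson(1.0, size=(60, 90))
    dense[:10, :30] += rng.poisson(2.0, size=(10, 30))
    m = make_matrix(dense)
    labels = np.asarray(["A"] * 30 + ["B"] * 60, dtype=object)
    markers = sc.find_all_markers(
        sc.normalize_cp10k_log(m), m.gene_ids, labels,
        sc.MarkerParams(min_log2fc=-np.inf, min_pct=0.0),
    )
    assert (markers["p_adj"] >= markers["p_value"] - 1e-15).all()
    for _, sub in markers.groupby("cluster"):
        ordered = sub.sort_values("p_value")
        assert (np.diff(ordered["p_adj"]) >= -1e-12).all()


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_marker_pct_bounds_property(seed):
    """pct_in/pct_out always lie in [0, 1] and tested rows respect filters."""
    rng = np.random.default_rng(seed)
    dense = rng.poisson(0.7, size=(12, 24))
    dense[0, :] += 1  # keep cell totals positive
    m = make_matrix(dense)
    labels = np.asarray(["A", "B", "C"] * 8, dtype=object)
    params = sc.MarkerParams(min_log2fc=0.1, min_pct=0.2)
    markers = sc.find_all_markers(
        sc.normalize_cp10k_log(m), m.gene_ids, labels, params
    )
    assert markers["pct_in"].between(0, 1).all()
    assert markers["pct_out"].between(0, 1).all()
    assert (markers["pct_in"] >= params.min_pct).all()
    assert (markers["log2fc"] >= params.min_log2fc).all()
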