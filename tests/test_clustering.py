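"""Variable genes, PCA, balanced kNN, Leiden, DEGs, quality flags, markers."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

import tmekit as tk
from tmekit import clustering as cl

from conftest import make_adata


# ---------------------------------------------------------------------------
# variable genes / PCA
# ---------------------------------------------------------------------------

def test_variable_genes_tie_rule_on_constant_matrix():
    adata = make_adata(np.ones((5, 6)), gene_names=["f", "b", "d", "a", "c", "e"])
    assert cl.select_variable_genes(tk.normalize(adata), 5) == ["a", "b", "c", "d", "e"]


def test_variable_genes_full_list_is_permutation():
    rng = np.random.default_rng(0)
    adata = make_adata(rng.integers(0, 9, (20, 8)) + 1)
    norm = tk.normalize(adata)
    got = cl.select_variable_genes(norm, 8)
    assert sorted(got) == sorted(norm.var_names)


def test_variable_genes_capture_planted_markers(clustering_norm, clustering_cohort):
    _, _, truth = clustering_cohort
    markers = set(
        truth.gene_modules.index[truth.gene_modules.str.startswith("marker:")]
    )
    top = set(cl.select_variable_genes(clustering_norm, 2 * len(markers)))
    assert markers <= top


def test_pca_matches_dense_eigendecomposition():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(60, 12))
    adata = make_adata(np.zeros_like(X))
    adata.X = X
    genes = list(adata.var_names)
    emb = cl.embed_pca(adata, genes, 5)
    cov = np.cov(X.T, ddof=1)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1][:5]
    np.testing.assert_allclose(emb.var(axis=0, ddof=1), eig, rtol=1e-8)


def test_pca_rank2_reconstruction_and_duplicates():
    rng = np.random.default_rng(2)
    X = np.outer(rng.normal(size=30), rng.normal(size=8)) + np.outer(
        rng.normal(size=30), rng.normal(size=8)
    )
    X = np.vstack([X, X[:1]])  # duplicated cell
    adata = make_adata(np.zeros_like(X))
    adata.X = X
    emb = cl.embed_pca(adata, list(adata.var_names), 2)
    np.testing.assert_allclose(emb[-1], emb[0], atol=1e-8)
    # rank-2 data: 2 components capture everything
    resid = X - X.mean(0) - emb @ np.linalg.pinv(emb) @ (X - X.mean(0))
    assert np.abs(resid).max() < 1e-8


# ---------------------------------------------------------------------------
# balanced kNN
# ---------------------------------------------------------------------------

def brute_force_balanced_edges(emb, batches, k):
    n = len(emb)
    edges = set()
    for i in range(n):
        for b in np.unique(batches):
            idx = [j for j in np.flatnonzero(batches == b) if j != i]
            d = [(np.linalg.norm(emb[i] - emb[j]), j) for j in idx]
            for _, j in sorted(d)[:k]:
                edges.add(frozenset((i, j)))
    return edges


def test_balanced_knn_equals_brute_force():
    rng = np.random.default_rng(3)
    emb = rng.normal(size=(30, 4))
    batches = np.array(["a", "b"] * 15)
    adj = cl.build_balanced_knn(emb, batches, k_within=3)
    got = {
        frozenset((i, j))
        for i, j in zip(*adj.nonzero())
    }
    assert got == brute_force_balanced_edges(emb, batches, 3)


def test_balanced_knn_single_batch_is_plain_knn():
    rng = np.random.default_rng(4)
    emb = rng.normal(size=(25, 3))
    adj = cl.build_balanced_knn(emb, np.repeat("x", 25), k_within=4)
    assert got_symmetric(adj)
    assert adj.nonzero()[0].size >= 25 * 4  # union-symmetrized plain kNN


def got_symmetric(adj):
    return (adj != adj.T).nnz == 0


def test_balanced_knn_duplicated_batches_link_twins():
    rng = np.random.default_rng(5)
    emb = rng.normal(size=(10, 3))
    both = np.vstack([emb, emb])
    batches = np.array(["a"] * 10 + ["b"] * 10)
    adj = cl.build_balanced_knn(both, batches, k_within=1)
    for i in range(10):
        assert adj[i, i + 10] == 1  # each cell links to its duplicate


def test_balanced_knn_small_batch_warns():
    rng = np.random.default_rng(6)
    emb = rng.normal(size=(6, 2))
    batches = np.array(["a"] * 4 + ["b"] * 2)
    with pytest.warns(UserWarning, match="batch"):
        cl.build_balanced_knn(emb, batches, k_within=3)


# ---------------------------------------------------------------------------
# Leiden
# ---------------------------------------------------------------------------

def test_leiden_two_cliques_one_bridge():
    n = 8
    A = np.zeros((2 * n, 2 * n))
    A[:n, :n] = 1
    A[n:, n:] = 1
    np.fill_diagonal(A, 0)
    A[0, n] = A[n, 0] = 1
    labels = cl.leiden_cluster(sp.csr_matrix(A), resolution=1.0, seed=0)
    assert len(set(labels[:n])) == 1 and len(set(labels[n:])) == 1
    assert labels[0] != labels[-1]


def test_leiden_deterministic_under_seed(clustering_norm):
    genes = cl.select_variable_genes(clustering_norm, 200)
    emb = cl.embed_pca(clustering_norm, genes, 30)
    adj = cl.build_balanced_knn(emb, clustering_norm.obs["batch"].to_numpy(), 3)
    l1 = cl.leiden_cluster(adj, seed=9)
    l2 = cl.leiden_cluster(adj, seed=9)
    np.testing.assert_array_equal(l1, l2)


def test_leiden_rejects_empty_graph():
    with pytest.raises(ValueError):
        cl.leiden_cluster(sp.csr_matrix((0, 0)))


# ---------------------------------------------------------------------------
# two-round recovery on the synthetic cohort
# ---------------------------------------------------------------------------

def test_two_round_recovers_planted_structure(clustering_norm, clustering_cohort):
    _, _, truth = clustering_cohort
    res = tk.two_round_cluster(
        clustering_norm,
        seed=0,
        sub_resolution=0.3,
        marker_map=truth.major_marker_map(),
    )
    assert adjusted_rand_score(truth.cell_major, res["major"]) >= 0.9
    assert adjusted_rand_score(truth.cell_minor, res["minor"]) >= 0.9
    # namespacing: minor ids of different majors are disjoint
    for m in res["major"].unique():
        minors_here = set(res.loc[res["major"] == m, "minor"])
        minors_there = set(res.loc[res["major"] != m, "minor"])
        assert not minors_here & minors_there


def test_subcluster_skips_small_majors(clustering_norm):
    labels = pd.Series("A", index=clustering_norm.obs_names)
    labels.iloc[:30] = "tiny"
    with pytest.warns(UserWarning, match="skipped"):
        out = cl.subcluster(clustering_norm, labels, "tiny", min_size=100)
    assert out is None


# ---------------------------------------------------------------------------
# DEGs
# ---------------------------------------------------------------------------

def test_deg_pvalues_match_scipy_per_gene(clustering_norm, clustering_cohort):
    _, _, truth = clustering_cohort
    labels = truth.cell_minor
    degs = tk.find_cluster_degs(clustering_norm, labels)
    cluster = sorted(labels.unique())[0]
    sub = degs[degs["cluster"] == cluster].set_index("gene")
    X = np.asarray(clustering_norm.X)
    mask = (labels == cluster).to_numpy()
    rng = np.random.default_rng(0)
    for gi in rng.choice(clustering_norm.n_vars, 15, replace=False):
        gene = clustering_norm.var_names[gi]
        ref = sps.mannwhitneyu(
            X[mask, gi], X[~mask, gi], alternative="two-sided", method="asymptotic"
        )
        assert sub.loc[gene, "pval"] == pytest.approx(float(ref.pvalue), rel=1e-9)


def test_constant_gene_is_not_deg():
    counts = np.ones((20, 4))
    counts[:, 1] = [5] * 10 + [1] * 10  # one informative gene
    counts[:, 2] = np.arange(20) % 3 + 1
    counts[:, 3] = 20 - counts[:, :3].sum(axis=1)  # equalize depth
    adata = make_adata(counts)
    norm = tk.normalize(adata)
    labels = np.array(["A"] * 10 + ["B"] * 10)
    degs = tk.find_cluster_degs(norm, labels)
    flat = degs[(degs["gene"] == "g0")]
    assert not flat["is_deg"].any()
    assert (flat["pval"] > 0.9).all()


def test_planted_markers_are_degs_of_their_cluster_only(
    clustering_norm, clustering_cohort
):
    _, _, truth = clustering_cohort
    degs = tk.find_cluster_degs(clustering_norm, truth.cell_minor)
    hit = degs[degs["is_deg"]].groupby("gene")["cluster"].agg(list)
    for minor in sorted(truth.cell_minor.unique()):
        for g in truth.marker_genes(minor):
            assert hit.get(g) == [minor]


def test_small_cluster_is_skipped_with_warning(clustering_norm):
    labels = np.array(
        ["tiny"] * 2 + ["rest"] * (clustering_norm.n_obs - 2), dtype=object
    )
    with pytest.warns(UserWarning, match="tiny"):
        degs = tk.find_cluster_degs(clustering_norm, labels)
    assert set(degs["cluster"]) == {"rest"}


def test_flag_low_quality_clusters_conjunction_rule():
    qc = pd.DataFrame(
        {
            "genes_detected": [180] * 10 + [3000] * 10 + [150] * 10,
            "mito_frac": [0.01] * 30,
        },
        index=[f"c{i}" for i in range(30)],
    )
    labels = ["junk"] * 10 + ["good"] * 10 + ["lowbutmarked"] * 10
    degs = pd.DataFrame(
        {
            "cluster": ["good", "good", "lowbutmarked"],
            "gene": ["g1", "g2", "g3"],
            "is_deg": [True, True, True],
        }
    )
    flagged = tk.flag_low_quality_clusters(labels, qc, degs)
    # junk: low complexity AND no unique DEG; lowbutmarked saved by unique DEG
    assert flagged == {"junk"}


def test_flag_high_mito_cluster():
    qc = pd.DataFrame(
        {"genes_detected": [3000] * 20, "mito_frac": [0.01] * 10 + [0.4] * 10},
        index=[f"c{i}" for i in range(20)],
    )
    labels = ["ok"] * 10 + ["dying"] * 10
    degs = pd.DataFrame(
        {"cluster": ["ok", "dying"], "gene": ["a", "b"], "is_deg": [True, True]}
    )
    assert tk.flag_low_quality_clusters(labels, qc, degs) == {"dying"}


def test_patient_contribution_counts_and_flags(clustering_cohort):
    _, adata, truth = clustering_cohort
    out = tk.patient_contribution(truth.cell_minor, adata.obs["patient"])
    assert (out["n_patients"] >= 5).all()
    assert not out["flagged"].any()
    single = tk.patient_contribution(["X"] * 4, ["p1"] * 4)
    assert single.loc[0, "n_patients"] == 1 and bool(single.loc[0, "flagged"])


def test_patient_contribution_rejects_empty():
    with pytest.raises(ValueError):
        tk.patient_contribution([], [])


def test_select_top_markers_tie_rule():
    degs = pd.DataFrame(
        {
            "cluster": ["A"] * 4,
            "gene": ["w", "x", "y", "z"],
            "log2fc": [3.0, 2.0, 2.0, 1.5],
            "padj_holm": [0.02, 0.01, 0.001, 0.04],
            "is_deg": [True] * 4,
        }
    )
    top = tk.select_top_markers(degs, k=3)
    # fold change first; between the 2.0 ties the smaller Holm p wins
    assert top["A"] == ["w", "y", "x"]
    assert tk.select_top_markers(degs, k=0)["A"] == []


def test_top_markers_are_planted_markers(clustering_norm, clustering_cohort):
    _, _, truth = clustering_cohort
    degs = tk.find_cluster_degs(clustering_norm, truth.cell_minor)
    top = tk.select_top_markers(degs, k=3)
    for minor, genes in top.items():
        planted = set(truth.marker_genes(minor)) | {
            g
            for g in truth.gene_modules.index[
                truth.gene_modules == f"major_marker:{minor.split('.')[0]}"
            ]
        }
        assert set(genes) <= planted


def test_merge_clusters_by_markers_recovers_majors(
    clustering_norm, clustering_cohort
):
    _, _, truth = clustering_cohort
    merged = cl.merge_clusters_by_markers(
        clustering_norm, truth.cell_minor, truth.major_marker_map()
    )
    assert (merged == truth.cell_major).all()
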