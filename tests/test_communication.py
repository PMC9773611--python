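"""Affinity formulas, affinity kNN, connectivity, centrality, contributions."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import tmekit as tk
from tmekit import communication as cm

from conftest import make_adata


def random_expression(n_cells=50, n_pairs=30, n_extra=20, seed=0):
    """Normalized-expression fixture with a pair table over its genes."""
    rng = np.random.default_rng(seed)
    n_genes = 2 * n_pairs + n_extra
    X = rng.uniform(0, 3, size=(n_cells, n_genes))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    adata = make_adata(np.zeros_like(X), gene_names=genes)
    adata.X = X
    pairs = pd.DataFrame(
        {
            "ligand": [genes[2 * i] for i in range(n_pairs)],
            "receptor": [genes[2 * i + 1] for i in range(n_pairs)],
        }
    )
    return adata, pairs


def brute_force_affinity(X, li, ri):
    n = X.shape[0]
    A = np.zeros((n, n))
    for c1 in range(n):
        for c2 in range(n):
            if c1 == c2:
                continue
            for l, r in zip(li, ri):
                A[c1, c2] += X[c1, l] * X[c2, r] + X[c1, r] * X[c2, l]
    return A


# ---------------------------------------------------------------------------
# affinity
# ---------------------------------------------------------------------------

def test_pair_affinity_is_a_product():
    assert cm.pair_affinity(2.0, 3.0) == 6.0
    assert cm.pair_affinity(0.0, 5.0) == 0.0


def test_total_affinity_two_cell_hand_sum():
    adata = make_adata(np.zeros((2, 2)), gene_names=["L", "R"])
    adata.X = np.array([[1.0, 0.0], [0.0, 1.0]])
    pairs = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
    A = tk.total_affinity(adata, pairs).matrix()
    assert A[0, 1] == pytest.approx(1.0)  # E[c1,L]*E[c2,R] + E[c1,R]*E[c2,L]
    assert A[1, 0] == pytest.approx(1.0)
    assert A[0, 0] == 0.0 and A[1, 1] == 0.0


def test_duplicate_pair_doubles_affinity_without_dedup():
    adata, pairs = random_expression(n_cells=10, n_pairs=5)
    dup = pd.concat([pairs, pairs.iloc[[0]]], ignore_index=True)
    base = tk.total_affinity(adata, pairs, dedup=False)
    plus = tk.total_affinity(adata, dup, dedup=False)
    X = np.asarray(adata.X)
    li0 = list(adata.var_names).index(pairs.loc[0, "ligand"])
    ri0 = list(adata.var_names).index(pairs.loc[0, "receptor"])
    extra = brute_force_affinity(X, [li0], [ri0])
    np.testing.assert_allclose(plus.matrix(), base.matrix() + extra, atol=1e-10)
    # dedup on by default: duplicate is dropped
    np.testing.assert_allclose(
        tk.total_affinity(adata, dup).matrix(), base.matrix(), atol=1e-12
    )


def test_total_affinity_equals_brute_force():
    adata, pairs = random_expression(n_cells=50, n_pairs=30, seed=1)
    model = tk.total_affinity(adata, pairs)
    X = np.asarray(adata.X)
    names = list(adata.var_names)
    li = [names.index(g) for g in pairs["ligand"]]
    ri = [names.index(g) for g in pairs["receptor"]]
    np.testing.assert_allclose(
        model.matrix(), brute_force_affinity(X, li, ri), atol=1e-8
    )


def test_total_affinity_invariant_to_cell_and_gene_order():
    adata, pairs = random_expression(n_cells=20, n_pairs=8, seed=2)
    A = tk.total_affinity(adata, pairs).matrix()
    rng = np.random.default_rng(3)
    cperm = rng.permutation(adata.n_obs)
    gperm = rng.permutation(adata.n_vars)
    shuffled = adata[cperm, gperm].copy()
    A2 = tk.total_affinity(shuffled, pairs).matrix()
    np.testing.assert_allclose(A2, A[np.ix_(cperm, cperm)], atol=1e-10)


def test_scaling_expression_scales_affinity_quadratically():
    adata, pairs = random_expression(n_cells=15, n_pairs=6, seed=4)
    model = tk.total_affinity(adata, pairs)
    scaled = adata.copy()
    scaled.X = np.asarray(adata.X) * 3.0
    model3 = tk.total_affinity(scaled, pairs)
    np.testing.assert_allclose(model3.matrix(), 9.0 * model.matrix(), atol=1e-8)
    labels = np.array(["A"] * 7 + ["B"] * 8)
    c1 = tk.lr_contribution(model, labels, "A", "B")
    c2 = tk.lr_contribution(model3, labels, "A", "B")
    np.testing.assert_allclose(
        c1["contribution"], c2["contribution"], atol=1e-12
    )


def test_total_affinity_rejects_disjoint_pair_table():
    adata, _ = random_expression(n_cells=5, n_pairs=2)
    bad = pd.DataFrame({"ligand": ["nope"], "receptor": ["nada"]})
    with pytest.raises(ValueError, match="intersection"):
        tk.total_affinity(adata, bad)


def test_dense_cap_guard():
    adata, pairs = random_expression(n_cells=30, n_pairs=3)
    model = tk.total_affinity(adata, pairs, dense_cell_cap=10)
    with pytest.raises(MemoryError):
        model.matrix()
    # neighbor search still works block-wise above the cap
    adj = tk.affinity_knn(model, k=4, block_size=7)
    assert adj.shape == (30, 30)


# ---------------------------------------------------------------------------
# affinity kNN
# ---------------------------------------------------------------------------

def model_from_matrix(A):
    """Wrap a precomputed symmetric affinity matrix for neighbor search."""
    n = A.shape[0]
    m = cm.AffinityModel(
        ligand_expr=np.zeros((n, 1)),
        receptor_expr=np.zeros((n, 1)),
        pairs=pd.DataFrame({"ligand": ["x"], "receptor": ["y"]}),
        cell_names=[str(i) for i in range(n)],
    )

    def row_block(start, stop):
        block = A[start:stop].astype(float).copy()
        for i in range(start, stop):
            block[i - start, i] = -np.inf
        return block

    m._row_block = row_block
    return m


def test_affinity_knn_hand_enumeration():
    A = np.zeros((3, 3))
    A[0, 1] = A[1, 0] = 5
    A[0, 2] = A[2, 0] = 1
    A[1, 2] = A[2, 1] = 2
    adj = tk.affinity_knn(model_from_matrix(A), k=1)
    edges = {frozenset((i, j)) for i, j in zip(*adj.nonzero())}
    assert edges == {frozenset((0, 1)), frozenset((1, 2))}


def test_affinity_knn_tie_rule_is_deterministic():
    A = np.ones((6, 6))
    np.fill_diagonal(A, 0)
    adj = tk.affinity_knn(model_from_matrix(A), k=2)
    # all affinities equal: each cell picks the 2 lowest-index others
    for i in range(6):
        picked = sorted(adj[i].nonzero()[1])
        expected_out = [j for j in range(6) if j != i][:2]
        assert set(expected_out) <= set(picked)
    a1 = tk.affinity_knn(model_from_matrix(A), k=2)
    assert (adj != a1).nnz == 0


def test_affinity_knn_complete_graph_when_k_large():
    A = np.random.default_rng(5).uniform(size=(5, 5))
    A = A + A.T
    with pytest.warns(UserWarning, match="complete"):
        adj = tk.affinity_knn(model_from_matrix(A), k=10)
    assert adj.nnz == 5 * 4
    adj2 = tk.affinity_knn(model_from_matrix(A), k=4)
    assert adj2.nnz == 5 * 4


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def test_connectivity_zero_without_inter_edges():
    A = np.zeros((8, 8))
    A[:4, :4] = 1
    A[4:, 4:] = 1
    np.fill_diagonal(A, 0)
    comm = tk.cluster_connectivity(sp.csr_matrix(A), ["a"] * 4 + ["b"] * 4)
    assert comm.connectivity.loc["a", "b"] == 0.0
    assert not comm.significant.loc["a", "b"]


def test_connectivity_matches_direct_counting_oracle():
    rng = np.random.default_rng(6)
    n = 60
    A = (rng.uniform(size=(n, n)) < 0.1).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    labels = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
    comm = tk.cluster_connectivity(sp.csr_matrix(A), labels)
    total_edges = int(A.sum() // 2)
    for x, y, nx_, ny_ in (("a", "b", 20, 20), ("a", "c", 20, 20), ("b", "c", 20, 20)):
        observed = int(A[labels == x][:, labels == y].sum())
        expected = total_edges * nx_ * ny_ / (n * (n - 1) / 2)
        assert comm.connectivity.loc[x, y] == pytest.approx(observed / expected)


# ---------------------------------------------------------------------------
# closeness centrality
# ---------------------------------------------------------------------------

def comm_from_weights(weights, cutoff=0.05):
    clusters = sorted({c for e in weights for c in e})
    df = pd.DataFrame(0.0, index=clusters, columns=clusters)
    for (a, b), w in weights.items():
        df.loc[a, b] = df.loc[b, a] = w
    return cm.ClusterCommunicationGraph(connectivity=df, cutoff=cutoff)


def test_path_center_has_highest_closeness():
    comm = comm_from_weights({("A", "B"): 1.0, ("B", "C"): 1.0})
    cent = tk.closeness_centrality(comm)
    assert cent.index[0] == "B"


def test_closeness_matches_floyd_warshall_oracle():
    rng = np.random.default_rng(7)
    names = list("ABCDE")
    weights = {}
    for i in range(5):
        for j in range(i + 1, 5):
            if rng.uniform() < 0.7:
                weights[(names[i], names[j])] = rng.uniform(0.1, 2.0)
    comm = comm_from_weights(weights)
    cent = tk.closeness_centrality(comm)
    # Floyd-Warshall on lengths 1/connectivity
    INF = np.inf
    D = np.full((5, 5), INF)
    np.fill_diagonal(D, 0.0)
    for (a, b), w in weights.items():
        i, j = names.index(a), names.index(b)
        D[i, j] = D[j, i] = 1.0 / w
    for k in range(5):
        for i in range(5):
            for j in range(5):
                D[i, j] = min(D[i, j], D[i, k] + D[k, j])
    for i, name in enumerate(names):
        reach = [d for j, d in enumerate(D[i]) if j != i and d < INF]
        expected = len(reach) / sum(reach) if reach else 0.0
        assert cent[name] == pytest.approx(expected)


def test_isolated_cluster_has_zero_closeness():
    comm = comm_from_weights({("A", "B"): 1.0, ("C", "C"): 0.0})
    cent = tk.closeness_centrality(comm)
    assert cent["C"] == 0.0


# ---------------------------------------------------------------------------
# contributions
# ---------------------------------------------------------------------------

def test_single_pair_contribution_is_one():
    adata = make_adata(np.zeros((4, 2)), gene_names=["L", "R"])
    adata.X = np.array([[1.0, 0.2], [2.0, 0.1], [0.5, 1.0], [0.1, 2.0]])
    pairs = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
    model = tk.total_affinity(adata, pairs)
    out = tk.lr_contribution(model, ["M", "M", "N", "N"], "M", "N")
    assert out["contribution"].iloc[0] == pytest.approx(1.0)


def test_two_pair_contribution_arithmetic():
    # mean affinities 6 and 4 -> contributions 0.6 and 0.4
    adata = make_adata(np.zeros((2, 4)), gene_names=["L1", "R1", "L2", "R2"])
    adata.X = np.array([[3.0, 0.0, 2.0, 0.0], [0.0, 2.0, 0.0, 2.0]])
    pairs = pd.DataFrame({"ligand": ["L1", "L2"], "receptor": ["R1", "R2"]})
    model = tk.total_affinity(adata, pairs)
    out = tk.lr_contribution(model, ["M", "N"], "M", "N")
    np.testing.assert_allclose(out["contribution"], [0.6, 0.4])


def test_contribution_matches_brute_force_and_sums_to_one():
    adata, pairs = random_expression(n_cells=40, n_pairs=30, seed=8)
    labels = np.array(["M"] * 15 + ["N"] * 25)
    model = tk.total_affinity(adata, pairs)
    out = tk.lr_contribution(model, labels, "M", "N")
    X = np.asarray(adata.X)
    names = list(adata.var_names)
    for _, row in out.iterrows():
        li, ri = names.index(row["ligand"]), names.index(row["receptor"])
        s = 0.0
        for c1 in np.flatnonzero(labels == "M"):
            for c2 in np.flatnonzero(labels == "N"):
                s += X[c1, li] * X[c2, ri]
        s /= 15 * 25
        assert row["affinity"] == pytest.approx(s, abs=1e-10)
    assert out["contribution"].sum() == pytest.approx(1.0, abs=1e-9)


def test_contribution_directionality():
    adata, pairs = random_expression(n_cells=20, n_pairs=5, seed=9)
    labels = np.array(["M"] * 10 + ["N"] * 10)
    model = tk.total_affinity(adata, pairs)
    mn = tk.lr_contribution(model, labels, "M", "N")
    nm = tk.lr_contribution(model, labels, "N", "M")
    assert not np.allclose(mn["affinity"], nm["affinity"])
    # summed over both directions the pair affinity is symmetric
    np.testing.assert_allclose(
        (mn["affinity"] + nm["affinity"]).to_numpy(),
        (nm["affinity"] + mn["affinity"]).to_numpy(),
    )


def test_zero_total_affinity_warns_and_returns_empty():
    adata = make_adata(np.zeros((4, 2)), gene_names=["L", "R"])
    pairs = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
    model = tk.total_affinity(adata, pairs)
    with pytest.warns(UserWarning, match="zero"):
        out = tk.lr_contribution(model, ["M", "M", "N", "N"], "M", "N")
    assert out.empty


# ---------------------------------------------------------------------------
# planted hub cohort end to end
# ---------------------------------------------------------------------------

def test_planted_hub_is_recovered(hub_norm, hub_cohort):
    _, _, truth = hub_cohort
    model = tk.total_affinity(hub_norm, truth.lr_table)
    adj = tk.affinity_knn(model, k=15)
    comm = tk.cluster_connectivity(adj, truth.cell_minor.to_numpy(), cutoff=0.05)
    cent = tk.closeness_centrality(comm)
    assert cent.index[0] == truth.hub_cluster
    planted = [
        (r.sender, r.receiver)
        for r in truth.axes.itertuples()
        if r.sender != r.receiver
    ]
    planted_vals = [comm.connectivity.loc[s, r] for s, r in planted]
    assert min(planted_vals) > 0.05
    pset = set(map(frozenset, planted))
    clusters = list(comm.connectivity.index)
    decoys = [
        comm.connectivity.loc[a, b]
        for i, a in enumerate(clusters)
        for b in clusters[i + 1 :]
        if frozenset((a, b)) not in pset
    ]
    # decoy cluster pairs stay clearly below every planted axis
    assert max(decoys) < min(planted_vals)
    # decoy LR pairs (planted at background everywhere) contribute < 1%
    sender, receiver = planted[0]
    contrib = tk.lr_contribution(model, truth.cell_minor.to_numpy(), sender, receiver)
    decoy_rows = contrib[contrib["ligand"].str.startswith("LIGD")]
    assert (decoy_rows["contribution"] < 0.01).all()


def test_packaged_lr_table_loads():
    pairs = tk.load_lr_pairs()
    assert {"ligand", "receptor"} <= set(pairs.columns)
    assert len(pairs) > 100
    assert not pairs.duplicated(["ligand", "receptor"]).any()
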