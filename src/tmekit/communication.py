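"""Ligand-receptor cell-cell communication networks and hub ranking.

The affinity between two cells is the sum, over a ligand-receptor pair
database, of the product of ligand expression in one cell and receptor
expression in the other, taken in both directions:

    A(C1, C2) = sum_i E[C1, L_i] * E[C2, R_i]  +  sum_i E[C1, R_i] * E[C2, L_i]

Computed as two low-rank products over the ligand- and receptor-expression
blocks, so the full cell x cell matrix is only materialized below a
configurable cell count.  A neighbor graph links each cell to its k cells of
*highest* affinity; cluster-pair communication strength is the graph-
abstraction connectivity statistic (observed inter-cluster edge count over
its expectation under random edge placement given cluster sizes), thresholded
at a significance cutoff.  Hubs are ranked by closeness centrality on the
significant-edge subgraph with edge length 1/connectivity.  For a cluster
pair (M, N), each pair's mean directional affinity (ligand on the M side)
is normalized into a contribution summing to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "load_lr_pairs",
    "intersect_pairs",
    "pair_affinity",
    "AffinityModel",
    "total_affinity",
    "affinity_knn",
    "cluster_connectivity",
    "closeness_centrality",
    "lr_contribution",
]

#: above this cell count the dense cell x cell affinity matrix is refused
DEFAULT_DENSE_CELL_CAP = 5000


def load_lr_pairs(path=None) -> pd.DataFrame:
    """Load a ligand-receptor pair table (columns ligand, receptor[, annotation]).

    Without a path, returns the packaged curated human pair list.
    """
    if path is None:
        with resources.files("tmekit.data").joinpath("lr_pairs.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("pair table needs 'ligand' and 'receptor' columns")
    return df


def intersect_pairs(
    pairs: pd.DataFrame, gene_names, dedup: bool = True
) -> pd.DataFrame:
    """Restrict the pair table to pairs whose genes are both in the matrix."""
    genes = set(map(str, gene_names))
    out = pairs[pairs["ligand"].isin(genes) & pairs["receptor"].isin(genes)]
    if dedup:
        out = out.drop_duplicates(subset=["ligand", "receptor"])
    out = out.reset_index(drop=True)
    if out.empty:
        raise ValueError("no ligand-receptor pair survives gene intersection")
    return out


def pair_affinity(e1_ligand: float, e2_receptor: float) -> float:
    """Affinity contributed by one pair between two cells: E[C1,L] * E[C2,R]."""
    return float(e1_ligand) * float(e2_receptor)


@dataclass
class AffinityModel:
    """Low-rank factors of the cell x cell affinity matrix.

    ``ligand_expr`` and ``receptor_expr`` are cells x pairs blocks of the
    normalized expression of each pair's ligand and receptor; the full matrix
    is ``L R^T + R L^T`` and is only materialized up to ``dense_cell_cap``.
    """

    ligand_expr: np.ndarray
    receptor_expr: np.ndarray
    pairs: pd.DataFrame
    cell_names: list[str]
    dense_cell_cap: int = DEFAULT_DENSE_CELL_CAP

    @property
    def n_cells(self) -> int:
        return self.ligand_expr.shape[0]

    def matrix(self) -> np.ndarray:
        """Dense affinity matrix with zeroed diagonal (self-affinity excluded)."""
        if self.n_cells > self.dense_cell_cap:
            raise MemoryError(
                f"{self.n_cells} cells exceed the dense cap {self.dense_cell_cap};"
                " use affinity_knn which works block-wise"
            )
        A = self.ligand_expr @ self.receptor_expr.T
        A = A + A.T
        np.fill_diagonal(A, 0.0)
        return A

    def _row_block(self, start: int, stop: int) -> np.ndarray:
        block = (
            self.ligand_expr[start:stop] @ self.receptor_expr.T
            + self.receptor_expr[start:stop] @ self.ligand_expr.T
        )
        for i in range(start, stop):
            block[i - start, i] = -np.inf  # self excluded from neighbor search
        return block


def total_affinity(
    norm: ad.AnnData,
    pairs: pd.DataFrame,
    dedup: bool = True,
    dense_cell_cap: int = DEFAULT_DENSE_CELL_CAP,
) -> AffinityModel:
    """Build the affinity model from a normalized matrix and a pair table."""
    pairs = intersect_pairs(pairs, norm.var_names, dedup=dedup)
    X = norm.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    col = {g: i for i, g in enumerate(norm.var_names)}
    li = [col[g] for g in pairs["ligand"]]
    ri = [col[g] for g in pairs["receptor"]]
    return AffinityModel(
        ligand_expr=np.ascontiguousarray(X[:, li], dtype=np.float64),
        receptor_expr=np.ascontiguousarray(X[:, ri], dtype=np.float64),
        pairs=pairs,
        cell_names=list(map(str, norm.obs_names)),
        dense_cell_cap=dense_cell_cap,
    )


def affinity_knn(
    model: AffinityModel, k: int = 15, block_size: int = 2048
) -> sp.csr_matrix:
    """Graph linking each cell to its k highest-affinity partners.

    Ties are broken by cell index (lower first); the directed edge set is
    union-symmetrized; self-links are excluded.  Works block-wise over the
    low-rank factors, never materializing the full matrix.
    """
    n = model.n_cells
    if k >= n:
        warnings.warn(f"k={k} >= {n} cells; returning the complete graph", stacklevel=2)
        adj = sp.csr_matrix(np.ones((n, n)) - np.eye(n))
        return adj
    rows = []
    cols = []
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = model._row_block(start, stop)
        # stable argsort on descending affinity -> lowest index wins ties
        order = np.argsort(-block, axis=1, kind="stable")[:, :k]
        rows.append(np.repeat(np.arange(start, stop), k))
        cols.append(order.ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = sp.coo_matrix((np.ones(len(r)), (r, c)), shape=(n, n)).tocsr()
    adj = adj.maximum(adj.T)
    adj.data[:] = 1.0
    return adj


@dataclass
class ClusterCommunicationGraph:
    """Cluster-pair connectivity weights with a significance mask."""

    connectivity: pd.DataFrame  # clusters x clusters, symmetric
    cutoff: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.connectivity > self.cutoff

    def significant_edges(self) -> list[tuple[str, str, float]]:
        out = []
        cl = list(self.connectivity.index)
        for i, a in enumerate(cl):
            for b in cl[i + 1 :]:
                w = self.connectivity.loc[a, b]
                if w > self.cutoff:
                    out.append((a, b, float(w)))
        return out


def cluster_connectivity(
    adj: sp.spmatrix, labels, cutoff: float = 0.05
) -> ClusterCommunicationGraph:
    """Graph-abstraction connectivity: observed / expected inter-cluster edges.

    For clusters M, N with sizes m, n in a graph of ``n_cells`` nodes and
    ``E`` undirected edges, the expected inter-cluster edge count under random
    edge placement is ``E * m * n / C(n_cells, 2)``; connectivity is the
    observed count divided by that expectation.
    """
    labels = np.asarray(labels)
    adj = sp.csr_matrix(adj)
    clusters = sorted(pd.unique(labels))
    sizes = {cl: int((labels == cl).sum()) for cl in clusters}
    if any(v == 0 for v in sizes.values()):
        raise ValueError("empty cluster")
    n_cells = adj.shape[0]
    coo = sp.triu(adj, k=1).tocoo()
    total_edges = coo.nnz
    idx = {cl: i for i, cl in enumerate(clusters)}
    counts = np.zeros((len(clusters), len(clusters)))
    la = labels[coo.row]
    lb = labels[coo.col]
    for a, b in zip(la, lb):
        i, j = idx[a], idx[b]
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    n_possible = n_cells * (n_cells - 1) / 2.0
    conn = np.zeros_like(counts)
    for a in clusters:
        for b in clusters:
            if a == b:
                continue
            expected = total_edges * sizes[a] * sizes[b] / n_possible
            conn[idx[a], idx[b]] = counts[idx[a], idx[b]] / expected if expected else 0.0
    df = pd.DataFrame(conn, index=clusters, columns=clusters)
    return ClusterCommunicationGraph(connectivity=df, cutoff=cutoff)


def closeness_centrality(comm: ClusterCommunicationGraph) -> pd.Series:
    """Closeness ranking on the significant subgraph, edge length 1/connectivity.

    Closeness of a cluster is (n_reachable - 1) / (sum of shortest-path
    lengths to reachable clusters), computed within its connected component;
    isolated clusters get 0.  Returned sorted descending, ties by cluster id.
    """
    clusters = list(comm.connectivity.index)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    g = nx.Graph()
    g.add_nodes_from(clusters)
    for a, b, w in comm.significant_edges():
        g.add_edge(a, b, length=1.0 / w)
    cc = nx.closeness_centrality(g, distance="length", wf_improved=False)
    ser = pd.Series(cc, name="closeness")
    order = sorted(ser.index, key=lambda cl: (-ser[cl], cl))
    return ser.loc[order]


def lr_contribution(
    model: AffinityModel,
    labels,
    cluster_m: str,
    cluster_n: str,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-pair mean affinity and contribution between two clusters.

    Direction-specific: the ligand is read on ``cluster_m`` cells and the
    receptor on ``cluster_n`` cells.  The mean affinity of pair i is
    mean_M(E_L) * mean_N(E_R); contributions normalize these to sum to 1.
    Rows with contribution above ``threshold`` are flagged ``plot``.
    """
    labels = np.asarray(labels)
    mask_m = labels == cluster_m
    mask_n = labels == cluster_n
    if mask_m.sum() == 0 or mask_n.sum() == 0:
        raise ValueError("both clusters must contain cells")
    mean_l = model.ligand_expr[mask_m].mean(axis=0)
    mean_r = model.receptor_expr[mask_n].mean(axis=0)
    affinity = mean_l * mean_r
    total = affinity.sum()
    out = model.pairs.copy()
    out["cluster_m"] = cluster_m
    out["cluster_n"] = cluster_n
    out["affinity"] = affinity
    if total <= 0:
        warnings.warn(
            f"total affinity between {cluster_m} and {cluster_n} is zero; "
            "contributions undefined",
            stacklevel=2,
        )
        return out.iloc[0:0]
    out["contribution"] = affinity / total
    out["plot"] = out["contribution"] > threshold
    return out
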