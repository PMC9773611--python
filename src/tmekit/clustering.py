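"""Stepwise two-round clustering with batch-balanced neighbor graphs.

Round one clusters all cells: top variable genes -> PCA -> a batch-balanced
kNN graph (each cell is linked to its k nearest neighbors *within every
chemistry batch*, so batches cannot segregate into their own clusters) ->
Leiden community detection.  Round two repeats the same pipeline inside each
major cluster with fewer genes and components to resolve minor subtypes.

Cluster markers come from a one-vs-rest Wilcoxon rank-sum scan per gene with
Benjamini-Hochberg adjustment; a gene is a differential marker of a cluster
when its adjusted p < 0.05 and over 30% of the cluster's cells express it.
Clusters that combine a low median of detected genes with a complete lack of
unique markers are flagged as low quality.
"""

from __future__ import annotations

import warnings

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .stats import bh_adjust, holm_adjust

__all__ = [
    "select_variable_genes",
    "embed_pca",
    "build_balanced_knn",
    "leiden_cluster",
    "cluster_cells",
    "merge_clusters_by_markers",
    "subcluster",
    "two_round_cluster",
    "find_cluster_degs",
    "flag_low_quality_clusters",
    "patient_contribution",
    "select_top_markers",
]


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def select_variable_genes(norm: ad.AnnData, n: int) -> list[str]:
    """Top ``n`` genes by variance across cells; ties broken by gene identifier."""
    if n > norm.n_vars:
        raise ValueError("n exceeds the number of genes")
    var = _dense(norm.X).var(axis=0)
    names = np.asarray(norm.var_names, dtype=object)
    # descending variance, ascending name among ties
    order = np.lexsort((names, -var))
    return [str(names[i]) for i in order[:n]]


def embed_pca(
    norm: ad.AnnData, genes: list[str], n_components: int
) -> np.ndarray:
    """PCA embedding of the gene-centered matrix restricted to ``genes``.

    Components are ordered by decreasing explained variance and re-signed so
    that each component's largest-|loading| gene weight is positive,
    making the embedding deterministic.
    """
    missing = set(genes) - set(norm.var_names)
    if missing:
        raise ValueError(f"genes not in matrix: {sorted(missing)[:5]} ...")
    X = _dense(norm[:, genes].X)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix dimensions")
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(X)
    comp = pca.components_  # components x genes
    flip = np.sign(comp[np.arange(comp.shape[0]), np.argmax(np.abs(comp), axis=1)])
    flip[flip == 0] = 1.0
    return emb * flip


def build_balanced_knn(
    embedding: np.ndarray, batch_labels, k_within: int = 3
) -> sp.csr_matrix:
    """Batch-balanced kNN graph: k nearest neighbors within *each* batch.

    Every cell is connected to its ``k_within`` nearest neighbors (Euclidean,
    excluding itself) inside every batch, then the edge set is symmetrized, so
    a cell has at most ``k_within * n_batches`` outgoing links.  Batches with
    too few cells contribute all their members, with a warning.
    """
    if k_within < 1:
        raise ValueError("k_within must be >= 1")
    batches = np.asarray(batch_labels)
    n = embedding.shape[0]
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for b in np.unique(batches):
        idx = np.flatnonzero(batches == b)
        k = k_within
        if len(idx) < k_within + 1:
            warnings.warn(
                f"batch {b!r} has only {len(idx)} cells; connecting to all",
                stacklevel=2,
            )
            k = max(len(idx) - 1, 0)
        nn = NearestNeighbors(n_neighbors=min(k + 1, len(idx))).fit(embedding[idx])
        _, nbrs = nn.kneighbors(embedding)  # all cells vs this batch
        for j in range(n):
            cand = idx[nbrs[j]]
            cand = cand[cand != j][:k]
            rows.append(np.full(len(cand), j))
            cols.append(cand)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = sp.coo_matrix((np.ones(len(r)), (r, c)), shape=(n, n)).tocsr()
    adj = adj.maximum(adj.T)
    adj.data[:] = 1.0
    return adj


def leiden_cluster(
    adj: sp.spmatrix, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden partition of an undirected cell graph; deterministic under seed."""
    adj = sp.csr_matrix(adj)
    if adj.shape[0] == 0:
        raise ValueError("empty graph")
    coo = sp.triu(adj, k=1).tocoo()
    g = igraph.Graph(
        n=adj.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist()))
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership)


def cluster_cells(
    norm: ad.AnnData,
    n_top_genes: int = 1000,
    n_pcs: int = 100,
    k_within: int = 3,
    resolution: float = 1.0,
    seed: int = 0,
    batch_key: str = "batch",
) -> pd.Series:
    """Round-one clustering: variable genes -> PCA -> balanced kNN -> Leiden."""
    genes = select_variable_genes(norm, min(n_top_genes, norm.n_vars))
    n_pcs = min(n_pcs, len(genes), norm.n_obs - 1)
    emb = embed_pca(norm, genes, n_pcs)
    adj = build_balanced_knn(emb, norm.obs[batch_key].to_numpy(), k_within)
    labels = leiden_cluster(adj, resolution=resolution, seed=seed)
    return pd.Series(
        [f"C{l:02d}" for l in labels], index=norm.obs_names, name="major"
    )


def merge_clusters_by_markers(
    norm: ad.AnnData, labels: pd.Series, marker_map: dict[str, list[str]]
) -> pd.Series:
    """Merge fine clusters into named major populations by canonical markers.

    ``marker_map`` maps a major-population name to its canonical marker genes
    (the curation the study would keep in a YAML file).  Each cluster is
    assigned the name whose marker set has the highest mean normalized
    expression in the cluster; clusters sharing a name are merged.
    """
    if not marker_map:
        raise ValueError("marker_map is empty")
    X = _dense(norm.X)
    col = {g: i for i, g in enumerate(norm.var_names)}
    names = sorted(marker_map)
    sets = []
    for name in names:
        idx = [col[g] for g in marker_map[name] if g in col]
        if not idx:
            raise ValueError(f"no canonical marker of {name!r} is in the matrix")
        sets.append(idx)
    out = pd.Series(index=labels.index, dtype=object, name="major")
    for cl in labels.unique():
        mask = (labels == cl).to_numpy()
        scores = [X[mask][:, idx].mean() for idx in sets]
        out.loc[mask] = names[int(np.argmax(scores))]
    return out


def subcluster(
    norm: ad.AnnData,
    major_labels: pd.Series,
    major_id: str,
    n_genes: int = 600,
    n_pcs: int = 25,
    k_within: int = 3,
    resolution: float = 1.0,
    seed: int = 0,
    min_size: int = 100,
    batch_key: str = "batch",
) -> pd.Series | None:
    """Round-two clustering inside one major cluster; minor ids namespaced.

    Returns a Series over the major cluster's cells with labels like
    ``"C00.1"``, or None (with a warning) when the subset is too small.
    """
    mask = (major_labels == major_id).to_numpy()
    if mask.sum() < min_size:
        warnings.warn(
            f"major cluster {major_id} has {mask.sum()} cells < {min_size}; skipped",
            stacklevel=2,
        )
        return None
    sub = norm[mask].copy()
    genes = select_variable_genes(sub, min(n_genes, sub.n_vars))
    n_pcs = min(n_pcs, len(genes), sub.n_obs - 1)
    emb = embed_pca(sub, genes, n_pcs)
    adj = build_balanced_knn(emb, sub.obs[batch_key].to_numpy(), k_within)
    labels = leiden_cluster(adj, resolution=resolution, seed=seed)
    return pd.Series(
        [f"{major_id}.{l}" for l in labels], index=sub.obs_names, name="minor"
    )


def two_round_cluster(
    norm: ad.AnnData,
    n_top_genes: int = 1000,
    n_pcs: int = 100,
    sub_n_genes: int = 600,
    sub_n_pcs: int = 25,
    k_within: int = 3,
    resolution: float = 1.0,
    sub_resolution: float = 1.0,
    seed: int = 0,
    min_subcluster_size: int = 100,
    batch_key: str = "batch",
    marker_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Full stepwise clustering; returns per-cell ``major`` and ``minor`` labels.

    When ``marker_map`` is given, first-round clusters are merged into named
    major populations by canonical-marker expression before subclustering
    (the config-driven analog of curated cluster merging).  Majors too small
    to subcluster keep ``minor == major + ".0"``.
    """
    major = cluster_cells(
        norm,
        n_top_genes=n_top_genes,
        n_pcs=n_pcs,
        k_within=k_within,
        resolution=resolution,
        seed=seed,
        batch_key=batch_key,
    )
    if marker_map is not None:
        major = merge_clusters_by_markers(norm, major, marker_map)
    minor = pd.Series(index=norm.obs_names, dtype=object, name="minor")
    for m in sorted(major.unique()):
        sub = subcluster(
            norm,
            major,
            m,
            n_genes=sub_n_genes,
            n_pcs=sub_n_pcs,
            k_within=k_within,
            resolution=sub_resolution,
            seed=seed,
            min_size=min_subcluster_size,
            batch_key=batch_key,
        )
        if sub is None:
            minor.loc[major == m] = f"{m}.0"
        else:
            minor.loc[sub.index] = sub
    return pd.DataFrame({"major": major, "minor": minor})


def find_cluster_degs(
    norm: ad.AnnData,
    labels,
    min_frac: float = 0.30,
    alpha: float = 0.05,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum differential expression per cluster.

    P-values use the tie-corrected normal approximation, BH-adjusted within
    each cluster's gene family (Holm-adjusted values are carried alongside for
    marker ranking).  Fold change is computed on expm1 of the normalized group
    means with a 1e-9 pseudocount.  A gene is flagged ``is_deg`` when
    BH-adjusted p < ``alpha`` and the in-cluster expressed fraction exceeds
    ``min_frac``.
    """
    labels = pd.Series(np.asarray(labels), index=norm.obs_names)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("differential expression needs at least two clusters")
    X = _dense(norm.X)
    genes = np.asarray(norm.var_names, dtype=object)
    frames = []
    for cl in clusters:
        mask = (labels == cl).to_numpy()
        n_in = int(mask.sum())
        if n_in < min_cluster_size:
            warnings.warn(f"cluster {cl} has {n_in} cells < {min_cluster_size}; skipped",
                          stacklevel=2)
            continue
        xin, xout = X[mask], X[~mask]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.mannwhitneyu(
                xin, xout, axis=0, alternative="two-sided", method="asymptotic"
            )
        pvals = np.nan_to_num(res.pvalue, nan=1.0)
        mean_in = np.expm1(xin.mean(axis=0)) + 1e-9
        mean_out = np.expm1(xout.mean(axis=0)) + 1e-9
        log2fc = np.log2(mean_in / mean_out)
        frac_in = (xin > 0).mean(axis=0)
        frac_out = (xout > 0).mean(axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "cluster": cl,
                    "gene": genes,
                    "log2fc": log2fc,
                    "pval": pvals,
                    "padj_bh": bh_adjust(pvals),
                    "padj_holm": holm_adjust(pvals),
                    "frac_in": frac_in,
                    "frac_out": frac_out,
                }
            )
        )
    degs = pd.concat(frames, ignore_index=True)
    degs["is_deg"] = (degs["padj_bh"] < alpha) & (degs["frac_in"] > min_frac) & (
        degs["log2fc"] > 0
    )
    return degs


def unique_deg_counts(degs: pd.DataFrame) -> pd.Series:
    """Number of DEGs unique to each cluster (DEG of that cluster only)."""
    hits = degs[degs["is_deg"]]
    per_gene = hits.groupby("gene")["cluster"].nunique()
    unique_genes = set(per_gene.index[per_gene == 1])
    uniq = hits[hits["gene"].isin(unique_genes)].groupby("cluster").size()
    return uniq.reindex(sorted(degs["cluster"].unique()), fill_value=0)


def flag_low_quality_clusters(
    labels,
    qc_metrics: pd.DataFrame,
    degs: pd.DataFrame,
    median_genes_max: float = 250,
    max_mito: float = 0.10,
) -> set[str]:
    """Flag clusters with low library complexity and no unique markers.

    A cluster is flagged when its median detected-gene count is at or below
    ``median_genes_max`` AND it has zero unique DEGs; clusters whose median
    mitochondrial fraction exceeds ``max_mito`` are flagged regardless.
    """
    labels = pd.Series(np.asarray(labels), index=qc_metrics.index)
    uniq = unique_deg_counts(degs)
    flagged: set[str] = set()
    for cl, grp in qc_metrics.groupby(labels):
        med_genes = grp["genes_detected"].median()
        med_mito = grp["mito_frac"].median()
        if med_genes <= median_genes_max and uniq.get(cl, 0) == 0:
            flagged.add(cl)
        if med_mito > max_mito:
            flagged.add(cl)
    return flagged


def patient_contribution(labels, patients, floor: int = 5) -> pd.DataFrame:
    """Distinct contributing patients per cluster; flags clusters below ``floor``."""
    labels = np.asarray(labels)
    patients = np.asarray(patients)
    if labels.size == 0:
        raise ValueError("no cells provided")
    df = pd.DataFrame({"cluster": labels, "patient": patients})
    counts = df.groupby("cluster")["patient"].nunique().rename("n_patients")
    out = counts.reset_index()
    out["flagged"] = out["n_patients"] < floor
    return out


def select_top_markers(degs: pd.DataFrame, k: int = 3) -> dict[str, list[str]]:
    """Top-k marker genes per cluster by fold change, then Holm p, then gene id."""
    out: dict[str, list[str]] = {}
    for cl, grp in degs[degs["is_deg"]].groupby("cluster"):
        ranked = grp.sort_values(
            ["log2fc", "padj_holm", "gene"], ascending=[False, True, True]
        )
        if len(ranked) < k:
            warnings.warn(
                f"cluster {cl} has only {len(ranked)} DEGs (< {k})", stacklevel=2
            )
        out[str(cl)] = ranked["gene"].head(k).tolist()
    return out
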