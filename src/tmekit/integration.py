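"""Assign bulk-derived deregulated genes to cell populations by bi-clustering.

Bulk RNA-seq differential expression flattens the mixture of cell types; to
recover which population carries each deregulated gene, genes are profiled by
their mean normalized expression per single-cell cluster, z-scored per gene
across clusters ("scaled average expression"), and hierarchically clustered
(1 - Pearson correlation distance, average linkage).  Up- and downregulated
genes are clustered in separate runs.  Robustness to cell-composition change
is quantified by repeatedly removing a fraction of a target cell type,
re-clustering, matching the new gene clusters to the originals by maximal
overlap (Hungarian assignment), and recording the fraction of each original
cluster's genes that keep their co-cluster membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ClusterProfile",
    "cluster_profile",
    "GeneClusterAssignment",
    "bicluster_genes",
    "match_gene_clusters",
    "downsample_robustness",
]


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


@dataclass
class ClusterProfile:
    """Cluster-averaged expression: raw means and per-gene z-scores."""

    mean: pd.DataFrame  # genes x clusters
    z: pd.DataFrame  # genes x clusters, row mean 0 / sd 1 (constant rows -> 0)


def cluster_profile(norm: ad.AnnData, labels, genes) -> ClusterProfile:
    """Mean normalized expression per cluster, z-scaled per gene across clusters.

    Genes absent from the matrix are dropped with a warning; constant genes
    z-scale to an all-zero row.
    """
    genes = [str(g) for g in genes]
    present = [g for g in genes if g in set(norm.var_names)]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} genes absent from matrix; dropped", stacklevel=2)
    if not present:
        raise ValueError("no requested gene is present in the matrix")
    labels = pd.Series(np.asarray(labels), index=norm.obs_names)
    X = _dense(norm[:, present].X)
    clusters = sorted(labels.unique())
    means = np.vstack(
        [X[(labels == cl).to_numpy()].mean(axis=0) for cl in clusters]
    ).T  # genes x clusters
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / sd, 0.0)
    return ClusterProfile(
        mean=pd.DataFrame(means, index=present, columns=clusters),
        z=pd.DataFrame(z, index=present, columns=clusters),
    )


@dataclass
class GeneClusterAssignment:
    """Gene -> gene-cluster labels with the linkage that produced them."""

    labels: pd.Series  # gene -> int label, ordered by leaf-order first occurrence
    linkage: np.ndarray
    n_clusters: int


def bicluster_genes(profile_z: pd.DataFrame, n_gene_clusters: int) -> GeneClusterAssignment:
    """Agglomerative clustering of gene rows, cut at ``n_gene_clusters``.

    Distance is 1 - Pearson correlation between z-score rows, average linkage.
    Labels are renumbered 1..k by the position of each cluster's first gene in
    the dendrogram leaf order, so the assignment is deterministic and
    invariant to gene input order up to identical label sets.
    """
    if len(profile_z) < 2:
        raise ValueError("need at least two genes")
    if n_gene_clusters > len(profile_z):
        raise ValueError("more gene clusters requested than genes")
    X = profile_z.to_numpy(float)
    # correlation distance is undefined for constant rows; jitter-free guard:
    # treat constant rows as zero-correlation with everything (distance 1)
    link = hierarchy.linkage(X, method="average", metric=_safe_correlation)
    raw = hierarchy.fcluster(link, t=n_gene_clusters, criterion="maxclust")
    leaves = hierarchy.leaves_list(link)
    seen: dict[int, int] = {}
    for leaf in leaves:
        seen.setdefault(raw[leaf], len(seen) + 1)
    labels = pd.Series([seen[r] for r in raw], index=profile_z.index, name="gene_cluster")
    return GeneClusterAssignment(labels=labels, linkage=link, n_clusters=int(labels.nunique()))


def _safe_correlation(u: np.ndarray, v: np.ndarray) -> float:
    du = u - u.mean()
    dv = v - v.mean()
    nu = np.sqrt((du**2).sum())
    nv = np.sqrt((dv**2).sum())
    if nu == 0.0 or nv == 0.0:
        return 1.0
    return float(1.0 - (du @ dv) / (nu * nv))


def match_gene_clusters(reference: pd.Series, other: pd.Series) -> dict[int, int]:
    """Map ``other`` labels onto ``reference`` labels by maximal gene overlap.

    Hungarian assignment on the negative overlap-count matrix over the shared
    genes; unmatched labels (when counts differ) are left unmapped.
    """
    genes = reference.index.intersection(other.index)
    ref = reference.loc[genes]
    oth = other.loc[genes]
    ref_labels = sorted(ref.unique())
    oth_labels = sorted(oth.unique())
    overlap = np.zeros((len(oth_labels), len(ref_labels)))
    for i, a in enumerate(oth_labels):
        for j, b in enumerate(ref_labels):
            overlap[i, j] = ((oth == a) & (ref == b)).sum()
    rows, cols = linear_sum_assignment(-overlap)
    return {int(oth_labels[i]): int(ref_labels[j]) for i, j in zip(rows, cols)}


def downsample_robustness(
    norm: ad.AnnData,
    labels,
    genes,
    original: GeneClusterAssignment,
    target_cluster: str,
    frac: float = 0.9,
    reps: int = 100,
    seed: int = 0,
    n_gene_clusters: int | None = None,
) -> pd.DataFrame:
    """Gene-cluster preservation under repeated target-cell-type downsampling.

    Per repetition, ``frac`` of the target cluster's cells are removed at
    random, the profile and bi-clustering are recomputed, new clusters are
    matched to the originals by maximal overlap, and a gene counts as
    preserved when its new label maps to its original one.  Returns per
    original gene cluster the mean preservation fraction over repetitions.
    """
    if not 0.0 <= frac < 1.0:
        raise ValueError("frac must lie in [0, 1)")
    labels = pd.Series(np.asarray(labels), index=norm.obs_names)
    target_idx = np.flatnonzero((labels == target_cluster).to_numpy())
    if len(target_idx) == 0:
        raise ValueError(f"target cluster {target_cluster!r} has no cells")
    n_remove = int(round(frac * len(target_idx)))
    if n_remove >= len(target_idx):
        raise ValueError("downsampling would remove the whole target cluster")
    if n_gene_clusters is None:
        n_gene_clusters = original.n_clusters
    rng = np.random.Generator(np.random.PCG64(seed))
    per_rep = []
    for _ in range(reps):
        removed = rng.choice(target_idx, size=n_remove, replace=False)
        keep = np.ones(norm.n_obs, bool)
        keep[removed] = False
        prof = cluster_profile(norm[keep], labels[keep], genes)
        assign = bicluster_genes(prof.z, n_gene_clusters)
        mapping = match_gene_clusters(original.labels, assign.labels)
        mapped = assign.labels.map(mapping)
        per_rep.append((mapped == original.labels.loc[mapped.index]).rename("preserved"))
    pres = pd.concat(per_rep, axis=1).mean(axis=1)
    out = pd.DataFrame(
        {"gene_cluster": original.labels, "preservation": pres}
    )
    return (
        out.groupby("gene_cluster")["preservation"]
        .mean()
        .rename("preservation")
        .reset_index()
    )
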