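"""Cell QC, depth normalization, and ICA-based dissociation-artifact removal.

Quality control mirrors standard droplet scRNA-seq practice: cells are kept
when their detected-gene count and total UMI count fall inside inclusive
ranges (defaults 200-7500 genes, 500-75000 UMIs) and their mitochondrial
read fraction is strictly below a cap (default 10%).

Normalization scales each cell to the median post-QC depth and applies
log1p -- a depth-invariant monotone transform whose name is recorded in the
matrix provenance.

Tissue dissociation can imprint a stress (heat-shock) program on a subset of
samples.  Independent component analysis on the normalized matrix isolates
such a program as a component whose cell scores distribute sample-specifically;
the component is scored by the ratio of between-sample to pooled within-sample
variance of its cell scores, auto-selected by a robust outlier rule
(score > median + 5 MAD), and its rank-one term is subtracted from the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import FastICA

__all__ = [
    "QCThresholds",
    "ComponentDecomposition",
    "compute_qc_metrics",
    "filter_cells",
    "apply_qc",
    "normalize",
    "decompose_ica",
    "score_sample_specificity",
    "select_artifact_component",
    "remove_artifact_program",
]


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 200
    max_genes: int = 7500
    min_umi: int = 500
    max_umi: int = 75000
    max_mito_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes or self.min_umi >= self.max_umi:
            raise ValueError("QC ranges must satisfy min < max")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must lie in [0, 1]")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def compute_qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell detected genes, total UMI, and mitochondrial fraction.

    Requires a boolean ``mito`` column in ``adata.var``.  Cells with zero
    total UMI get mito fraction 0.
    """
    if "mito" not in adata.var:
        raise ValueError("adata.var must carry a boolean 'mito' flag")
    X = adata.X
    if sp.issparse(X):
        genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
        total = np.asarray(X.sum(axis=1)).ravel()
        mito = np.asarray(X[:, adata.var["mito"].to_numpy()].sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        genes_detected = (X > 0).sum(axis=1)
        total = X.sum(axis=1)
        mito = X[:, adata.var["mito"].to_numpy()].sum(axis=1)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "genes_detected": genes_detected.astype(int),
            "total_umi": total.astype(int),
            "mito_frac": mito_frac,
        },
        index=adata.obs_names,
    )


def filter_cells(metrics: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.Series:
    """Boolean keep-mask: inclusive gene/UMI ranges, strict mito cap."""
    t = thresholds or QCThresholds()
    keep = (
        (metrics["genes_detected"] >= t.min_genes)
        & (metrics["genes_detected"] <= t.max_genes)
        & (metrics["total_umi"] >= t.min_umi)
        & (metrics["total_umi"] <= t.max_umi)
        & (metrics["mito_frac"] < t.max_mito_frac)
    )
    keep.name = "keep"
    return keep


def apply_qc(adata: ad.AnnData, thresholds: QCThresholds | None = None) -> ad.AnnData:
    """Filter cells by QC thresholds; stores the metrics in ``obs``."""
    metrics = compute_qc_metrics(adata)
    keep = filter_cells(metrics, thresholds)
    out = adata[keep.to_numpy()].copy()
    out.obs = out.obs.join(metrics.loc[keep.to_numpy()])
    return out


def normalize(adata: ad.AnnData, target_sum: float | None = None) -> ad.AnnData:
    """Median-depth scaling followed by log1p.

    Each cell's counts are scaled to ``target_sum`` (default: the median total
    UMI across cells) and log1p-transformed.  Returns a new AnnData with dense
    float values and a provenance record in ``uns["provenance"]``.
    """
    X = _dense(adata.X).astype(np.float64)
    depth = X.sum(axis=1)
    if np.any(depth <= 0):
        raise ValueError("zero-depth cell encountered; run QC filtering first")
    if target_sum is None:
        target_sum = float(np.median(depth))
    vals = np.log1p(X * (target_sum / depth)[:, None])
    out = ad.AnnData(X=vals, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns["provenance"] = {
        "normalization": f"median-depth scaling (target_sum={target_sum:g}) + log1p",
        "removed_components": [],
    }
    return out


@dataclass
class ComponentDecomposition:
    """Gene loadings and unit-variance cell scores of an ICA decomposition.

    ``loadings`` is genes x components, ``scores`` is cells x components, and
    ``mean`` the per-gene centering vector; the centered input is approximated
    by ``scores @ loadings.T``.
    """

    loadings: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    n_iter: int
    specificity: np.ndarray | None = field(default=None)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T + self.mean

    def top_loading_genes(self, component: int, gene_names, k: int = 50) -> list[str]:
        w = np.abs(self.loadings[:, component])
        order = np.argsort(-w, kind="stable")[:k]
        return [gene_names[i] for i in order]


def decompose_ica(
    norm: ad.AnnData, n_components: int = 128, seed: int = 0, max_iter: int = 500
) -> ComponentDecomposition:
    """FastICA of the normalized matrix (cells as observations).

    Components are re-signed so each loading vector's largest-magnitude entry
    is positive; cell scores have unit variance.  Deterministic under a fixed
    seed and fixed input ordering.  A convergence failure is reported with the
    iteration count.
    """
    X = _dense(norm.X).astype(np.float64)
    n_cells, n_genes = X.shape
    if n_components > min(n_cells, n_genes):
        raise ValueError("n_components exceeds matrix rank bound")
    ica = FastICA(
        n_components=n_components,
        random_state=seed,
        max_iter=max_iter,
        whiten="unit-variance",
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = ica.fit_transform(X)  # cells x components
    if ica.n_iter_ >= max_iter:
        warnings.warn(
            f"FastICA stopped without convergence after {ica.n_iter_} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    loadings = ica.mixing_  # genes x components
    # sign convention: largest-|entry| of each loading vector positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    return ComponentDecomposition(
        loadings=loadings, scores=scores, mean=ica.mean_, n_iter=int(ica.n_iter_)
    )


def score_sample_specificity(
    decomp: ComponentDecomposition, sample_labels
) -> np.ndarray:
    """Between-sample over pooled within-sample variance of each component's scores.

    A component whose scores are constant within samples but differ across
    samples gets a large score; a component indifferent to sample identity
    scores near between/within parity.  Invariant to cell order.
    """
    samples = np.asarray(sample_labels)
    uniq = np.unique(samples)
    if uniq.size < 2:
        raise ValueError("sample specificity needs at least two samples")
    scores = decomp.scores
    means = np.vstack([scores[samples == s].mean(axis=0) for s in uniq])
    within = np.vstack([scores[samples == s].var(axis=0) for s in uniq])
    counts = np.array([(samples == s).sum() for s in uniq], float)
    w = counts / counts.sum()
    pooled_within = (w[:, None] * within).sum(axis=0)
    between = means.var(axis=0)
    return between / np.maximum(pooled_within, 1e-12)


def select_artifact_component(
    decomp: ComponentDecomposition, sample_labels, mad_factor: float = 5.0
) -> tuple[int | None, np.ndarray]:
    """Pick the sample-specific artifact component by a robust outlier rule.

    Returns ``(index, scores)`` where ``index`` is the top-scoring component
    if its specificity exceeds ``median + mad_factor * MAD`` of all component
    scores, else ``None``.
    """
    scores = score_sample_specificity(decomp, sample_labels)
    decomp.specificity = scores
    med = float(np.median(scores))
    mad = float(np.median(np.abs(scores - med)))
    cutoff = med + mad_factor * max(mad, 1e-12)
    best = int(np.argmax(scores))
    return (best if scores[best] > cutoff else None), scores


def remove_artifact_program(
    norm: ad.AnnData, decomp: ComponentDecomposition, component: int
) -> ad.AnnData:
    """Subtract one component's rank-one term from the normalized matrix.

    Output = input - scores[:, c] (outer) loadings[:, c]; the projections of
    all other components are unchanged.
    """
    if not 0 <= component < decomp.n_components:
        raise ValueError(f"component {component} out of range")
    X = _dense(norm.X).astype(np.float64)
    X = X - np.outer(decomp.scores[:, component], decomp.loadings[:, component])
    out = ad.AnnData(X=X, obs=norm.obs.copy(), var=norm.var.copy())
    prov = dict(norm.uns.get("provenance", {"normalization": "unknown"}))
    prov["removed_components"] = list(prov.get("removed_components", [])) + [int(component)]
    out.uns["provenance"] = prov
    return out
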