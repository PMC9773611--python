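"""Self-validation studies on planted synthetic cohorts.

Every public function here regenerates its inputs from a seed, runs the
relevant pipeline stage, and measures recovery of the planted ground truth or
agreement with an independent brute-force oracle.  They are used by the test
suite and by ``scripts/acceptance.py`` to report the package's headline
numbers; none of them reads anything from disk.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from . import synthetic
from .clustering import two_round_cluster
from .cohort import abundance_table, auroc, compare_abundance
from .communication import (
    affinity_knn,
    closeness_centrality,
    cluster_connectivity,
    lr_contribution,
    total_affinity,
)
from .integration import bicluster_genes, cluster_profile, downsample_robustness
from .preprocess import (
    QCThresholds,
    decompose_ica,
    filter_cells,
    normalize,
    remove_artifact_program,
    select_artifact_component,
)
from .stats import bh_adjust, holm_adjust, rank_sum_test, signed_rank_test
from .synthetic import generate_bulk_degs, generate_cohort

__all__ = [
    "affinity_oracle_deltas",
    "hub_recovery_study",
    "artifact_recovery",
    "clustering_recovery_study",
    "bicluster_recovery",
    "statistical_oracle_deltas",
    "qc_boundary_check",
    "abundance_recovery_study",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Child seeds below 2^31 derived deterministically from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


# ---------------------------------------------------------------------------
# 1. affinity formulas vs a naive quadruple-loop oracle
# ---------------------------------------------------------------------------

def affinity_oracle_deltas(seed: int = 0, n_cells: int = 50, n_pairs: int = 30) -> dict:
    """Compare cluster-pair mean affinities/contributions with brute force.

    A random expression fixture with random cluster labels; the oracle loops
    over every (cell, cell, pair) triple.  Returns the maximum absolute
    deviation of per-pair mean affinities and contributions, and the maximum
    deviation of the contribution sum from 1.
    """
    import anndata as ad

    rng = np.random.default_rng(seed)
    n_genes = 2 * n_pairs
    X = rng.uniform(0.0, 3.0, size=(n_cells, n_genes))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    adata = ad.AnnData(
        X=X, obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
        var=pd.DataFrame(index=genes),
    )
    pairs = pd.DataFrame(
        {
            "ligand": [genes[2 * i] for i in range(n_pairs)],
            "receptor": [genes[2 * i + 1] for i in range(n_pairs)],
        }
    )
    labels = rng.choice(["M", "N", "O"], size=n_cells)
    model = total_affinity(adata, pairs)
    max_aff = max_contrib = max_sum = 0.0
    for cm in ("M", "N", "O"):
        for cn in ("M", "N", "O"):
            if cm == cn:
                continue
            got = lr_contribution(model, labels, cm, cn)
            midx = np.flatnonzero(labels == cm)
            nidx = np.flatnonzero(labels == cn)
            oracle = np.zeros(n_pairs)
            for p in range(n_pairs):
                s = 0.0
                for c1 in midx:
                    for c2 in nidx:
                        s += X[c1, 2 * p] * X[c2, 2 * p + 1]
                oracle[p] = s / len(midx) / len(nidx)
            max_aff = max(max_aff, np.abs(got["affinity"].to_numpy() - oracle).max())
            oc = oracle / oracle.sum()
            max_contrib = max(
                max_contrib, np.abs(got["contribution"].to_numpy() - oc).max()
            )
            max_sum = max(max_sum, abs(got["contribution"].sum() - 1.0))
    return {
        "max_affinity_delta": float(max_aff),
        "max_contribution_delta": float(max_contrib),
        "max_contribution_sum_error": float(max_sum),
    }


# ---------------------------------------------------------------------------
# 2. hub recovery
# ---------------------------------------------------------------------------

def hub_recovery_study(seed: int = 0, n_seeds: int = 100, k: int = 15) -> dict:
    """Fraction of seeds where the planted hub is top-1 by closeness and all
    planted sender->receiver connectivities exceed the 0.05 cutoff."""
    hub_first = conn_above = 0
    for s in _spawn_seeds(seed, n_seeds):
        cfg = synthetic.hub_cohort_config(seed=s)
        adata, truth = generate_cohort(cfg)
        norm = normalize(adata)
        model = total_affinity(norm, truth.lr_table)
        comm = cluster_connectivity(
            affinity_knn(model, k=k), truth.cell_minor.to_numpy(), cutoff=0.05
        )
        cent = closeness_centrality(comm)
        hub_first += cent.index[0] == truth.hub_cluster
        planted = [
            (r.sender, r.receiver)
            for r in truth.axes.itertuples()
            if r.sender != r.receiver
        ]
        conn_above += all(comm.connectivity.loc[a, b] > 0.05 for a, b in planted)
    return {
        "hub_top1_rate": hub_first / n_seeds,
        "planted_connectivity_rate": conn_above / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 3. artifact removal
# ---------------------------------------------------------------------------

def artifact_recovery(seed: int = 0, n_components: int = 32) -> dict:
    """Jaccard of the selected component's top-50 loadings with the planted
    stress genes, and the residual specificity after subtraction."""
    cfg = synthetic.artifact_cohort_config(seed=seed)
    adata, truth = generate_cohort(cfg)
    norm = normalize(adata)
    samples = norm.obs["sample"].to_numpy()
    dec = decompose_ica(norm, n_components=n_components, seed=seed)
    idx, scores = select_artifact_component(dec, samples)
    if idx is None:
        return {"jaccard_top50": 0.0, "residual_specificity_ratio": 1.0}
    planted = set(truth.gene_modules.index[truth.gene_modules == "artifact"])
    top = set(dec.top_loading_genes(idx, list(norm.var_names), k=50))
    jaccard = len(top & planted) / len(top | planted)
    clean = remove_artifact_program(norm, dec, idx)
    dec2 = decompose_ica(clean, n_components=n_components, seed=seed)
    _, scores2 = select_artifact_component(dec2, samples)
    return {
        "jaccard_top50": float(jaccard),
        "residual_specificity_ratio": float(scores2.max() / scores[idx]),
    }


# ---------------------------------------------------------------------------
# 4. two-round clustering recovery
# ---------------------------------------------------------------------------

def clustering_recovery_study(seed: int = 0, n_seeds: int = 100) -> dict:
    """Fraction of seeds with major AND minor ARI >= 0.9 after two rounds."""
    ok = 0
    aris = []
    for s in _spawn_seeds(seed, n_seeds):
        cfg = synthetic.clustering_cohort_config(seed=s)
        adata, truth = generate_cohort(cfg)
        norm = normalize(adata)
        res = two_round_cluster(
            norm, seed=s, sub_resolution=0.3, marker_map=truth.major_marker_map()
        )
        a_major = adjusted_rand_score(truth.cell_major, res["major"])
        a_minor = adjusted_rand_score(truth.cell_minor, res["minor"])
        aris.append((a_major, a_minor))
        ok += (a_major >= 0.9) and (a_minor >= 0.9)
    arr = np.asarray(aris)
    return {
        "recovery_rate": ok / n_seeds,
        "median_major_ari": float(np.median(arr[:, 0])),
        "median_minor_ari": float(np.median(arr[:, 1])),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 5. bi-clustering recovery and robustness
# ---------------------------------------------------------------------------

def bicluster_recovery(seed: int = 0, reps: int = 20) -> dict:
    """ARI of the 5 planted DEG modules at matched k, and the minimum
    per-module preservation under 90% target-cell downsampling."""
    cfg = synthetic.bicluster_cohort_config(seed=seed)
    adata, truth = generate_cohort(cfg)
    norm = normalize(adata)
    degs = generate_bulk_degs(truth, cfg)
    prof = cluster_profile(norm, truth.cell_minor, degs["gene"].tolist())
    assign = bicluster_genes(prof.z, 5)
    programs = degs.set_index("gene").loc[assign.labels.index, "program"]
    ari = adjusted_rand_score(programs, assign.labels)
    rob = downsample_robustness(
        norm,
        truth.cell_minor,
        degs["gene"].tolist(),
        assign,
        target_cluster="M0.0",
        frac=0.9,
        reps=reps,
        seed=seed,
    )
    return {
        "module_ari": float(ari),
        "min_module_preservation": float(rob["preservation"].min()),
        "reps": reps,
    }


# ---------------------------------------------------------------------------
# 6. statistical oracles
# ---------------------------------------------------------------------------

def _enumerated_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    hits = total = 0
    for subset in combinations(range(len(pooled)), n1):
        u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return hits / total


def _enumerated_signed_rank_p(x: np.ndarray, y: np.ndarray) -> float:
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    mu = ranks.sum() / 2.0
    w_obs = ranks[d > 0].sum()
    hits = 0
    for mask in range(2 ** len(d)):
        w = sum(ranks[i] for i in range(len(d)) if mask >> i & 1)
        hits += abs(w - mu) >= abs(w_obs - mu) - 1e-12
    return hits / 2 ** len(d)


def statistical_oracle_deltas(seed: int = 0, n_fixtures: int = 200) -> dict:
    """Max |Delta p| of the rank tests vs full enumeration, of Holm/BH vs
    direct step formulas, and of AUROC vs pairwise concordance counting."""
    rng = np.random.default_rng(seed)
    d_rank = d_signed = d_holm = d_bh = d_auc = 0.0
    for _ in range(n_fixtures):
        n1, n2 = rng.integers(2, 9, size=2)
        x = rng.integers(0, 6, n1).astype(float)
        y = rng.integers(0, 6, n2).astype(float)
        got = rank_sum_test(x, y, method="exact").pvalue
        d_rank = max(d_rank, abs(got - _enumerated_rank_sum_p(x, y)))
        n = int(rng.integers(3, 9))
        a = rng.integers(0, 8, n).astype(float)
        b = rng.integers(0, 8, n).astype(float)
        if np.any(a != b):
            got = signed_rank_test(a, b, method="exact").pvalue
            d_signed = max(d_signed, abs(got - _enumerated_signed_rank_p(a, b)))
        p = rng.uniform(size=int(rng.integers(1, 15)))
        d_holm = max(d_holm, np.abs(holm_adjust(p) - _direct_holm(p)).max())
        d_bh = max(d_bh, np.abs(bh_adjust(p) - _direct_bh(p)).max())
        scores = rng.integers(0, 5, 20).astype(float)
        labels = rng.integers(0, 2, 20)
        if 0 < labels.sum() < 20:
            res = auroc(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            conc = sum(
                1.0 if a_ > b_ else 0.5 if a_ == b_ else 0.0
                for a_ in pos
                for b_ in neg
            )
            d_auc = max(d_auc, abs(res.auroc - conc / (len(pos) * len(neg))))
    return {
        "max_rank_sum_p_delta": float(d_rank),
        "max_signed_rank_p_delta": float(d_signed),
        "max_holm_delta": float(d_holm),
        "max_bh_delta": float(d_bh),
        "max_auroc_delta": float(d_auc),
        "n_fixtures": n_fixtures,
    }


def _direct_holm(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, min(1.0, (m - k) * p[idx]))
        adj[idx] = running
    return adj


def _direct_bh(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for k in range(m - 1, -1, -1):
        idx = order[k]
        running = min(running, min(1.0, m * p[idx] / (k + 1)))
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# 7. QC boundary fixture
# ---------------------------------------------------------------------------

def qc_boundary_check() -> dict:
    """Ten cells spanning every QC boundary vs the hand-derived retained set."""
    metrics = pd.DataFrame(
        {
            "genes_detected": [150, 200, 7500, 7501, 300, 300, 300, 300, 300, 199],
            "total_umi": [1000, 500, 75000, 1000, 499, 75001, 1000, 1000, 1000, 1000],
            "mito_frac": [0.02, 0.0999, 0.0, 0.0, 0.0, 0.0, 0.10, 0.0999, 0.2, 0.05],
        },
        index=[f"cell{i}" for i in range(10)],
    )
    keep = filter_cells(metrics, QCThresholds())
    expected = [False, True, True, False, False, False, False, True, False, False]
    mismatches = int((keep.to_numpy() != np.asarray(expected)).sum())
    return {"qc_boundary_mismatches": mismatches, "n_cells": len(metrics)}


# ---------------------------------------------------------------------------
# 8. abundance recovery
# ---------------------------------------------------------------------------

def abundance_recovery_study(seed: int = 0, n_seeds: int = 100) -> dict:
    """Fraction of seeds where the planted 5-fold enrichment is significant
    (Holm p < 0.05) with log2 ratio within +/-0.5 of log2(5)."""
    ok = 0
    errs = []
    for s in _spawn_seeds(seed, n_seeds):
        cfg = synthetic.abundance_cohort_config(seed=s)
        adata, truth = generate_cohort(cfg)
        cells = adata.obs.copy()
        cells["cluster"] = truth.cell_minor
        tab = abundance_table(cells.reset_index())
        res = compare_abundance(tab).set_index("cluster")
        row = res.loc["M0.0"]
        err = abs(row["log2_ratio"] - np.log2(5.0))
        errs.append(err)
        ok += (row["padj_holm"] < 0.05) and (err <= 0.5)
    return {
        "abundance_recovery_rate": ok / n_seeds,
        "median_log2_ratio_error": float(np.median(errs)),
        "n_seeds": n_seeds,
    }
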