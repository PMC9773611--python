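"""Cohort-level statistics: abundance shifts, signature scores, response AUROC.

Tumor-vs-normal abundance comparison follows per-sample composition: samples
with too few cells are excluded (default < 200 cells; in a lineage-restricted
run, < 50 cells of that lineage), each cluster's share of a sample is
expressed in percent, and tumor and normal percent distributions are compared
by a Wilcoxon rank-sum test (or the paired signed-rank variant for matched
samples) with Holm correction across clusters.  The displayed effect is
log2(mean tumor percent / mean normal percent) with a pseudocount.

Gene-signature scores are rank-based (UCell-style): within a cell's or bulk
sample's expression ranking (ties averaged, ranks clipped at ``max_rank``),
the Mann-Whitney U statistic of the signature genes is mapped to [0, 1], so
the score is invariant to any monotone transform of the expression vector.
AUROC for response classification is the normalized U statistic with tie
handling, together with the full sensitivity/specificity threshold sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import holm_adjust, rank_sum_test, signed_rank_test

__all__ = [
    "AbundanceTable",
    "abundance_table",
    "compare_abundance",
    "signature_score",
    "ROCResult",
    "auroc",
]


@dataclass
class AbundanceTable:
    """Per-sample cluster composition after exclusion rules."""

    per_sample: pd.DataFrame  # sample, tissue, patient, cluster, n_cells, percent
    excluded_samples: list[str]

    def percents(self) -> pd.DataFrame:
        """Wide sample x cluster percent matrix (rows sum to 100)."""
        return self.per_sample.pivot_table(
            index="sample", columns="cluster", values="percent", fill_value=0.0
        )


def abundance_table(
    cells: pd.DataFrame,
    min_cells_sample: int = 200,
    lineage_clusters: list[str] | None = None,
    min_cells_lineage: int = 50,
) -> AbundanceTable:
    """Per-sample cell-type percentages with the study's exclusion rules.

    ``cells`` needs columns ``sample``, ``tissue``, ``patient``, ``cluster``.
    Samples with fewer than ``min_cells_sample`` cells overall are dropped.
    When ``lineage_clusters`` restricts the analysis to one lineage, samples
    with fewer than ``min_cells_lineage`` cells of that lineage are dropped
    and percentages are computed within the lineage.
    """
    required = {"sample", "tissue", "patient", "cluster"}
    if not required <= set(cells.columns):
        raise ValueError(f"cells table needs columns {sorted(required)}")
    totals = cells.groupby("sample").size()
    excluded = sorted(totals.index[totals < min_cells_sample])
    kept = cells[~cells["sample"].isin(excluded)]
    if lineage_clusters is not None:
        kept = kept[kept["cluster"].isin(lineage_clusters)]
        lin_totals = kept.groupby("sample").size()
        lin_excluded = sorted(
            set(lin_totals.index[lin_totals < min_cells_lineage])
            | (set(kept["sample"].unique()) - set(lin_totals.index))
        )
        excluded = sorted(set(excluded) | set(lin_excluded))
        kept = kept[~kept["sample"].isin(lin_excluded)]
    if kept.empty:
        raise ValueError("all samples excluded")
    counts = (
        kept.groupby(["sample", "tissue", "patient", "cluster"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    denom = counts.groupby("sample")["n_cells"].transform("sum")
    counts["percent"] = 100.0 * counts["n_cells"] / denom
    return AbundanceTable(per_sample=counts, excluded_samples=excluded)


def compare_abundance(
    table: AbundanceTable,
    paired: bool = False,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Tumor-vs-normal abundance test per cluster with Holm correction.

    Unpaired mode runs a Wilcoxon rank-sum test of per-sample percents; paired
    mode a signed-rank test on patients with both tissues.  The log2 ratio is
    log2((mean tumor percent + pseudocount) / (mean normal percent +
    pseudocount)); the pseudocount (percentage points) guards tumor- or
    normal-exclusive clusters.
    """
    wide = table.percents()
    meta = table.per_sample[["sample", "tissue", "patient"]].drop_duplicates().set_index("sample")
    tissue = meta.loc[wide.index, "tissue"]
    rows = []
    for cl in wide.columns:
        t = wide.loc[tissue == "tumor", cl].to_numpy()
        n = wide.loc[tissue == "normal", cl].to_numpy()
        if len(t) == 0 or len(n) == 0:
            rows.append((cl, np.nan, np.nan, np.nan, np.nan))
            continue
        log2_ratio = float(np.log2((t.mean() + pseudocount) / (n.mean() + pseudocount)))
        if paired:
            patients = meta.loc[wide.index, "patient"]
            both = sorted(
                set(patients[tissue == "tumor"]) & set(patients[tissue == "normal"])
            )
            tv, nv = [], []
            for p in both:
                tv.append(wide.loc[(tissue == "tumor") & (patients == p), cl].mean())
                nv.append(wide.loc[(tissue == "normal") & (patients == p), cl].mean())
            res = signed_rank_test(np.asarray(tv), np.asarray(nv))
        else:
            res = rank_sum_test(t, n)
        rows.append((cl, t.mean(), n.mean(), log2_ratio, res.pvalue))
    out = pd.DataFrame(
        rows, columns=["cluster", "mean_tumor_pct", "mean_normal_pct", "log2_ratio", "pval"]
    )
    valid = out["pval"].notna()
    out["padj_holm"] = np.nan
    out.loc[valid, "padj_holm"] = holm_adjust(out.loc[valid, "pval"].to_numpy())
    return out


def signature_score(
    expr: pd.DataFrame, gene_sets: dict[str, list[str]], max_rank: int = 1500
) -> pd.DataFrame:
    """Rank-based signature scores per unit (cell or bulk sample) in [0, 1].

    ``expr`` is units x genes.  For each unit, genes are ranked by descending
    expression with ties averaged; ranks beyond ``max_rank`` are clipped to
    ``max_rank + 1`` (signature genes missing from the expression space get
    the clipped worst rank).  The score is ``1 - U / (n_sig * max_rank)``
    where U is the Mann-Whitney statistic of the signature ranks, so a
    signature occupying the top ranks scores 1.
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    for name, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"signature {name!r} is empty")
        if not set(genes) & set(expr.columns):
            raise ValueError(f"signature {name!r} shares no genes with the matrix")
    vals = expr.to_numpy(float)
    # rank 1 = highest expression; average ties; clip at max_rank
    ranks = sps.rankdata(-vals, axis=1)
    ranks = np.minimum(ranks, max_rank + 1)
    cols = {g: i for i, g in enumerate(expr.columns)}
    out = {}
    for name, genes in gene_sets.items():
        n_sig = len(genes)
        idx = [cols[g] for g in genes if g in cols]
        n_missing = n_sig - len(idx)
        r_sum = ranks[:, idx].sum(axis=1) + n_missing * (max_rank + 1)
        u = r_sum - n_sig * (n_sig + 1) / 2.0
        out[name] = 1.0 - u / (n_sig * max_rank)
    return pd.DataFrame(out, index=expr.index).clip(lower=0.0, upper=1.0)


@dataclass
class ROCResult:
    auroc: float
    sweep: pd.DataFrame  # threshold, sensitivity, specificity

    def youden_threshold(self) -> float:
        j = self.sweep["sensitivity"] + self.sweep["specificity"] - 1.0
        return float(self.sweep.loc[j.idxmax(), "threshold"])


def auroc(scores, labels) -> ROCResult:
    """AUROC of a score against binary labels, with a full threshold sweep.

    AUROC = U / (n_pos * n_neg) with average-rank tie handling (a tie between
    a positive and a negative counts 1/2).  The sweep classifies score >=
    threshold as positive at every observed score.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    area = u / (n_pos * n_neg)
    rows = []
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        rows.append((float(thr), tp / n_pos, tn / n_neg))
    sweep = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])
    return ROCResult(auroc=float(area), sweep=sweep)
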