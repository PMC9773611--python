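"""Plain-text on-disk formats: Matrix Market counts with TSV sidecars.

A cohort directory holds ``matrix.mtx`` (gene x cell sparse counts),
``genes.tsv`` (gene id + mito flag), ``barcodes.tsv`` (cell ids) and
``cells.tsv`` (per-cell metadata).  Ground truth round-trips as JSON and DEG
lists as TSV with columns gene/log2fc/padj.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .synthetic import GroundTruth

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "read_ground_truth",
    "write_degs",
    "read_degs",
]


def write_cohort(adata: ad.AnnData, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    mmwrite(out / "matrix.mtx", X.T.tocoo())  # genes x cells on disk
    genes = pd.DataFrame(
        {"gene": adata.var_names, "mito": adata.var.get("mito", False)}
    )
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        out / "barcodes.tsv", sep="\t", index=False
    )
    adata.obs.rename_axis("cell").reset_index().to_csv(
        out / "cells.tsv", sep="\t", index=False
    )


def read_cohort(indir) -> ad.AnnData:
    ind = Path(indir)
    X = sp.csr_matrix(mmread(ind / "matrix.mtx").T)
    genes = pd.read_csv(ind / "genes.tsv", sep="\t").set_index("gene")
    cells = pd.read_csv(ind / "cells.tsv", sep="\t").set_index("cell")
    if genes.index.duplicated().any() or cells.index.duplicated().any():
        raise ValueError("duplicate gene or cell identifiers")
    genes.index = genes.index.astype(str)
    cells.index = cells.index.astype(str)
    return ad.AnnData(X=X, obs=cells, var=genes)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "cell_minor": truth.cell_minor.to_dict(),
        "cell_major": truth.cell_major.to_dict(),
        "gene_modules": truth.gene_modules.to_dict(),
        "axes": truth.axes.to_dict(orient="records"),
        "lr_table": truth.lr_table.to_dict(orient="records"),
        "hub_cluster": truth.hub_cluster,
        "tumor_enriched": truth.tumor_enriched,
        "deg_programs": truth.deg_programs,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        cell_minor=pd.Series(payload["cell_minor"], name="true_minor"),
        cell_major=pd.Series(payload["cell_major"], name="true_major"),
        gene_modules=pd.Series(payload["gene_modules"], name="module"),
        axes=pd.DataFrame(
            payload["axes"],
            columns=["ligand", "receptor", "sender", "receiver", "effect"],
        ),
        lr_table=pd.DataFrame(payload["lr_table"], columns=["ligand", "receptor"]),
        hub_cluster=payload["hub_cluster"],
        tumor_enriched=payload["tumor_enriched"],
        deg_programs=payload["deg_programs"],
    )


def write_degs(degs: pd.DataFrame, path) -> None:
    degs[["gene", "log2fc", "padj"]].to_csv(path, sep="\t", index=False)


def read_degs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "log2fc", "padj"} <= set(df.columns):
        raise ValueError("DEG table needs columns gene, log2fc, padj")
    return df
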