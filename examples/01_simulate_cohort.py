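"""Simulate a multi-patient tumor/normal cohort and write it to disk.

Generates a 6-patient cohort (matched tumor and normal samples, two library
chemistries) with planted major/minor cell types, inspects the per-cell QC
metrics, and writes Matrix Market counts plus TSV sidecars and the ground
truth JSON.
"""

from pathlib import Path

import tmekit as tk

cfg = tk.synthetic.clustering_cohort_config(seed=0)
adata, truth = tk.generate_cohort(cfg)
metrics = tk.compute_qc_metrics(adata)

print(f"cohort: {adata.n_obs} cells x {adata.n_vars} genes, "
      f"{adata.obs['sample'].nunique()} samples, "
      f"{adata.obs['patient'].nunique()} patients")
print(f"planted clusters: {sorted(truth.cell_minor.unique())}")
print("median genes/cell:", int(metrics["genes_detected"].median()),
      "| median UMI/cell:", int(metrics["total_umi"].median()),
      "| median mito fraction:", round(float(metrics["mito_frac"].median()), 3))
# all cells should sit inside the QC window (200-7500 genes, 500-75000 UMI,
# <10% mito), so the default cohort survives filtering intact
print("cells passing QC:", int(tk.filter_cells(metrics).sum()), "/", adata.n_obs)

out = Path("scratch/example_cohort")
tk.io.write_cohort(adata, out)
tk.io.write_ground_truth(truth, out / "truth.json")
print("wrote", out)
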