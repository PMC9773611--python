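"""Synthetic multi-patient tumor/normal single-cell cohorts with known ground truth.

The generator emulates the structure of a droplet-based tumor-microenvironment
study: several patients, each contributing a tumor and a matched normal sample,
profiled in one of two library chemistries.  Counts are negative-binomial
(Gamma-Poisson) with planted structure:

* cluster identity   -- disjoint marker-gene blocks with a log2 mean shift,
  organised in two levels (major cell types, minor subtypes within each);
* a dissociation-stress artifact -- a dedicated gene block elevated only in a
  configurable subset of samples (additive on the log2-mean scale);
* ligand-receptor communication axes -- ligand genes up-shifted in a sender
  cluster and receptor genes in a receiver cluster, including an optional
  designated hub cluster sending several axes;
* tumor-enriched/depleted cell types -- per-sample cluster composition is
  Dirichlet-multinomial, with tumor-sample expectations scaled by planted fold
  changes so the realized percent ratio matches the fold change in expectation.

Everything planted is recorded in a :class:`GroundTruth` so each downstream
stage of the pipeline has a recoverable target.

Randomness: one master seed; each stage draws from ``PCG64(seed + offset)``
with the fixed offsets in :data:`SEED_OFFSETS`, so outputs are bit-identical
across runs and platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "LRAxis",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_bulk_degs",
    "clustering_cohort_config",
    "hub_cohort_config",
    "artifact_cohort_config",
    "abundance_cohort_config",
    "bicluster_cohort_config",
]

#: fixed per-stage seed offsets added to the master seed
SEED_OFFSETS = {"genes": 1, "composition": 2, "counts": 3, "degs": 4}


@dataclass(frozen=True)
class LRAxis:
    """One planted ligand-receptor communication axis.

    ``effect`` is the log2 up-shift of the ligand in the sender cluster and of
    the receptor in the receiver cluster.  An axis with ``effect == 0`` plants
    the genes at baseline everywhere -- a decoy pair for the communication
    database.
    """

    ligand: str
    receptor: str
    sender: str
    receiver: str
    effect: float


@dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int = 5
    cells_per_sample: int = 150
    n_genes: int = 300
    n_major_types: int = 3
    n_minor_per_major: int = 2
    marker_genes_per_cluster: int = 10
    marker_log2_effect: float = 3.0
    baseline_mean: float = 3.0
    nb_dispersion: float = 2.0
    mito_gene_fraction: float = 0.05
    artifact_gene_count: int = 0
    artifact_samples: tuple[str, ...] = ()
    artifact_effect: float = 0.0
    lr_pairs: tuple[LRAxis, ...] = ()
    hub_cluster: str | None = None
    tumor_enriched: dict[str, float] = field(default_factory=dict)
    degs_per_module: int = 20
    seed: int = 0
    # surrogate knobs beyond the planted structure
    major_markers_per_type: int = 12
    major_log2_effect: float | None = None  # defaults to marker_log2_effect
    base_proportions: dict[str, float] | None = None
    dirichlet_concentration: float = 100.0
    gene_mean_sigma: float = 0.4
    #: off-target baseline mean of ligand/receptor genes -- receptor and
    #: ligand expression is lineage-restricted, so outside their planted
    #: sender/receiver clusters these genes sit near this low mean
    lr_background_mean: float = 0.25

    # ---- derived vocabulary -------------------------------------------------
    @property
    def major_ids(self) -> list[str]:
        return [f"M{i}" for i in range(self.n_major_types)]

    @property
    def minor_ids(self) -> list[str]:
        return [
            f"M{i}.{j}"
            for i in range(self.n_major_types)
            for j in range(self.n_minor_per_major)
        ]

    def validate(self) -> None:
        if self.n_patients < 1 or self.cells_per_sample < 1:
            raise ValueError("need at least one patient and one cell per sample")
        if not 0.0 <= self.mito_gene_fraction <= 1.0:
            raise ValueError("mito_gene_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for cl, fc in self.tumor_enriched.items():
            if fc <= 0:
                raise ValueError(f"tumor_enriched fold change for {cl} must be > 0")
            if cl not in self.minor_ids:
                raise ValueError(f"tumor_enriched references unknown cluster {cl}")
        for axis in self.lr_pairs:
            for cl in (axis.sender, axis.receiver):
                if cl not in self.minor_ids:
                    raise ValueError(f"LR axis references unknown cluster {cl}")
        if self.hub_cluster is not None and self.hub_cluster not in self.minor_ids:
            raise ValueError(f"hub_cluster {self.hub_cluster} not among clusters")
        if self._gene_demand() > self.n_genes:
            raise ValueError(
                f"planted gene demand {self._gene_demand()} exceeds n_genes={self.n_genes}"
            )

    def _lr_gene_names(self) -> list[str]:
        names: list[str] = []
        for axis in self.lr_pairs:
            for g in (axis.ligand, axis.receptor):
                if g not in names:
                    names.append(g)
        return names

    def _gene_demand(self) -> int:
        n_mito = int(round(self.mito_gene_fraction * self.n_genes))
        n_major_mk = self.n_major_types * self.major_markers_per_type
        n_minor_mk = len(self.minor_ids) * self.marker_genes_per_cluster
        return (
            n_mito
            + n_major_mk
            + n_minor_mk
            + self.artifact_gene_count
            + len(self._lr_gene_names())
        )


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by the emitted identifiers."""

    cell_minor: pd.Series
    cell_major: pd.Series
    gene_modules: pd.Series
    axes: pd.DataFrame  # planted axes (effect > 0): ligand, receptor, sender, receiver, effect
    lr_table: pd.DataFrame  # full pair database incl. decoys: ligand, receptor
    hub_cluster: str | None
    tumor_enriched: dict[str, float]
    deg_programs: dict[str, str] = field(default_factory=dict)

    def marker_genes(self, cluster: str) -> list[str]:
        """Planted minor-cluster marker genes, in gene order."""
        m = self.gene_modules
        return list(m.index[m == f"marker:{cluster}"])

    def major_marker_map(self) -> dict[str, list[str]]:
        """Canonical marker genes per major type (the curation a study keeps in YAML)."""
        m = self.gene_modules
        majors = sorted(self.cell_major.unique())
        return {
            maj: list(m.index[m == f"major_marker:{maj}"]) for maj in majors
        }

    def validate(self) -> None:
        genes = set(self.gene_modules.index)
        clusters = set(self.cell_minor.unique())
        for _, row in self.axes.iterrows():
            if row["ligand"] not in genes or row["receptor"] not in genes:
                raise ValueError("planted axis references unknown genes")
            if row["sender"] not in clusters or row["receiver"] not in clusters:
                raise ValueError("planted axis references unknown clusters")


# ---------------------------------------------------------------------------
# gene vocabulary
# ---------------------------------------------------------------------------

def _build_gene_table(config: SyntheticConfig) -> pd.DataFrame:
    """Assign every gene slot a name, module label, and log2 shift recipe."""
    rows: list[tuple[str, str]] = []  # (name, module)
    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    for j in range(n_mito):
        rows.append((f"MT-{j:03d}", "mito"))
    for major in config.major_ids:
        for j in range(config.major_markers_per_type):
            rows.append((f"MK-{major}-{j:02d}", f"major_marker:{major}"))
    for minor in config.minor_ids:
        for j in range(config.marker_genes_per_cluster):
            rows.append((f"MK-{minor}-{j:02d}", f"marker:{minor}"))
    for j in range(config.artifact_gene_count):
        rows.append((f"HSP-{j:03d}", "artifact"))
    lr_roles: dict[str, str] = {}
    for i, axis in enumerate(config.lr_pairs):
        lr_roles.setdefault(axis.ligand, f"ligand:{i}")
        lr_roles.setdefault(axis.receptor, f"receptor:{i}")
    for g, role in lr_roles.items():
        rows.append((g, role))
    n_noise = config.n_genes - len(rows)
    for j in range(n_noise):
        rows.append((f"G{j:04d}", "noise"))
    names = [r[0] for r in rows]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names in synthetic vocabulary")
    return pd.DataFrame({"gene": names, "module": [r[1] for r in rows]}).set_index("gene")


def _log2_shifts(config: SyntheticConfig, gene_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster log2 mean shifts (genes x minor clusters)."""
    major_eff = (
        config.marker_log2_effect
        if config.major_log2_effect is None
        else config.major_log2_effect
    )
    shifts = pd.DataFrame(
        0.0, index=gene_table.index, columns=config.minor_ids
    )
    for minor in config.minor_ids:
        major = minor.split(".")[0]
        shifts.loc[gene_table["module"] == f"major_marker:{major}", minor] = major_eff
        shifts.loc[gene_table["module"] == f"marker:{minor}", minor] = (
            config.marker_log2_effect
        )
    for axis in config.lr_pairs:
        if axis.effect:
            shifts.loc[axis.ligand, axis.sender] += axis.effect
            shifts.loc[axis.receptor, axis.receiver] += axis.effect
    return shifts


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _expected_proportions(config: SyntheticConfig, tissue: str) -> np.ndarray:
    minors = config.minor_ids
    if config.base_proportions is not None:
        base = np.array([config.base_proportions[m] for m in minors], float)
        base = base / base.sum()
    else:
        base = np.full(len(minors), 1.0 / len(minors))
    if tissue == "normal" or not config.tumor_enriched:
        return base
    props = base.copy()
    enriched = np.array([m in config.tumor_enriched for m in minors])
    fc = np.array([config.tumor_enriched.get(m, 1.0) for m in minors])
    props[enriched] = base[enriched] * fc[enriched]
    planted_mass = props[enriched].sum()
    if planted_mass >= 1.0:
        raise ValueError("tumor_enriched fold changes exceed unit total abundance")
    props[~enriched] *= (1.0 - planted_mass) / base[~enriched].sum()
    return props


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a cohort of tumor/normal samples with planted structure.

    Returns an :class:`anndata.AnnData` with raw integer counts (CSR sparse),
    per-cell metadata (``patient``, ``sample``, ``tissue``, ``batch``) and a
    boolean ``mito`` flag per gene, together with the :class:`GroundTruth`.
    """
    config.validate()
    gene_table = _build_gene_table(config)
    shifts = _log2_shifts(config, gene_table)

    rng_genes = np.random.Generator(np.random.PCG64(config.seed + SEED_OFFSETS["genes"]))
    base_means = config.baseline_mean * rng_genes.lognormal(
        mean=-0.5 * config.gene_mean_sigma**2,
        sigma=config.gene_mean_sigma,
        size=config.n_genes,
    )
    is_lr = gene_table["module"].str.startswith(("ligand:", "receptor:")).to_numpy()
    base_means[is_lr] = config.lr_background_mean

    rng_comp = np.random.Generator(
        np.random.PCG64(config.seed + SEED_OFFSETS["composition"])
    )
    rng_counts = np.random.Generator(
        np.random.PCG64(config.seed + SEED_OFFSETS["counts"])
    )

    minors = config.minor_ids
    obs_rows = []
    count_blocks = []
    theta = config.nb_dispersion
    shift_mat = shifts.to_numpy()  # genes x minors
    artifact_mask = (gene_table["module"] == "artifact").to_numpy()

    for p in range(config.n_patients):
        patient = f"P{p:02d}"
        batch = "3prime" if p % 2 == 0 else "5prime"
        for tissue, suffix in (("tumor", "T"), ("normal", "N")):
            sample = f"{patient}{suffix}"
            props = _expected_proportions(config, tissue)
            alpha = props * config.dirichlet_concentration
            theta_s = rng_comp.dirichlet(alpha)
            n_per_cluster = rng_comp.multinomial(config.cells_per_sample, theta_s)
            in_artifact = sample in config.artifact_samples
            cell_idx = 0
            for ci, minor in enumerate(minors):
                n = int(n_per_cluster[ci])
                if n == 0:
                    continue
                log2mu = np.log2(base_means) + shift_mat[:, ci]
                if in_artifact:
                    log2mu = log2mu + config.artifact_effect * artifact_mask
                mu = np.exp2(log2mu)
                lam = rng_counts.gamma(shape=theta, scale=mu / theta, size=(n, config.n_genes))
                block = rng_counts.poisson(lam).astype(np.int32)
                count_blocks.append(block)
                for _ in range(n):
                    obs_rows.append(
                        (f"{sample}_{cell_idx:04d}", patient, sample, tissue, batch, minor)
                    )
                    cell_idx += 1

    counts = np.vstack(count_blocks)
    obs = pd.DataFrame(
        obs_rows, columns=["cell", "patient", "sample", "tissue", "batch", "true_minor"]
    ).set_index("cell")
    obs["true_major"] = obs["true_minor"].str.split(".").str[0]

    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs[["patient", "sample", "tissue", "batch"]].copy(),
        var=pd.DataFrame(
            {"mito": (gene_table["module"] == "mito").to_numpy()}, index=gene_table.index
        ),
    )

    lr_table = pd.DataFrame(
        [(a.ligand, a.receptor) for a in config.lr_pairs],
        columns=["ligand", "receptor"],
    ).drop_duplicates(ignore_index=True)
    axes = pd.DataFrame(
        [
            (a.ligand, a.receptor, a.sender, a.receiver, a.effect)
            for a in config.lr_pairs
            if a.effect
        ],
        columns=["ligand", "receptor", "sender", "receiver", "effect"],
    )
    truth = GroundTruth(
        cell_minor=obs["true_minor"].copy(),
        cell_major=obs["true_major"].copy(),
        gene_modules=gene_table["module"].copy(),
        axes=axes,
        lr_table=lr_table,
        hub_cluster=config.hub_cluster,
        tumor_enriched=dict(config.tumor_enriched),
    )
    truth.validate()
    return adata, truth


def generate_bulk_degs(
    truth: GroundTruth,
    config: SyntheticConfig,
    programs: list[str] | None = None,
    decoy_fraction: float = 0.0,
) -> pd.DataFrame:
    """Emit a bulk-DEG list whose genes map to planted cell-type programs.

    Each program (a planted minor cluster) contributes ``config.degs_per_module``
    of its marker genes with synthetic log2FC and adjusted p passing the
    upstream input contract (padj < 1e-5, log2FC > 2).  ``decoy_fraction``
    adds ``round(decoy_fraction * degs_per_module)`` noise genes per program,
    labeled ``"noise"`` in the ground truth.
    """
    if programs is None:
        programs = sorted(truth.cell_minor.unique())
    if not programs:
        raise ValueError("need at least one planted program")
    rng = np.random.Generator(np.random.PCG64(config.seed + SEED_OFFSETS["degs"]))
    k = config.degs_per_module
    rows: list[tuple[str, float, float, str]] = []
    for prog in programs:
        markers = truth.marker_genes(prog)
        if k > len(markers):
            raise ValueError(
                f"degs_per_module={k} exceeds the {len(markers)} planted markers of {prog}"
            )
        for g in markers[:k]:
            rows.append((g, rng.uniform(2.2, 5.0), 10.0 ** -rng.uniform(6, 12), prog))
    n_decoys = int(round(decoy_fraction * k)) * len(programs)
    if n_decoys:
        noise_pool = list(
            truth.gene_modules.index[truth.gene_modules == "noise"]
        )
        if n_decoys > len(noise_pool):
            raise ValueError("not enough noise genes for the requested decoy fraction")
        for g in rng.choice(noise_pool, size=n_decoys, replace=False):
            rows.append((str(g), rng.uniform(2.2, 5.0), 10.0 ** -rng.uniform(6, 12), "noise"))
    degs = pd.DataFrame(rows, columns=["gene", "log2fc", "padj", "program"])
    truth.deg_programs.update(dict(zip(degs["gene"], degs["program"])))
    return degs


# ---------------------------------------------------------------------------
# preset study conditions
# ---------------------------------------------------------------------------

def clustering_cohort_config(seed: int = 0) -> SyntheticConfig:
    """Two-level cohort for the stepwise clustering stage.

    3 major types x 2 subtypes, 6 patients with matched tumor/normal samples
    (12 samples, 1200 cells): every minor cluster receives cells from all
    patients and major clusters stay above the subclustering size floor.
    """
    return SyntheticConfig(
        n_patients=6,
        cells_per_sample=100,
        n_genes=300,
        n_major_types=3,
        n_minor_per_major=2,
        marker_genes_per_cluster=10,
        marker_log2_effect=3.0,
        major_markers_per_type=12,
        seed=seed,
    )


def hub_cohort_config(seed: int = 0) -> SyntheticConfig:
    """Communication cohort: 8 clusters, one hub sending 5 planted axes.

    Every cluster carries an autocrine (self) ligand-receptor pair so that
    cells preferentially neighbor their own cluster in the affinity graph;
    the hub cluster M0.0 additionally sends five strong paracrine axes to
    clusters M1.0..M5.0.  Four decoy pairs (effect 0) pad the pair database.
    """
    minors = [f"M{i}.0" for i in range(8)]
    pairs: list[LRAxis] = []
    for i, m in enumerate(minors):
        pairs.append(LRAxis(f"LIGA-{i}", f"RECA-{i}", m, m, 5.0))
    for j in range(1, 6):
        pairs.append(LRAxis(f"LIGH-{j}", f"RECH-{j}", "M0.0", f"M{j}.0", 6.0))
    for d in range(4):
        pairs.append(LRAxis(f"LIGD-{d}", f"RECD-{d}", "M0.0", "M0.0", 0.0))
    return SyntheticConfig(
        n_patients=4,
        cells_per_sample=100,
        n_genes=300,
        n_major_types=8,
        n_minor_per_major=1,
        marker_genes_per_cluster=8,
        marker_log2_effect=3.0,
        major_markers_per_type=8,
        lr_pairs=tuple(pairs),
        hub_cluster="M0.0",
        seed=seed,
    )


def artifact_cohort_config(seed: int = 0) -> SyntheticConfig:
    """Cohort with a dissociation-stress program in two of six samples."""
    return SyntheticConfig(
        n_patients=3,
        cells_per_sample=150,
        n_genes=300,
        n_major_types=2,
        n_minor_per_major=1,
        marker_genes_per_cluster=10,
        marker_log2_effect=3.0,
        artifact_gene_count=50,
        artifact_samples=("P00T", "P01N"),
        artifact_effect=2.5,
        seed=seed,
    )


def abundance_cohort_config(seed: int = 0) -> SyntheticConfig:
    """Abundance cohort: 10 tumor + 10 normal samples, one 5-fold enriched cluster.

    The enriched cluster M0.0 holds 4% of cells in normal tissue and 20% in
    tumor tissue in expectation; samples are large enough (250 cells) that the
    min-200-cells sample filter keeps all of them.
    """
    minors = [f"M{i}.0" for i in range(6)]
    base = {m: (0.04 if m == "M0.0" else 0.96 / 5) for m in minors}
    return SyntheticConfig(
        n_patients=10,
        cells_per_sample=250,
        n_genes=300,
        n_major_types=6,
        n_minor_per_major=1,
        marker_genes_per_cluster=8,
        base_proportions=base,
        tumor_enriched={"M0.0": 5.0},
        dirichlet_concentration=150.0,
        seed=seed,
    )


def bicluster_cohort_config(seed: int = 0) -> SyntheticConfig:
    """Bulk-integration cohort: 5 cell-type programs with 20 markers each."""
    return SyntheticConfig(
        n_patients=3,
        cells_per_sample=150,
        n_genes=400,
        n_major_types=5,
        n_minor_per_major=1,
        marker_genes_per_cluster=20,
        marker_log2_effect=3.0,
        degs_per_module=20,
        seed=seed,
    )
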