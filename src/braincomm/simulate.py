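"""Synthetic single-cell and bulk expression with known communication ground truth.

The single-cell generator emulates the statistical shape of droplet brain
scRNA/snRNA-seq data: negative-binomial counts with lognormally distributed
per-gene means, six major brain cell types distinguished by elevated marker
genes, a mitochondrial gene block with a designated high-content cell fraction
(to exercise the >20%% QC filter), and "planted" ligand-receptor signals whose
sender/receiver expression is multiplied by ``signal_fold`` only in samples
carrying the pair's condition label.

Planted genes follow an induction-from-repressed-baseline design: the planted
gene has a depressed baseline mean in its focal cell type (``planted_base_mean``,
the sender type for a ligand, the receiver type for a receptor) and a
constitutive baseline elsewhere (``planted_offtype_mean``). Under the matching
condition the focal-type mean is multiplied by ``signal_fold``, lifting it above
the constitutive level. This mimics disease-induced, cell-type-restricted
signaling and yields communication that is genuinely condition-specific rather
than a uniform shift.

The bulk generator plants disease subtypes as ligand-vs-receptor rank reversals:
each subtype lowers the ligand and raises the receptor of its own edge set by
``rank_shift`` on the log-expression scale, exactly the signal the
edge-perturbation subtyping statistic measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .resources import LRPair

logger = logging.getLogger(__name__)

BRAIN_CELL_TYPES: tuple[str, ...] = (
    "astrocytes",
    "endothelial cells",
    "microglia",
    "neurons",
    "OPC",
    "oligodendrocytes",
)

#: Canonical human marker panel for the six major brain cell types.
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "astrocytes": ("GFAP", "AQP4", "SLC1A2", "ALDH1L1", "S100B", "GJA1", "SLC1A3", "FGFR3"),
    "endothelial cells": ("CLDN5", "FLT1", "PECAM1", "VWF", "A2M", "ITM2A", "RGS5", "SLC2A1"),
    "microglia": ("CX3CR1", "CSF1R", "P2RY12", "TMEM119", "AIF1", "ITGAM", "PTPRC", "C1QB"),
    "neurons": ("SLC17A7", "SNAP25", "RBFOX3", "SYT1", "GAD1", "NEFL", "STMN2", "GRIN1"),
    "OPC": ("PDGFRA", "CSPG4", "OLIG1", "SOX10", "VCAN", "GPR17", "LHFPL3", "SSTR1"),
    "oligodendrocytes": ("MAG", "OLIG2", "MOG", "MBP", "PLP1", "MOBP", "CNP", "CLDN11"),
}


@dataclass(frozen=True)
class PlantedPair:
    """A ligand-receptor signal planted into the simulation ground truth."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    condition: str
    signal_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.signal_fold < 1:
            raise ValueError("signal_fold must be >= 1")

    @property
    def pair_id(self) -> str:
        return f"{self.ligand}_{self.receptor}"


@dataclass
class SimConfig:
    """Parameters of the single-cell simulator.

    ``n_genes`` counts background genes (named ``G0001``...); marker and
    mitochondrial genes are added on top. ``nb_mean`` is the median baseline
    negative-binomial mean per cell (per-gene means are lognormal around it
    with log-sd ``nb_sigma``); variance is mean + mean^2/``nb_dispersion``.
    """

    n_cells_per_type: int = 60
    cell_types: tuple[str, ...] = BRAIN_CELL_TYPES
    n_genes: int = 200
    n_mito_genes: int = 10
    nb_mean: float = 2.0
    nb_sigma: float = 0.8
    nb_dispersion: float = 5.0
    marker_fold: float = 6.0
    marker_base_mean: float = 4.0
    markers: Mapping[str, Sequence[str]] | None = None
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_base_mean: float = 0.2
    planted_offtype_mean: float = 1.0
    mito_high_fraction: float = 0.05
    mito_high_level: float = 0.35
    mito_base_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_type < 1 or self.n_genes < 1 or self.n_mito_genes < 1:
            raise ValueError("counts must be >= 1")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if not 0 <= self.mito_high_fraction <= 1:
            raise ValueError("mito_high_fraction must be in [0, 1]")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("duplicate cell types")
        self.planted_pairs = tuple(self.planted_pairs)
        for p in self.planted_pairs:
            if p.sender not in self.cell_types or p.receiver not in self.cell_types:
                raise ValueError(f"planted pair {p.pair_id}: unknown sender/receiver type")
        if self.markers is None:
            self.markers = {t: DEFAULT_MARKERS.get(t, ()) for t in self.cell_types}

    @property
    def background_genes(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def marker_genes(self) -> list[str]:
        out: list[str] = []
        for t in self.cell_types:
            out.extend(g for g in self.markers.get(t, ()) if g not in out)
        return out

    @property
    def mito_genes(self) -> list[str]:
        return [f"MT-G{i + 1:02d}" for i in range(self.n_mito_genes)]

    @property
    def gene_universe(self) -> list[str]:
        return self.background_genes + self.marker_genes + self.mito_genes


def _type_mean_matrix(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline mean counts per (cell type, gene), before condition effects."""
    genes = config.gene_universe
    base = pd.Series(0.0, index=genes)
    base[config.background_genes] = rng.lognormal(
        mean=np.log(config.nb_mean), sigma=config.nb_sigma, size=config.n_genes
    )
    # canonical cell-type markers are abundant transcripts in brain data
    base[config.marker_genes] = config.marker_base_mean

    M = pd.DataFrame(
        np.tile(base.values, (len(config.cell_types), 1)),
        index=list(config.cell_types),
        columns=genes,
    )
    for t in config.cell_types:
        for g in config.markers.get(t, ()):
            M.loc[t, g] = config.marker_base_mean * config.marker_fold

    # planted genes: constitutive off-type baseline, repressed in the focal type
    planted_focals: dict[str, set[str]] = {}
    gene_set = set(genes)
    mito_set = set(config.mito_genes)
    for p in config.planted_pairs:
        for gene, focal in ((p.ligand, p.sender), (p.receptor, p.receiver)):
            if gene not in gene_set or gene in mito_set:
                raise ValueError(f"planted gene {gene} not in gene universe")
            planted_focals.setdefault(gene, set()).add(focal)
    for gene, focals in planted_focals.items():
        M[gene] = config.planted_offtype_mean
        M.loc[sorted(focals), gene] = config.planted_base_mean
    return M


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with variance mean + mean^2/dispersion."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_sc(config: SimConfig, condition_labels: Sequence[Mapping[str, str]]) -> ad.AnnData:
    """Simulate one or more samples of brain single-cell counts.

    ``condition_labels`` holds one mapping per simulated sample with keys
    ``sample``, ``disease``, ``sex``, ``region`` (missing keys default to
    ``unknown``). A planted pair's fold is applied in the cells of samples
    where the pair's condition label equals any of the sample's label values.

    Returns an AnnData (cells x genes) with raw counts in ``X``, metadata in
    ``obs`` (including the ground-truth ``true_cell_type``), and a boolean
    mitochondrial flag ``mt`` in ``var``. Fully reproducible from
    ``config.seed``.
    """
    if not condition_labels:
        raise ValueError("need at least one sample's condition labels")
    rng_universe = np.random.default_rng(config.seed)
    base_M = _type_mean_matrix(config, rng_universe)
    genes = config.gene_universe
    mito = set(config.mito_genes)
    mito_cols = np.array([g in mito for g in genes])

    blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []
    for si, labels in enumerate(condition_labels):
        sample = str(labels.get("sample", f"S{si + 1}"))
        label_values = {str(v) for v in labels.values()}
        rng = np.random.default_rng([int(config.seed), 1000 + si])

        M = base_M.copy()
        for p in config.planted_pairs:
            if p.condition in label_values:
                M.loc[p.sender, p.ligand] *= p.signal_fold
                M.loc[p.receiver, p.receptor] *= p.signal_fold

        for t in config.cell_types:
            n = config.n_cells_per_type
            means = np.tile(M.loc[t].values, (n, 1))
            # designate high-mito cells, then set mito means to hit the target
            # expected mito content f: mito_total = f/(1-f) * non-mito total
            n_high = int(np.ceil(config.mito_high_fraction * n))
            high = np.zeros(n, dtype=bool)
            high[rng.permutation(n)[:n_high]] = True
            non_mito_total = M.loc[t, ~mito_cols].sum()
            for mask, level in ((high, config.mito_high_level), (~high, config.mito_base_level)):
                f = level
                mito_mean = f / (1.0 - f) * non_mito_total / config.n_mito_genes
                means[np.ix_(mask, mito_cols)] = mito_mean
            counts = _nb_draw(rng, means, config.nb_dispersion)
            blocks.append(counts)
            for ci in range(n):
                obs_rows.append({
                    "sample": sample,
                    "disease": str(labels.get("disease", "unknown")),
                    "sex": str(labels.get("sex", "unknown")),
                    "region": str(labels.get("region", "unknown")),
                    "true_cell_type": t,
                    "mito_high": bool(high[ci]),
                })

    X = np.vstack(blocks).astype(np.float64)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"{r['sample']}:C{i + 1:05d}" for i, r in obs.iterrows()]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mt"] = mito_cols
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["normalized"] = False
    adata.uns["dataset_id"] = "SIM"
    return adata


@dataclass
class BulkSimConfig:
    """Parameters of the bulk simulator with planted rank-reversal subtypes."""

    n_normal: int = 20
    n_disease: int = 80
    n_subtypes: int = 4
    edges_per_subtype: int = 10
    rank_shift: float = 4.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_disease < self.n_subtypes:
            raise ValueError("n_disease must be >= n_subtypes")
        if self.edges_per_subtype < 1:
            raise ValueError("edges_per_subtype must be >= 1")
        if self.rank_shift < 0 or self.noise_sd < 0:
            raise ValueError("rank_shift and noise_sd must be nonnegative")


@dataclass
class BulkSim:
    """Output bundle of :func:`simulate_bulk`."""

    expr: pd.DataFrame            # genes x samples, log-scale expression
    labels: pd.Series             # per sample: "normal" / "disease"
    true_subtype: pd.Series       # per disease sample: "subtype1"...
    edges: list[tuple[str, str]]  # all (ligand gene, receptor gene) edges
    subtype_edges: dict[str, list[tuple[str, str]]]


def flatten_edges(pairs: Sequence[LRPair]) -> list[tuple[str, str]]:
    """Expand complexes into all (ligand gene, receptor gene) subunit edges."""
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for p in pairs:
        for lg in p.ligand_units:
            for rg in p.receptor_units:
                if (lg, rg) not in seen:
                    seen.add((lg, rg))
                    edges.append((lg, rg))
    return edges


def make_disjoint_pairs(n: int) -> list[LRPair]:
    """n single-gene pairs over disjoint synthetic gene symbols (for bulk studies)."""
    return [LRPair((f"LG{i + 1:03d}",), (f"RG{i + 1:03d}",)) for i in range(n)]


def simulate_bulk(config: BulkSimConfig, pairs: Sequence[LRPair]) -> BulkSim:
    """Simulate a bulk cohort with planted edge-perturbation subtypes.

    Normal samples share one log-expression profile plus Gaussian noise.
    Disease samples belong to one of ``n_subtypes`` subtypes; each subtype
    inverts the ligand-vs-receptor ordering of its own allocated edge set by
    lowering the ligand and raising the receptor by ``rank_shift``.
    """
    edges = flatten_edges(pairs)
    need = config.n_subtypes * config.edges_per_subtype
    if len(edges) < need:
        raise ValueError(f"need >= {need} edges to allocate {config.edges_per_subtype} "
                         f"per subtype, got {len(edges)}")
    subtype_names = [f"subtype{i + 1}" for i in range(config.n_subtypes)]
    subtype_edges: dict[str, list[tuple[str, str]]] = {}
    used_genes: dict[str, str] = {}
    for i, name in enumerate(subtype_names):
        alloc = edges[i * config.edges_per_subtype:(i + 1) * config.edges_per_subtype]
        for lg, rg in alloc:
            for g in (lg, rg):
                owner = used_genes.get(g)
                if owner is not None and owner != name:
                    raise ValueError(f"overlapping edge allocation: gene {g} in both "
                                     f"{owner} and {name}")
                used_genes[g] = name
        subtype_edges[name] = alloc

    genes: list[str] = []
    for lg, rg in edges:
        for g in (lg, rg):
            if g not in genes:
                genes.append(g)

    rng = np.random.default_rng(config.seed)
    base = pd.Series(rng.uniform(3.0, 8.0, size=len(genes)), index=genes)

    cols: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    truth: dict[str, str] = {}
    for i in range(config.n_normal):
        sid = f"N{i + 1:03d}"
        cols[sid] = base.values + rng.normal(0, config.noise_sd, len(genes))
        labels[sid] = "normal"
    for i in range(config.n_disease):
        sid = f"D{i + 1:03d}"
        st = subtype_names[i % config.n_subtypes]
        mu = base.copy()
        for lg, rg in subtype_edges[st]:
            mu[lg] -= config.rank_shift
            mu[rg] += config.rank_shift
        cols[sid] = mu.values + rng.normal(0, config.noise_sd, len(genes))
        labels[sid] = "disease"
        truth[sid] = st

    expr = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return BulkSim(
        expr=expr,
        labels=pd.Series(labels, name="label"),
        true_subtype=pd.Series(truth, name="subtype"),
        edges=edges,
        subtype_edges=subtype_edges,
    )


# ---------------------------------------------------------------------------
# plain-text writers (MTX-style single-cell bundle, TSV bulk bundle)

def write_sc(adata: ad.AnnData, outdir) -> dict[str, str]:
    """Write counts as MTX + genes.tsv + barcodes.tsv + metadata.tsv."""
    import os

    from scipy import io as spio
    from scipy import sparse

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "matrix": os.path.join(outdir, "matrix.mtx"),
        "genes": os.path.join(outdir, "genes.tsv"),
        "barcodes": os.path.join(outdir, "barcodes.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
    }
    # genes x cells orientation on disk, as in CellRanger-style bundles
    spio.mmwrite(paths["matrix"], sparse.csr_matrix(adata.X.T))
    adata.var.to_csv(paths["genes"], sep="\t")
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    adata.obs.to_csv(paths["metadata"], sep="\t")
    return paths


def read_sc(indir) -> ad.AnnData:
    """Read a bundle written by :func:`write_sc`."""
    import os

    from scipy import io as spio

    X = spio.mmread(os.path.join(indir, "matrix.mtx")).toarray().T.astype(np.float64)
    var = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t", index_col=0)
    var["mt"] = var["mt"].astype(bool)
    obs = pd.read_csv(os.path.join(indir, "metadata.tsv"), sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["normalized"] = False
    return adata


def write_bulk(sim: BulkSim, outdir) -> dict[str, str]:
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "expr": os.path.join(outdir, "bulk_expr.tsv"),
        "labels": os.path.join(outdir, "bulk_labels.tsv"),
        "subtypes": os.path.join(outdir, "bulk_true_subtypes.tsv"),
        "edges": os.path.join(outdir, "edges.tsv"),
    }
    sim.expr.to_csv(paths["expr"], sep="\t")
    sim.labels.rename_axis("sample").to_csv(paths["labels"], sep="\t")
    sim.true_subtype.rename_axis("sample").to_csv(paths["subtypes"], sep="\t")
    pd.DataFrame(sim.edges, columns=["ligand", "receptor"]).to_csv(
        paths["edges"], sep="\t", index=False)
    return paths
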