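"""Single-cell QC, normalization, feature selection, clustering, annotation.

The pipeline mirrors the standard droplet workflow: remove cells with
mitochondrial content above 20% (strict '>'), log-normalize to 10,000
transcripts per cell, select the 2,000 most variable genes by standardized
variance, embed with PCA, build a shared-nearest-neighbor (SNN) Jaccard graph,
partition it by modularity community detection, and assign each cluster the
brain cell type whose markers best overlap the cluster's up-regulated genes
(fallback label: "other cells").
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

OTHER_CELLS = "other cells"

#: cell type -> marker gene symbols
MarkerDB = Mapping[str, Sequence[str]]


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def filter_cells(adata: ad.AnnData, max_mito: float = 0.20) -> ad.AnnData:
    """Remove cells whose mitochondrial count fraction strictly exceeds ``max_mito``.

    Requires raw counts and a boolean ``mt`` column in ``var``. Cells with zero
    total counts are removed as well (their fraction is undefined) and logged.
    Surviving cell order is preserved; the operation is idempotent.
    """
    if adata.uns.get("normalized", False):
        raise ValueError("filter_cells expects raw counts (matrix is normalized)")
    if "mt" not in adata.var:
        raise ValueError("var['mt'] mitochondrial flags are not set")
    X = _dense(adata.X)
    if np.any(X < 0):
        raise ValueError("negative values in count matrix")
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("filter_cells: removing %d zero-count cells", int(zero.sum()))
    mt = adata.var["mt"].values.astype(bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(zero, np.inf, X[:, mt].sum(axis=1) / np.where(zero, 1, totals))
    keep = frac <= max_mito
    out = adata[keep].copy()
    out.obs["pct_mito"] = frac[keep]
    return out


def normalize_log(adata: ad.AnnData, scale_factor: float = 10_000.0) -> ad.AnnData:
    """ln(1 + count / cell_total * scale_factor); raw counts kept in layers['counts'].

    After back-transformation each cell's totals sum to ``scale_factor``
    exactly (up to floating tolerance).
    """
    X = _dense(adata.X)
    if np.any(X < 0):
        raise ValueError("negative values in count matrix")
    totals = X.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("zero-count cell encountered; run filter_cells first")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    out.X = np.log1p(X / totals * scale_factor)
    out.uns["normalized"] = True
    out.uns["scale_factor"] = float(scale_factor)
    return out


def select_hvg(adata: ad.AnnData, n: int = 2000) -> list[str]:
    """Top-``n`` genes by standardized variance (vst-style), ties broken lexicographically.

    Per gene, counts are standardized by the observed mean and an expected
    standard deviation from a quadratic mean-variance trend fitted in
    log10 space, clipped at sqrt(n_cells); genes are ranked by the variance of
    the clipped standardized counts. Uses ``layers['counts']`` when present.
    """
    counts = adata.layers["counts"] if "counts" in adata.layers else _dense(adata.X)
    counts = _dense(counts)
    n_cells, n_genes = counts.shape
    if n > n_genes:
        warnings.warn(f"select_hvg: n={n} > {n_genes} genes; returning all genes")
        return sorted(adata.var_names.tolist())

    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    std_var = np.zeros(n_genes)
    fit_mask = (var > 0) & (mean > 0)
    if fit_mask.sum() >= 3:
        lm, lv = np.log10(mean[fit_mask]), np.log10(var[fit_mask])
        coef = np.polyfit(lm, lv, deg=2)
        exp_sd = np.sqrt(10.0 ** np.polyval(coef, np.log10(mean[fit_mask])))
        z = (counts[:, fit_mask] - mean[fit_mask]) / exp_sd
        z = np.clip(z, None, np.sqrt(n_cells))
        std_var[fit_mask] = z.var(axis=0, ddof=1)
    else:
        std_var[fit_mask] = var[fit_mask]

    order = sorted(range(n_genes), key=lambda i: (-std_var[i], adata.var_names[i]))
    return [adata.var_names[i] for i in order[:n]]


def _snn_graph(pcs: np.ndarray, k_neighbors: int, prune: float) -> sparse.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph on a PC embedding."""
    n = pcs.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    # neighbor sets include self, as in the Seurat SNN construction
    rows = np.repeat(np.arange(n), idx.shape[1])
    A = sparse.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n), dtype=np.float64
    )
    shared = (A @ A.T).toarray()
    ksize = idx.shape[1]
    union = 2 * ksize - shared
    with np.errstate(divide="ignore", invalid="ignore"):
        jacc = shared / union
    jacc[jacc < prune] = 0.0
    np.fill_diagonal(jacc, 0.0)
    return sparse.csr_matrix(jacc)


def embed_cluster(
    adata: ad.AnnData,
    n_pcs: int = 20,
    k_neighbors: int = 15,
    resolution: float = 0.8,
    hvgs: Sequence[str] | None = None,
    prune: float = 1.0 / 15.0,
    seed: int = 0,
) -> np.ndarray:
    """PCA -> SNN graph -> modularity community detection; labels written to obs['cluster'].

    Labels are contiguous integers from 0, ordered by decreasing cluster size.
    """
    X = _dense(adata.X)
    if hvgs is not None:
        cols = adata.var_names.get_indexer(list(hvgs))
        if np.any(cols < 0):
            raise ValueError("hvgs contains genes absent from the matrix")
        X = X[:, cols]
    n_cells, n_genes = X.shape
    if n_pcs >= min(n_cells, n_genes):
        raise ValueError(f"n_pcs={n_pcs} must be < min(cells, genes) = {min(n_cells, n_genes)}")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -10, 10)
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(Z)

    snn = _snn_graph(pcs, k_neighbors, prune)
    src, dst = snn.nonzero()
    keep = src < dst
    g = igraph.Graph(
        n=n_cells,
        edges=list(zip(src[keep].tolist(), dst[keep].tolist())),
        edge_attrs={"weight": np.asarray(snn[src[keep], dst[keep]]).ravel().tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # relabel by decreasing size (ties: first occurrence)
    sizes = pd.Series(raw).value_counts()
    first_pos = {c: int(np.argmax(raw == c)) for c in sizes.index}
    order = sorted(sizes.index, key=lambda c: (-sizes[c], first_pos[c]))
    remap = {c: i for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    adata.obs["cluster"] = pd.Categorical(labels)
    return labels


def rank_markers(
    X_in: np.ndarray, X_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene Wilcoxon rank-sum p (cluster vs rest) and Seurat-style ln fold change."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(X_in, X_out, axis=0, alternative="two-sided")
    lfc = np.log((np.expm1(X_in).mean(axis=0) + 1.0) / (np.expm1(X_out).mean(axis=0) + 1.0))
    return np.asarray(res.pvalue), lfc


def annotate_clusters(
    adata: ad.AnnData,
    markers: MarkerDB,
    min_lfc: float = 0.25,
    alpha: float = 0.05,
    cluster_key: str = "cluster",
) -> dict[int, str]:
    """Assign a cell type to every cluster by marker-gene overlap.

    Candidate markers of a cluster are genes with Wilcoxon p < ``alpha``
    (cluster vs rest) and ln fold change > ``min_lfc``. The cluster gets the
    type with the largest overlap between candidates and the type's marker
    list; ties go to the larger mean fold change of the overlapping markers;
    zero overlap everywhere gives "other cells". Writes obs['cell_type'].
    """
    if cluster_key not in adata.obs:
        raise ValueError("run embed_cluster first (no cluster labels)")
    X = _dense(adata.X)
    clusters = np.asarray(adata.obs[cluster_key])
    assignment: dict[int, str] = {}
    var_names = np.asarray(adata.var_names)
    for c in sorted(pd.unique(clusters)):
        mask = clusters == c
        if mask.sum() == 0:
            raise ValueError(f"empty cluster {c}")
        if (~mask).sum() == 0:
            # single-cluster dataset: every gene trivially 'candidate' by fold change
            pvals = np.zeros(X.shape[1])
            lfc = np.full(X.shape[1], np.inf)
        else:
            pvals, lfc = rank_markers(X[mask], X[~mask])
        cand = set(var_names[(pvals < alpha) & (lfc > min_lfc)])
        lfc_by_gene = dict(zip(var_names, lfc))
        best_type, best_key = OTHER_CELLS, (0, -np.inf)
        for cell_type, marker_genes in markers.items():
            overlap = cand.intersection(marker_genes)
            if not overlap:
                continue
            key = (len(overlap), float(np.mean([lfc_by_gene[g] for g in overlap])))
            if key > best_key:
                best_key, best_type = key, cell_type
        assignment[int(c)] = best_type
    adata.obs["cell_type"] = pd.Categorical(
        [assignment[int(c)] for c in clusters]
    )
    return assignment
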