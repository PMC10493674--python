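"""Edge-perturbation subtyping of disease samples.

Procedure: (i) within each sample, convert expression of the edge genes to
ascending ranks (ties -> average ranks); (ii) score each ligand-receptor edge
as rank(ligand) - rank(receptor); (iii) build a normal reference edge vector
from a single ranking of the mean expression over normal samples; (iv) the
perturbation matrix is the disease edge matrix minus the reference, so a
disease sample whose ranking equals the reference has an all-zero column.
Because only ranks enter, the whole pipeline is invariant to any strictly
increasing per-sample transform of expression.

Disease samples are then partitioned by consensus clustering: 80% of samples
and 80% of edges are subsampled per repetition, PAM (k-medoids, Euclidean)
clusters each subsample for each K, and the consensus matrix records how often
two samples co-cluster when co-sampled. K is chosen from the relative change
in area under the consensus-CDF curve (delta area), and final labels come from
PAM on 1 - consensus at the chosen K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def rank_transform(expr: pd.DataFrame, gene_subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sample (column) ascending ranks 1..G with average ranks for ties."""
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in expr.index]
        if missing:
            raise ValueError(f"genes missing from expression matrix: {missing[:5]}")
        expr = expr.loc[list(dict.fromkeys(gene_subset))]
    ranks = stats.rankdata(expr.values, axis=0, method="average")
    return pd.DataFrame(ranks, index=expr.index, columns=expr.columns)


def edge_matrix(ranks: pd.DataFrame, edges: Sequence[Edge]) -> pd.DataFrame:
    """value(edge, sample) = rank(ligand) - rank(receptor)."""
    for lg, rg in edges:
        for g in (lg, rg):
            if g not in ranks.index:
                raise ValueError(f"edge gene {g} missing from rank matrix")
    lig = ranks.loc[[e[0] for e in edges]].values
    rec = ranks.loc[[e[1] for e in edges]].values
    idx = pd.Index([f"{lg}_{rg}" for lg, rg in edges], name="edge")
    return pd.DataFrame(lig - rec, index=idx, columns=ranks.columns)


def reference_edges(normal_expr: pd.DataFrame, edges: Sequence[Edge]) -> pd.Series:
    """Edge values from one ranking of genes by their mean over normal samples."""
    if normal_expr.shape[1] == 0:
        raise ValueError("need at least one normal sample")
    mean = normal_expr.mean(axis=1).to_frame("reference")
    ranks = rank_transform(mean)
    return edge_matrix(ranks, edges)["reference"]


def perturbation(disease_edges: pd.DataFrame, reference: pd.Series) -> pd.DataFrame:
    """Column-wise subtraction of the normal reference edge vector."""
    if not disease_edges.index.equals(reference.index):
        raise ValueError("edge universe mismatch between disease matrix and reference")
    return disease_edges.sub(reference, axis=0)


# ---------------------------------------------------------------------------
# PAM (k-medoids, BUILD + best-improvement SWAP) on a precomputed distance matrix

def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))
        medoids.append(h)
        d_near = np.minimum(d_near, D[h])
    return medoids


def pam(
    D: np.ndarray,
    k: int,
    max_iter: int = 200,
    n_restarts: int = 4,
    restart_seed: int = 0,
) -> tuple[np.ndarray, list[int], float]:
    """Partitioning Around Medoids on distance matrix ``D``.

    BUILD initialization plus best-improvement SWAP descent; because SWAP can
    terminate in a local optimum, the descent is repeated from ``n_restarts``
    deterministic random medoid sets and the lowest-cost solution wins.
    Returns (labels in 0..k-1 by medoid order, medoid indices, total cost).
    Fully deterministic: ties break toward the lowest index.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for n={n}")
    starts = [_pam_build(D, k)]
    rng = np.random.default_rng(restart_seed)
    for _ in range(n_restarts):
        starts.append(sorted(rng.choice(n, size=k, replace=False).tolist()))

    best: tuple[float, list[int]] | None = None
    for start in starts:
        medoids = _pam_swap(D, k, list(start), max_iter)
        cost = float(D[medoids].min(axis=0).sum())
        if best is None or cost < best[0] - 1e-12:
            best = (cost, medoids)
    cost, medoids = best
    labels = np.argmin(D[medoids], axis=0)
    return labels, medoids, cost


def _pam_swap(D: np.ndarray, k: int, medoids: list[int], max_iter: int) -> list[int]:
    n = D.shape[0]
    for _ in range(max_iter):
        Dm = D[medoids]                     # k x n
        nearest = np.argmin(Dm, axis=0)     # index into medoid list
        order = np.argsort(Dm, axis=0)
        d1 = Dm[order[0], np.arange(n)]
        d2 = Dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)

        best_delta, best_swap = -1e-12, None
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        Dh = D[non_medoids]                 # h x n
        for mi in range(k):
            owned = nearest == mi
            # points owned by m: fall back to 2nd-nearest or to h
            gain_owned = (np.minimum(Dh[:, owned], d2[owned]) - d1[owned]).sum(axis=1)
            # other points: may defect to h
            other = ~owned
            gain_other = np.minimum(Dh[:, other] - d1[other], 0.0).sum(axis=1)
            delta = gain_owned + gain_other
            j = int(np.argmin(delta))
            if delta[j] < best_delta:
                best_delta = float(delta[j])
                best_swap = (mi, int(non_medoids[j]))
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    return sorted(medoids)


def pam_exhaustive_cost(D: np.ndarray, k: int) -> float:
    """Global optimum assignment cost over all medoid subsets (oracle for tiny n)."""
    from itertools import combinations

    D = np.asarray(D, dtype=float)
    return min(D[list(c)].min(axis=0).sum() for c in combinations(range(D.shape[0]), k))


# ---------------------------------------------------------------------------
# consensus clustering

@dataclass
class ConsensusResult:
    """Per-K consensus matrices, CDF areas, delta areas, chosen K and labels."""

    k_range: list[int]
    consensus: dict[int, pd.DataFrame]
    areas: dict[int, float] = field(default_factory=dict)
    deltas: dict[int, float] = field(default_factory=dict)
    chosen_k: int = 0
    labels: pd.Series | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"K": self.k_range,
             "cdf_area": [self.areas[k] for k in self.k_range],
             "delta_area": [self.deltas[k] for k in self.k_range]}
        ).set_index("K")


def _cdf_area(consensus: np.ndarray, grid_points: int = 101) -> float:
    """Trapezoid area under the empirical CDF of off-diagonal consensus values."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    grid = np.linspace(0.0, 1.0, grid_points)
    cdf = np.searchsorted(vals, grid, side="right") / vals.size
    return float(np.trapezoid(cdf, grid))


def consensus_cluster(
    P: pd.DataFrame,
    k_range: Sequence[int] = range(2, 7),
    reps: int = 1000,
    p_sample: float = 0.8,
    p_feature: float = 0.8,
    seed: int = 0,
    delta_floor: float = 0.1,
) -> ConsensusResult:
    """Subsampled PAM consensus clustering of perturbation columns (samples).

    ``P`` is edges x samples. Per repetition, floor(p_sample * n) samples and
    floor(p_feature * n_edges) edges are drawn without replacement; PAM with
    Euclidean distance clusters the subsample at each K. consensus(i, j) =
    co-cluster count / co-sampled count. Delta(2) = A(2) and
    Delta(K) = (A(K) - A(K-1)) / A(K-1); the chosen K is the largest K whose
    delta area stays above ``delta_floor`` (the point where the area gain has
    not yet slowed down), defaulting to the smallest K if none qualifies.
    """
    k_range = sorted(k_range)
    samples = P.columns
    n = len(samples)
    if n < max(k_range) + 1:
        raise ValueError(f"need >= {max(k_range) + 1} samples, got {n}")
    X = P.values.T.astype(float)  # samples x edges
    n_edges = X.shape[1]
    ns = max(2, int(np.floor(p_sample * n)))
    nf = max(1, int(np.floor(p_feature * n_edges)))

    consensus: dict[int, pd.DataFrame] = {}
    for k in k_range:
        co = np.zeros((n, n))
        cnt = np.zeros((n, n))
        for rep in range(reps):
            rng = np.random.default_rng([seed, k, rep])
            s_idx = np.sort(rng.choice(n, size=ns, replace=False))
            f_idx = rng.choice(n_edges, size=nf, replace=False)
            D = squareform(pdist(X[np.ix_(s_idx, f_idx)], metric="euclidean"))
            labels, _, _ = pam(D, k)
            eq = (labels[:, None] == labels[None, :]).astype(float)
            co[np.ix_(s_idx, s_idx)] += eq
            cnt[np.ix_(s_idx, s_idx)] += 1.0
        off = ~np.eye(n, dtype=bool)
        if np.any(cnt[off] == 0):
            raise ValueError("some sample pair was never co-sampled; raise reps")
        M = np.divide(co, cnt, out=np.zeros_like(co), where=cnt > 0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = pd.DataFrame(M, index=samples, columns=samples)

    result = ConsensusResult(k_range=list(k_range), consensus=consensus)
    prev_area = None
    for k in k_range:
        a = _cdf_area(consensus[k].values)
        result.areas[k] = a
        result.deltas[k] = a if prev_area is None else (a - prev_area) / prev_area
        prev_area = a

    qualified = [k for k in k_range if result.deltas[k] > delta_floor]
    result.chosen_k = max(qualified) if qualified else k_range[0]

    final_D = 1.0 - consensus[result.chosen_k].values
    labels, _, _ = pam(final_D, result.chosen_k)
    result.labels = pd.Series(labels, index=samples, name="subtype")
    return result


def subtype_pipeline(
    expr: pd.DataFrame,
    labels: pd.Series,
    edges: Sequence[Edge],
    disease_label: str = "disease",
    normal_label: str = "normal",
    **consensus_kwargs,
) -> tuple[pd.DataFrame, ConsensusResult]:
    """Rank -> edge -> perturbation -> consensus clustering, end to end."""
    genes = sorted({g for e in edges for g in e})
    disease_cols = labels.index[labels == disease_label]
    normal_cols = labels.index[labels == normal_label]
    ranks = rank_transform(expr[disease_cols], genes)
    dis_edges = edge_matrix(ranks, edges)
    ref = reference_edges(expr.loc[genes, normal_cols], edges)
    pert = perturbation(dis_edges, ref)
    return pert, consensus_cluster(pert, **consensus_kwargs)
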