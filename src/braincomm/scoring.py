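"""Four ligand-receptor scoring schemes over (pair, sender type, receiver type).

Each scheme represents one family of published communication scorers:

``hill``
    Mass-action score with half-saturation: score = l*r / (0.5 + l*r), where
    l and r are Tukey trimeans of ligand/receptor expression in the sender and
    receiver type (robust location, saturating response).
``regularized``
    sqrt(l*r) / (mu + sqrt(l*r)) with l, r mean expression and mu the global
    mean of the normalized matrix (regularized product).
``product``
    Product of per-gene expression min-max scaled to [0, 10] across cell
    types, so scores live in [0, 100] and reward type-specific expression.
``gated``
    Plain product of means, emitted only when the ligand (receptor) passes an
    expression gate in the sender (receiver): detection fraction >= 10% and a
    type mean above the gene's across-type mean. Absent entries are distinct
    from zero scores and are zero-imputed downstream.

Complexes are aggregated with the geometric mean (see
:func:`braincomm.resources.complex_expression`), so every scheme propagates a
zero subunit to a zero/absent score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .preprocess import OTHER_CELLS
from .resources import LRPair

logger = logging.getLogger(__name__)

METHODS = ("hill", "regularized", "product", "gated")

KEY_NAMES = ["pair_id", "sender", "receiver"]


def tukey_trimean(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """(Q1 + 2*median + Q3) / 4 with linear-interpolation quartiles."""
    q1, q2, q3 = np.percentile(values, [25, 50, 75], axis=axis, method="linear")
    return (q1 + 2.0 * q2 + q3) / 4.0


@dataclass
class CellTypeProfile:
    """Per (cell type, gene) summaries of one annotated, normalized sub-dataset."""

    mean: pd.DataFrame      # types x genes, mean normalized expression
    trimean: pd.DataFrame   # types x genes, Tukey trimean
    detect: pd.DataFrame    # types x genes, fraction of cells with count > 0
    n_cells: pd.Series      # per type
    mu: float               # global mean of the normalized matrix

    @property
    def cell_types(self) -> list[str]:
        return self.mean.index.tolist()


@dataclass
class MethodScoreTable:
    """Raw (or normalized) scores of one method in one sub-dataset.

    ``scores`` is a float Series indexed by (pair_id, sender, receiver);
    keys missing from the index are *absent*, which is distinct from a 0.0.
    """

    method: str
    scores: pd.Series
    subdataset_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.scores) and self.scores.index.has_duplicates:
            raise ValueError("duplicate (pair, sender, receiver) keys")
        if len(self.scores) and (self.scores < 0).any():
            raise ValueError("negative scores")
        self.scores = self.scores.astype(float)
        self.scores.index.names = KEY_NAMES

    def to_frame(self) -> pd.DataFrame:
        df = self.scores.rename("raw_score").reset_index()
        df.insert(0, "method", self.method)
        df["subdataset_id"] = self.subdataset_id
        return df


def build_profiles(adata: ad.AnnData, min_cells: int = 3) -> CellTypeProfile:
    """Summarize an annotated, normalized matrix per cell type.

    "other cells" are excluded from scoring; types with fewer than
    ``min_cells`` cells are excluded with a warning.
    """
    if not adata.uns.get("normalized", False):
        raise ValueError("build_profiles expects a normalized matrix")
    if "cell_type" not in adata.obs:
        raise ValueError("matrix is not annotated (no obs['cell_type'])")
    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
    cell_types = [t for t in pd.unique(adata.obs["cell_type"]) if t != OTHER_CELLS]

    rows_mean, rows_tri, rows_det, ns, kept = [], [], [], [], []
    global_mask = np.zeros(adata.n_obs, dtype=bool)
    for t in cell_types:
        mask = (adata.obs["cell_type"] == t).values
        n = int(mask.sum())
        if n < min_cells:
            logger.warning("build_profiles: excluding type %r with %d < %d cells", t, n, min_cells)
            continue
        kept.append(t)
        ns.append(n)
        global_mask |= mask
        sub = X[mask]
        rows_mean.append(sub.mean(axis=0))
        rows_tri.append(tukey_trimean(sub, axis=0))
        rows_det.append((sub > 0).mean(axis=0))
    if not kept:
        raise ValueError("no cell type with enough cells to profile")
    genes = adata.var_names
    return CellTypeProfile(
        mean=pd.DataFrame(rows_mean, index=kept, columns=genes),
        trimean=pd.DataFrame(rows_tri, index=kept, columns=genes),
        detect=pd.DataFrame(rows_det, index=kept, columns=genes),
        n_cells=pd.Series(ns, index=kept),
        mu=float(X[global_mask].mean()),
    )


def _usable_pairs(profile: CellTypeProfile, pairs: Sequence[LRPair]) -> list[LRPair]:
    genes = set(profile.mean.columns)
    usable, dropped = [], 0
    for p in pairs:
        if all(g in genes for g in p.genes):
            usable.append(p)
        else:
            dropped += 1
    if dropped:
        logger.warning("%d/%d pairs dropped: subunit gene absent from matrix", dropped, len(pairs))
    return usable


def _complex_stat(stat: pd.DataFrame, units: Sequence[str]) -> np.ndarray:
    """Geometric mean of subunit rows of a (types x genes) stat table -> per-type vector."""
    vals = stat[list(units)].values  # types x units
    if vals.shape[1] == 1:
        return vals[:, 0].copy()
    with np.errstate(divide="ignore"):
        logs = np.log(vals, where=vals > 0, out=np.full_like(vals, -np.inf))
    out = np.exp(logs.mean(axis=1))
    out[np.any(vals == 0, axis=1)] = 0.0
    return out


def _table(method: str, entries: dict, subdataset_id: str) -> MethodScoreTable:
    if entries:
        idx = pd.MultiIndex.from_tuples(entries.keys(), names=KEY_NAMES)
        scores = pd.Series(list(entries.values()), index=idx, dtype=float)
    else:
        scores = pd.Series(
            [], index=pd.MultiIndex.from_arrays([[], [], []], names=KEY_NAMES), dtype=float
        )
    return MethodScoreTable(method=method, scores=scores, subdataset_id=subdataset_id)


def score_hill(profile: CellTypeProfile, pairs: Sequence[LRPair],
               subdataset_id: str = "") -> MethodScoreTable:
    """Trimean-based mass-action score with half-saturation constant 0.5."""
    entries: dict = {}
    types = profile.cell_types
    for p in _usable_pairs(profile, pairs):
        l_vec = _complex_stat(profile.trimean, p.ligand_units)
        r_vec = _complex_stat(profile.trimean, p.receptor_units)
        for si, s in enumerate(types):
            for ri, r in enumerate(types):
                lr = l_vec[si] * r_vec[ri]
                entries[(p.pair_id, s, r)] = lr / (0.5 + lr)
    return _table("hill", entries, subdataset_id)


def score_regularized(profile: CellTypeProfile, pairs: Sequence[LRPair],
                      subdataset_id: str = "") -> MethodScoreTable:
    """sqrt(l*r) / (mu + sqrt(l*r)) on mean expression, mu = global matrix mean."""
    if profile.mu == 0:
        raise ValueError("global mean is zero (all-zero matrix)")
    entries: dict = {}
    types = profile.cell_types
    for p in _usable_pairs(profile, pairs):
        l_vec = _complex_stat(profile.mean, p.ligand_units)
        r_vec = _complex_stat(profile.mean, p.receptor_units)
        for si, s in enumerate(types):
            for ri, r in enumerate(types):
                root = np.sqrt(l_vec[si] * r_vec[ri])
                entries[(p.pair_id, s, r)] = root / (profile.mu + root)
    return _table("regularized", entries, subdataset_id)


def score_product(profile: CellTypeProfile, pairs: Sequence[LRPair],
                  subdataset_id: str = "") -> MethodScoreTable:
    """Product of per-gene [0,10] min-max-scaled expression across cell types."""
    m = profile.mean
    lo, hi = m.min(axis=0), m.max(axis=0)
    span = hi - lo
    scaled = pd.DataFrame(0.0, index=m.index, columns=m.columns)
    ok = span > 0
    scaled.loc[:, ok] = (10.0 * (m.loc[:, ok] - lo[ok]) / span[ok]).clip(0.0, 10.0)
    # degenerate genes: constant nonzero -> 10, constant zero -> 0
    const_nonzero = (~ok) & (hi > 0)
    scaled.loc[:, const_nonzero] = 10.0

    entries: dict = {}
    types = profile.cell_types
    for p in _usable_pairs(profile, pairs):
        l_vec = _complex_stat(scaled, p.ligand_units)
        r_vec = _complex_stat(scaled, p.receptor_units)
        for si, s in enumerate(types):
            for ri, r in enumerate(types):
                entries[(p.pair_id, s, r)] = l_vec[si] * r_vec[ri]
    return _table("product", entries, subdataset_id)


def score_gated(profile: CellTypeProfile, pairs: Sequence[LRPair],
                subdataset_id: str = "", min_detect: float = 0.10) -> MethodScoreTable:
    """Mean-expression product gated on detection and type-enriched expression.

    A gene passes in a type iff its detection fraction there is >= ``min_detect``
    and its mean in that type exceeds its across-type mean; for complexes every
    subunit must pass. Failing keys are absent (no entry), not zero.
    """
    entries: dict = {}
    types = profile.cell_types
    across = profile.mean.mean(axis=0)  # per-gene unweighted mean over types
    passes = (profile.detect >= min_detect) & profile.mean.gt(across, axis=1)
    for p in _usable_pairs(profile, pairs):
        l_vec = _complex_stat(profile.mean, p.ligand_units)
        r_vec = _complex_stat(profile.mean, p.receptor_units)
        l_pass = passes[list(p.ligand_units)].all(axis=1).values
        r_pass = passes[list(p.receptor_units)].all(axis=1).values
        for si, s in enumerate(types):
            if not l_pass[si]:
                continue
            for ri, r in enumerate(types):
                if not r_pass[ri]:
                    continue
                entries[(p.pair_id, s, r)] = l_vec[si] * r_vec[ri]
    return _table("gated", entries, subdataset_id)


def score_all(adata: ad.AnnData, pairs: Sequence[LRPair],
              subdataset_id: str = "", min_cells: int = 3) -> dict[str, MethodScoreTable]:
    """Run all four scorers on one annotated sub-dataset."""
    profile = build_profiles(adata, min_cells=min_cells)
    return {
        "hill": score_hill(profile, pairs, subdataset_id),
        "regularized": score_regularized(profile, pairs, subdataset_id),
        "product": score_product(profile, pairs, subdataset_id),
        "gated": score_gated(profile, pairs, subdataset_id),
    }
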