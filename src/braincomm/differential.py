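"""Condition-specific communication calling: Wilcoxon rank-sum + log2 ratio.

For every (pair, sender, receiver) key surviving all-zero pruning, the
ISIscore is compared between two condition groups (e.g. AD vs normal) with a
two-sided Wilcoxon rank-sum test (exact when both groups have <= 25
observations and no pooled ties, normal approximation with continuity
correction otherwise). A key is called condition-specific when p < 0.05 and
|log2((mean_A + eps) / (mean_B + eps))| > 3 with eps = 1e-3 — both strict
inequalities.

Sampling unit: when both groups contain >= 3 sub-datasets, the Wilcoxon
samples are the per-sub-dataset ISIscores. With fewer sub-datasets (the paper's
single AD vs single normal comparison), a rank-sum test on one score per side
is impossible, so the test falls back to per-cell ligand x receptor expression
products over sender/receiver cells, quantile-matched to a common length.
"""

from __future__ import annotations

import logging
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .integration import ISITable, prune_all_zero
from .resources import LRPair
from .scoring import KEY_NAMES

logger = logging.getLogger(__name__)

EPSILON = 1e-3

CALL_A = "A-specific"
CALL_B = "B-specific"
CALL_NONE = "not-specific"


def wilcoxon_ranksum(a: np.ndarray, b: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both samples have <= ``exact_max_n``
    observations (ties enter through average ranks; the exact distribution
    carries no tie correction); otherwise the normal approximation with tie
    and continuity corrections.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    method = "exact" if max(len(a), len(b)) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def _percell_products(
    tables: Sequence[ISITable],
    cells: Sequence[ad.AnnData],
    pair: LRPair,
    sender: str,
    receiver: str,
    max_quantiles: int = 200,
) -> np.ndarray:
    """Per-cell fallback samples: quantile-matched ligand x receptor products."""
    out: list[np.ndarray] = []
    for adata in cells:
        genes = adata.var_names
        if any(g not in genes for g in pair.genes):
            continue
        X = np.asarray(adata.X)
        sender_mask = (adata.obs["cell_type"] == sender).values
        receiver_mask = (adata.obs["cell_type"] == receiver).values
        if sender_mask.sum() == 0 or receiver_mask.sum() == 0:
            continue

        def complex_per_cell(mask: np.ndarray, units: tuple[str, ...]) -> np.ndarray:
            vals = X[np.ix_(mask, genes.get_indexer(list(units)))]
            with np.errstate(divide="ignore"):
                logs = np.log(vals, where=vals > 0, out=np.full_like(vals, -np.inf))
            v = np.exp(logs.mean(axis=1))
            v[np.any(vals == 0, axis=1)] = 0.0
            return v

        lig = complex_per_cell(sender_mask, pair.ligand_units)
        rec = complex_per_cell(receiver_mask, pair.receptor_units)
        m = min(len(lig), len(rec), max_quantiles)
        qs = (np.arange(m) + 0.5) / m
        out.append(np.quantile(lig, qs) * np.quantile(rec, qs))
    if not out:
        raise ValueError(f"no cells available for fallback test of {pair.pair_id} "
                         f"({sender} -> {receiver})")
    return np.concatenate(out)


def compare_conditions(
    group_a: Sequence[ISITable],
    group_b: Sequence[ISITable],
    cells_a: Sequence[ad.AnnData] | None = None,
    cells_b: Sequence[ad.AnnData] | None = None,
    min_subdatasets: int = 3,
) -> pd.DataFrame:
    """Test every pruned key for an ISIscore difference between two groups.

    Returns a frame indexed by (pair_id, sender, receiver) with columns
    mean_a, mean_b, p, p_bh, log2_ratio, sampling_unit.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("each group needs at least one sub-dataset")
    pruned, kept = prune_all_zero(list(group_a) + list(group_b))
    pa, pb = pruned[: len(group_a)], pruned[len(group_a):]

    use_subdataset = len(group_a) >= min_subdatasets and len(group_b) >= min_subdatasets
    if not use_subdataset and (cells_a is None or cells_b is None):
        raise ValueError(
            "fewer than 3 sub-datasets per group: per-cell fallback requires "
            "cells_a and cells_b"
        )

    rows = []
    for key in kept:
        vec_a = np.array([t.df["isiscore"].get(key, 0.0) for t in pa])
        vec_b = np.array([t.df["isiscore"].get(key, 0.0) for t in pb])
        mean_a, mean_b = float(vec_a.mean()), float(vec_b.mean())
        if use_subdataset:
            p = wilcoxon_ranksum(vec_a, vec_b)
            unit = "subdataset"
        else:
            pair = LRPair.from_pair_id(key[0])
            sa = _percell_products(pa, cells_a, pair, key[1], key[2])
            sb = _percell_products(pb, cells_b, pair, key[1], key[2])
            p = wilcoxon_ranksum(sa, sb)
            unit = "cell"
        rows.append((*key, mean_a, mean_b, p,
                     float(np.log2((mean_a + EPSILON) / (mean_b + EPSILON))), unit))

    df = pd.DataFrame(
        rows, columns=KEY_NAMES + ["mean_a", "mean_b", "p", "log2_ratio", "sampling_unit"]
    ).set_index(KEY_NAMES)
    # BH-adjusted column is reported alongside but does not drive the calls
    df["p_bh"] = multipletests(df["p"].values, method="fdr_bh")[1] if len(df) else []
    return df[["mean_a", "mean_b", "p", "p_bh", "log2_ratio", "sampling_unit"]]


def call_specific(
    diff: pd.DataFrame, alpha: float = 0.05, log2_cut: float = 3.0
) -> pd.DataFrame:
    """Add the specificity call (strict inequalities on both criteria)."""
    out = diff.copy()
    sig = out["p"] < alpha
    out["call"] = CALL_NONE
    out.loc[sig & (out["log2_ratio"] > log2_cut), "call"] = CALL_A
    out.loc[sig & (out["log2_ratio"] < -log2_cut), "call"] = CALL_B
    return out


def collect_marker_genes(pair_ids: Sequence[str]) -> list[str]:
    """Unique, sorted gene symbols over all ligand and receptor subunits."""
    genes: set[str] = set()
    for pid in pair_ids:
        genes.update(LRPair.from_pair_id(pid).genes)
    return sorted(genes)
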