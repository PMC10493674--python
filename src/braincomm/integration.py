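"""ISIscore: per-method [0,1] normalization, zero imputation, and averaging.

For one sub-dataset, each method's raw scores are min-max normalized over that
method's present entries; the four normalized tables are joined on the union of
(pair, sender, receiver) keys with 0 imputed for method-absent entries; the
ISIscore is the arithmetic mean of the four components. Keys whose ISIscore is
zero in every sub-dataset of a comparison are pruned before testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import KEY_NAMES, METHODS, MethodScoreTable

logger = logging.getLogger(__name__)

COMPONENT_COLUMNS = [f"comp_{m}" for m in METHODS]


@dataclass
class ISITable:
    """Integrated scores of one sub-dataset.

    ``df`` is indexed by (pair_id, sender, receiver) with columns ``isiscore``
    and the four normalized components ``comp_hill`` ... ``comp_gated``.
    """

    subdataset_id: str
    df: pd.DataFrame
    labels: Mapping[str, str] = field(default_factory=dict)

    @property
    def isiscore(self) -> pd.Series:
        return self.df["isiscore"]

    def to_frame(self) -> pd.DataFrame:
        out = self.df.reset_index()
        out.insert(0, "subdataset_id", self.subdataset_id)
        for k in ("disease", "sex", "region"):
            out[k] = self.labels.get(k, "unknown")
        return out


def normalize_scores(table: MethodScoreTable) -> MethodScoreTable:
    """Min-max normalize one method's present entries to [0, 1].

    Degenerate cases: all present entries equal and positive -> 1; all equal
    zero -> 0. Absent entries stay absent.
    """
    s = table.scores
    if len(s) == 0:
        warnings.warn(f"normalize_scores: empty {table.method} table")
        norm = s.copy()
    else:
        lo, hi = float(s.min()), float(s.max())
        if hi > lo:
            norm = (s - lo) / (hi - lo)
        elif hi > 0:
            norm = pd.Series(1.0, index=s.index)
        else:
            norm = pd.Series(0.0, index=s.index)
    return MethodScoreTable(
        method=table.method, scores=norm, subdataset_id=table.subdataset_id, normalized=True
    )


def compute_isiscore(
    tables: Sequence[MethodScoreTable] | Mapping[str, MethodScoreTable],
    subdataset_id: str | None = None,
    labels: Mapping[str, str] | None = None,
) -> ISITable:
    """Join four normalized method tables into an ISITable.

    Missing components are imputed as 0; the ISIscore is their exact mean.
    Keys absent from all four methods do not appear at all.
    """
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    if len(tables) != 4 or sorted(t.method for t in tables) != sorted(METHODS):
        raise ValueError(f"need exactly one table per method {METHODS}")
    sub_ids = {t.subdataset_id for t in tables if t.subdataset_id}
    if len(sub_ids) > 1:
        raise ValueError(f"tables from different sub-datasets: {sorted(sub_ids)}")
    if subdataset_id is None:
        subdataset_id = next(iter(sub_ids), "")

    by_method = {t.method: t for t in tables}
    for m, t in by_method.items():
        if not t.normalized:
            by_method[m] = normalize_scores(t)
        if len(by_method[m].scores) and not (
            (by_method[m].scores >= 0) & (by_method[m].scores <= 1)
        ).all():
            raise ValueError(f"method {m}: normalized scores outside [0, 1]")

    df = pd.concat(
        {f"comp_{m}": by_method[m].scores for m in METHODS}, axis=1, join="outer"
    ).fillna(0.0)
    df.index.names = KEY_NAMES
    df["isiscore"] = df[COMPONENT_COLUMNS].mean(axis=1)
    df = df[["isiscore"] + COMPONENT_COLUMNS].sort_index()
    return ISITable(subdataset_id=subdataset_id, df=df, labels=dict(labels or {}))


def prune_all_zero(tables: Sequence[ISITable]) -> tuple[list[ISITable], pd.Index]:
    """Keep only keys with ISIscore > 0 in at least one table."""
    if not tables:
        raise ValueError("empty table list")
    kept: pd.Index | None = None
    for t in tables:
        nz = t.df.index[t.df["isiscore"] > 0]
        kept = nz if kept is None else kept.union(nz)
    pruned = [
        ISITable(t.subdataset_id, t.df.loc[t.df.index.intersection(kept)].sort_index(), t.labels)
        for t in tables
    ]
    return pruned, kept.sort_values()


def summarize_communication(
    table: ISITable, cell_types: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per (sender, receiver): sum of ISIscore and count of nonzero pairs.

    With the six brain types this is the 6x6 = 36-cell communication summary.
    """
    df = table.df.reset_index()
    if cell_types is None:
        cell_types = sorted(set(df["sender"]).union(df["receiver"]))
    grouped = df.groupby(["sender", "receiver"], observed=True)["isiscore"]
    sums = grouped.sum()
    counts = df[df["isiscore"] > 0].groupby(["sender", "receiver"], observed=True).size()
    idx = pd.MultiIndex.from_product([cell_types, cell_types], names=["sender", "receiver"])
    out = pd.DataFrame(index=idx)
    out["isiscore_sum"] = sums.reindex(idx).fillna(0.0)
    out["n_pairs"] = counts.reindex(idx).fillna(0).astype(int)
    return out
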