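"""Ligand-receptor pair universe: parsing, complexes, ortholog mapping.

A ligand-receptor interaction is written ``LIGAND_RECEPTOR`` where either side
may be a multi-subunit complex joined by ``+`` (e.g. ``BMP7_BMPR1A+ACVR2A``:
the ligand BMP7 binding the heterodimeric type-I/type-II BMP receptor).
Complex expression is summarized by the geometric mean of its subunits, so a
missing subunit abolishes the complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

COMPLEX_SEP = "+"
PAIR_SEP = "_"


@dataclass(frozen=True)
class LRPair:
    """One ligand-receptor interaction; each side is >=1 gene symbol."""

    ligand_units: tuple[str, ...]
    receptor_units: tuple[str, ...]

    def __post_init__(self) -> None:
        for side, units in (("ligand", self.ligand_units), ("receptor", self.receptor_units)):
            if len(units) == 0:
                raise ValueError(f"empty {side} unit list")
            if any(not u for u in units):
                raise ValueError(f"blank {side} subunit in {units!r}")
            if len(set(units)) != len(units):
                raise ValueError(f"duplicate {side} subunits in {units!r}")

    @property
    def pair_id(self) -> str:
        return COMPLEX_SEP.join(self.ligand_units) + PAIR_SEP + COMPLEX_SEP.join(self.receptor_units)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.ligand_units) + tuple(self.receptor_units)

    @classmethod
    def from_strings(cls, ligand: str, receptor: str) -> "LRPair":
        return cls(
            tuple(s.strip() for s in ligand.split(COMPLEX_SEP)),
            tuple(s.strip() for s in receptor.split(COMPLEX_SEP)),
        )

    @classmethod
    def from_pair_id(cls, pair_id: str) -> "LRPair":
        try:
            ligand, receptor = pair_id.split(PAIR_SEP)
        except ValueError as exc:
            raise ValueError(f"malformed pair id {pair_id!r}") from exc
        return cls.from_strings(ligand, receptor)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.pair_id


def load_lr_database(path) -> list[LRPair]:
    """Parse a two-column (ligand, receptor) TSV into deduplicated LRPairs.

    ``+`` joins complex subunits. A header line with the literal column names
    ``ligand``/``receptor`` is tolerated. Duplicated pair ids keep the first
    occurrence; input order is preserved.
    """
    pairs: list[LRPair] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
            ligand, receptor = (f.strip() for f in fields)
            if lineno == 1 and ligand.lower() == "ligand" and receptor.lower() == "receptor":
                continue
            if not ligand or not receptor:
                raise ValueError(f"{path}:{lineno}: empty ligand or receptor field")
            try:
                pair = LRPair.from_strings(ligand, receptor)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if pair.pair_id not in seen:
                seen.add(pair.pair_id)
                pairs.append(pair)
    return pairs


def bundled_lr_pairs() -> list[LRPair]:
    """The small ligand-receptor table shipped with the package (~50 human pairs)."""
    ref = _importlib_resources.files("braincomm").joinpath("data/lr_pairs.tsv")
    with _importlib_resources.as_file(ref) as path:
        return load_lr_database(path)


@dataclass
class OrthologReport:
    """Bookkeeping for :func:`map_orthologs`."""

    n_input: int = 0
    n_mapped: int = 0
    n_dropped: int = 0
    dropped_pair_ids: list[str] = field(default_factory=list)


def map_orthologs(
    pairs: Sequence[LRPair],
    ortholog_table: Mapping[str, str] | Iterable[tuple[str, str]],
) -> tuple[list[LRPair], OrthologReport]:
    """Map every subunit through a source->target symbol table.

    Pairs with any unmapped subunit are dropped and counted. If the table has
    one-to-many rows, the first mapping in table order wins (warning logged).
    """
    if isinstance(ortholog_table, Mapping):
        table = dict(ortholog_table)
    else:
        table = {}
        for src, dst in ortholog_table:
            if src in table:
                logger.warning("one-to-many ortholog mapping for %s: keeping %s, ignoring %s",
                               src, table[src], dst)
                continue
            table[src] = dst

    report = OrthologReport(n_input=len(pairs))
    mapped: list[LRPair] = []
    for pair in pairs:
        if all(g in table for g in pair.genes):
            mapped.append(LRPair(
                tuple(table[g] for g in pair.ligand_units),
                tuple(table[g] for g in pair.receptor_units),
            ))
        else:
            report.n_dropped += 1
            report.dropped_pair_ids.append(pair.pair_id)
    report.n_mapped = len(mapped)
    if report.n_dropped:
        logger.warning("map_orthologs dropped %d/%d pairs with unmapped subunits",
                       report.n_dropped, report.n_input)
    return mapped, report


def complex_expression(unit_values: Sequence[float] | np.ndarray) -> float:
    """Geometric mean of subunit expression values (zero subunit -> zero complex)."""
    vals = np.asarray(unit_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty unit value list")
    if np.any(vals < 0):
        raise ValueError("negative subunit expression")
    if np.any(vals == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))
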