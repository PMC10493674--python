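"""Sub-dataset partitioning and end-to-end pipeline orchestration.

A *sub-dataset* is the set of cells of one dataset sharing a combination of
condition labels (disease, sex, brain region) — the unit on which
communication is scored. ``run_pipeline`` chains the stages
simulate/load -> preprocess -> partition -> score -> integrate -> diff ->
(subtype, predict) from a flat YAML config, writing every artifact plus a
manifest of parameters and seeds.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import differential, integration, prediction, preprocess, scoring, simulate, subtyping
from .resources import LRPair, load_lr_database, bundled_lr_pairs

logger = logging.getLogger(__name__)

PARTITION_FIELDS = ("disease", "sex", "region")


@dataclass(frozen=True)
class SubDatasetKey:
    """Identity of one sub-dataset: dataset id plus its condition labels."""

    dataset_id: str
    disease: str = ""
    sex: str = ""
    region: str = ""

    @property
    def id(self) -> str:
        parts = [self.dataset_id] + [v for v in (self.disease, self.sex, self.region) if v]
        return "-".join(parts)

    @classmethod
    def from_id(cls, s: str, fields: Sequence[str] = PARTITION_FIELDS) -> "SubDatasetKey":
        parts = s.split("-")
        kwargs = dict(zip(fields, parts[1:]))
        return cls(dataset_id=parts[0], **kwargs)

    @property
    def labels(self) -> dict[str, str]:
        return {k: v for k, v in
                (("disease", self.disease), ("sex", self.sex), ("region", self.region)) if v}


def partition_subdatasets(
    adata: ad.AnnData,
    by: Sequence[str] = ("disease",),
    min_cells: int = 50,
) -> list[tuple[SubDatasetKey, ad.AnnData]]:
    """Split cells into sub-datasets by observed combinations of metadata fields.

    The partition is disjoint and exhaustive before the size filter;
    combinations with fewer than ``min_cells`` cells are dropped with a warning.
    """
    for f in by:
        if f not in adata.obs.columns:
            raise ValueError(f"unknown metadata field {f!r}")
    dataset_id = str(adata.uns.get("dataset_id", "DATASET"))
    if not by:
        key = SubDatasetKey(dataset_id=dataset_id)
        return [(key, adata.copy())]

    out: list[tuple[SubDatasetKey, ad.AnnData]] = []
    groups = adata.obs.groupby(list(by), observed=True, sort=True).groups
    for combo, cell_index in groups.items():
        if not isinstance(combo, tuple):
            combo = (combo,)
        if len(cell_index) < min_cells:
            logger.warning("partition: dropping %s=%s with %d < %d cells",
                           by, combo, len(cell_index), min_cells)
            continue
        kwargs = {f: str(v) for f, v in zip(by, combo) if f in PARTITION_FIELDS}
        key = SubDatasetKey(dataset_id=dataset_id, **kwargs)
        sub = adata[adata.obs_names.isin(cell_index)].copy()
        out.append((key, sub))
    return out


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class Manifest:
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    notes: dict[str, object] = field(default_factory=dict)

    def record(self, name: str, path: str) -> str:
        self.outputs[name] = path
        return path

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "outputs": self.outputs,
                 "timings_sec": self.timings, "notes": self.notes},
                fh, indent=2, default=str,
            )


def _load_pairs(cfg: Mapping) -> list[LRPair]:
    path = cfg.get("lr_database")
    return load_lr_database(path) if path else bundled_lr_pairs()


def integrate_subdatasets(
    subs: Sequence[tuple[SubDatasetKey, ad.AnnData]],
    pairs: Sequence[LRPair],
) -> list[integration.ISITable]:
    """Score and integrate every sub-dataset into an ISITable."""
    tables = []
    for key, sub in subs:
        method_tables = scoring.score_all(sub, pairs, subdataset_id=key.id)
        normalized = {m: integration.normalize_scores(t) for m, t in method_tables.items()}
        tables.append(integration.compute_isiscore(normalized, key.id, labels=key.labels))
    return tables


def run_pipeline(config_path: str) -> str:
    """Execute the configured stages; returns the manifest path.

    Raises on any stage failure after preserving partial outputs and logging
    the failing stage.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    for required in ("outdir",):
        if required not in cfg:
            raise KeyError(f"config missing required key {required!r}")
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = Manifest(config=cfg)
    manifest_path = os.path.join(outdir, "manifest.json")

    stage = "init"
    try:
        pairs = _load_pairs(cfg)

        # --- single-cell input -------------------------------------------
        stage = "simulate"
        t0 = time.time()
        if "counts_dir" in cfg:
            adata = simulate.read_sc(cfg["counts_dir"])
        else:
            sim_cfg_kwargs = dict(cfg.get("simulate", {}))
            planted = [simulate.PlantedPair(**p) for p in sim_cfg_kwargs.pop("planted_pairs", [])]
            conditions = sim_cfg_kwargs.pop("conditions", [
                {"sample": "S1", "disease": "AD"},
                {"sample": "S2", "disease": "normal"},
            ])
            sim_cfg = simulate.SimConfig(
                planted_pairs=tuple(planted), seed=seed, **sim_cfg_kwargs
            )
            adata = simulate.simulate_sc(sim_cfg, conditions)
            for name, path in simulate.write_sc(adata, os.path.join(outdir, "sc")).items():
                manifest.record(f"sc_{name}", path)
        manifest.timings[stage] = time.time() - t0

        # --- preprocess ---------------------------------------------------
        stage = "preprocess"
        t0 = time.time()
        pp = cfg.get("preprocess", {})
        adata = preprocess.filter_cells(adata, max_mito=pp.get("max_mito", 0.20))
        adata = preprocess.normalize_log(adata, scale_factor=pp.get("scale_factor", 10_000))
        hvgs = preprocess.select_hvg(adata, n=pp.get("n_hvg", 2000))
        if pp.get("cluster", True):
            preprocess.embed_cluster(
                adata,
                n_pcs=pp.get("n_pcs", 20),
                k_neighbors=pp.get("k_neighbors", 15),
                resolution=pp.get("resolution", 0.8),
                hvgs=hvgs,
                seed=seed,
            )
            markers = cfg.get("markers") or simulate.DEFAULT_MARKERS
            preprocess.annotate_clusters(adata, markers)
        else:
            adata.obs["cell_type"] = adata.obs["true_cell_type"]
        adata.obs.to_csv(manifest.record(
            "annotated_metadata", os.path.join(outdir, "annotated_metadata.tsv")), sep="\t")
        manifest.timings[stage] = time.time() - t0

        # --- partition + score + integrate --------------------------------
        stage = "partition"
        t0 = time.time()
        by = cfg.get("partition_by", ["disease"])
        subs = partition_subdatasets(adata, by=by, min_cells=cfg.get("min_subdataset_cells", 50))
        manifest.notes["subdatasets"] = [k.id for k, _ in subs]
        manifest.timings[stage] = time.time() - t0

        stage = "integrate"
        t0 = time.time()
        tables = integrate_subdatasets(subs, pairs)
        isi_frame = pd.concat([t.to_frame() for t in tables], ignore_index=True)
        isi_frame.to_csv(manifest.record(
            "isiscores", os.path.join(outdir, "isiscores.tsv")), sep="\t", index=False)
        manifest.timings[stage] = time.time() - t0

        # --- differential --------------------------------------------------
        stage = "diff"
        t0 = time.time()
        diff_cfg = cfg.get("diff", {})
        field_name = diff_cfg.get("field", "disease")
        value_a, value_b = diff_cfg.get("group_a", "AD"), diff_cfg.get("group_b", "normal")
        group_a = [t for t in tables if t.labels.get(field_name) == value_a]
        group_b = [t for t in tables if t.labels.get(field_name) == value_b]
        specific_ids: list[str] = []
        if group_a and group_b:
            sub_by_id = {k.id: s for k, s in subs}
            cells_a = [sub_by_id[t.subdataset_id] for t in group_a]
            cells_b = [sub_by_id[t.subdataset_id] for t in group_b]
            diff = differential.compare_conditions(group_a, group_b, cells_a, cells_b)
            calls = differential.call_specific(
                diff, alpha=diff_cfg.get("alpha", 0.05), log2_cut=diff_cfg.get("log2_cut", 3.0)
            )
            calls.reset_index().to_csv(manifest.record(
                "diff_calls", os.path.join(outdir, "diff_calls.tsv")), sep="\t", index=False)
            specific_ids = calls.index.get_level_values("pair_id")[
                calls["call"] == differential.CALL_A].unique().tolist()
            genes = differential.collect_marker_genes(specific_ids) if specific_ids else []
            with open(manifest.record(
                    "specific_genes", os.path.join(outdir, "specific_genes.txt")), "w") as fh:
                fh.write("\n".join(genes) + ("\n" if genes else ""))
        else:
            logger.warning("diff: skipped (a group has no sub-dataset)")
        manifest.timings[stage] = time.time() - t0

        # --- bulk stages ----------------------------------------------------
        if "bulk" in cfg:
            stage = "bulk"
            t0 = time.time()
            bulk_cfg = dict(cfg["bulk"])
            n_pairs = bulk_cfg.pop("n_pairs", 60)
            bc = simulate.BulkSimConfig(seed=seed, **bulk_cfg)
            sim = simulate.simulate_bulk(bc, simulate.make_disjoint_pairs(n_pairs))
            for name, path in simulate.write_bulk(sim, outdir).items():
                manifest.record(f"bulk_{name}", path)

            pert, consensus = subtyping.subtype_pipeline(
                sim.expr, sim.labels, sim.edges,
                k_range=range(2, cfg.get("kmax", 6) + 1),
                reps=cfg.get("reps", 1000), seed=seed,
            )
            pert.to_csv(manifest.record(
                "perturbation", os.path.join(outdir, "perturbation.tsv")), sep="\t")
            consensus.summary().to_csv(manifest.record(
                "consensus_summary", os.path.join(outdir, "consensus_summary.tsv")), sep="\t")
            consensus.labels.rename_axis("sample").to_csv(manifest.record(
                "subtype_labels", os.path.join(outdir, "subtype_labels.tsv")), sep="\t")
            manifest.notes["chosen_k"] = consensus.chosen_k

            panel = sorted({g for e in sim.edges for g in e})
            report = prediction.train_evaluate(sim.expr, sim.labels, panel, seed=seed)
            report.to_json(manifest.record(
                "prediction_report", os.path.join(outdir, "prediction_report.json")))
            manifest.notes["prediction_auc"] = report.auc
            manifest.timings[stage] = time.time() - t0

        stage = "manifest"
        manifest.write(manifest_path)
        manifest.outputs["manifest"] = manifest_path
        manifest.write(manifest_path)
        return manifest_path
    except Exception:
        logger.exception("pipeline failed at stage %r; partial outputs kept in %s", stage, outdir)
        manifest.notes["failed_stage"] = stage
        try:
            manifest.write(manifest_path)
        except OSError:
            pass
        raise
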