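"""Canonical synthetic benchmark studies exercising the full pipeline.

Each study generates data with known ground truth, runs the relevant pipeline
stages end to end, and reports the recovery/calibration quantities a method
paper would tabulate. Problem sizes are chosen so every study runs in seconds
to a few minutes on one CPU; see docs/methods.md for the rationale behind the
study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import differential, preprocess, simulate
from .resources import LRPair
from .simulate import BulkSimConfig, PlantedPair, SimConfig
from .subtyping import subtype_pipeline
from .prediction import train_evaluate
from .workflow import integrate_subdatasets, partition_subdatasets

BRAIN_TYPES = simulate.BRAIN_CELL_TYPES


def _background_pairs(n: int, offset: int = 0) -> list[LRPair]:
    return [LRPair((f"G{2 * i + 1 + offset:04d}",), (f"G{2 * i + 2 + offset:04d}",))
            for i in range(n)]


def _conditions(n_per_group: int) -> list[dict]:
    return ([{"sample": f"A{i}", "disease": "AD"} for i in range(n_per_group)]
            + [{"sample": f"N{i}", "disease": "normal"} for i in range(n_per_group)])


def _differential_run(config: SimConfig, conditions: list[dict], pairs: list[LRPair]):
    adata = simulate.simulate_sc(config, conditions)
    adata = preprocess.normalize_log(preprocess.filter_cells(adata))
    # ground-truth annotation isolates the differential stage from clustering
    adata.obs["cell_type"] = adata.obs["true_cell_type"]
    subs = partition_subdatasets(adata, by=["sample", "disease"])
    tables = integrate_subdatasets(subs, pairs)
    group_a = [t for t in tables if t.labels.get("disease") == "AD"]
    group_b = [t for t in tables if t.labels.get("disease") == "normal"]
    return differential.compare_conditions(group_a, group_b)


def null_calibration_study(
    seed: int = 0,
    n_per_group: int = 10,
    n_cells_per_type: int = 80,
    n_pairs: int = 15,
    alpha: float = 0.05,
) -> dict:
    """False-positive rate of the Wilcoxon test with no planted signal."""
    cfg = SimConfig(seed=seed, n_cells_per_type=n_cells_per_type)
    diff = _differential_run(cfg, _conditions(n_per_group), _background_pairs(n_pairs))
    return {
        "n_keys": int(len(diff)),
        "fraction_p_below_alpha": float((diff["p"] < alpha).mean()),
        "alpha": alpha,
    }


def planted_recovery_study(
    seed: int = 0,
    signal_fold: float = 8.0,
    n_per_group: int = 5,
    n_cells_per_type: int = 40,
    n_planted: int = 10,
    n_background: int = 20,
) -> dict:
    """Recovery of planted condition-specific communications and FP control."""
    planted = []
    for i in range(n_planted):
        planted.append(PlantedPair(
            ligand=f"G{2 * i + 1:04d}", receptor=f"G{2 * i + 2:04d}",
            sender=BRAIN_TYPES[i % 6], receiver=BRAIN_TYPES[(i + 2) % 6],
            condition="AD", signal_fold=signal_fold,
        ))
    pairs = ([LRPair((p.ligand,), (p.receptor,)) for p in planted]
             + _background_pairs(n_background, offset=2 * n_planted))
    cfg = SimConfig(seed=seed, n_cells_per_type=n_cells_per_type,
                    planted_pairs=tuple(planted))
    diff = _differential_run(cfg, _conditions(n_per_group), pairs)
    calls = differential.call_specific(diff)

    planted_keys = {(p.pair_id, p.sender, p.receiver) for p in planted}
    in_table = [k for k in planted_keys if k in calls.index]
    recovered = int((calls.loc[in_table, "call"] == differential.CALL_A).sum())
    others = calls.loc[[k for k in calls.index if k not in planted_keys]]
    n_fp = int((others["call"] != differential.CALL_NONE).sum())
    return {
        "n_planted": n_planted,
        "n_recovered": recovered,
        "recovery_rate": recovered / n_planted,
        "n_nonplanted_keys": int(len(others)),
        "n_false_positive_calls": n_fp,
        "false_positive_rate": n_fp / max(len(others), 1),
    }


def subtype_recovery_study(
    seed: int = 0,
    n_normal: int = 20,
    n_disease: int = 80,
    n_subtypes: int = 4,
    edges_per_subtype: int = 10,
    n_pairs: int = 60,
    rank_shift: float = 4.0,
    noise_sd: float = 0.5,
    reps: int = 250,
) -> dict:
    """Consensus-clustering recovery of planted bulk subtypes."""
    cfg = BulkSimConfig(n_normal=n_normal, n_disease=n_disease, n_subtypes=n_subtypes,
                        edges_per_subtype=edges_per_subtype, rank_shift=rank_shift,
                        noise_sd=noise_sd, seed=seed)
    sim = simulate.simulate_bulk(cfg, simulate.make_disjoint_pairs(n_pairs))
    _, result = subtype_pipeline(sim.expr, sim.labels, sim.edges, reps=reps, seed=seed)
    ari = adjusted_rand_score(sim.true_subtype.loc[result.labels.index], result.labels)
    return {
        "true_k": n_subtypes,
        "chosen_k": int(result.chosen_k),
        "ari": float(ari),
        "delta_areas": {int(k): float(v) for k, v in result.deltas.items()},
    }


def prediction_study(seed: int = 0, n_permutation_seeds: int = 20) -> dict:
    """Classifier sanity: separable data and a permutation null."""
    cfg = BulkSimConfig(n_normal=60, n_disease=100, n_subtypes=1, edges_per_subtype=20,
                        rank_shift=4.0, noise_sd=0.3, seed=seed)
    sim = simulate.simulate_bulk(cfg, simulate.make_disjoint_pairs(40))
    panel = sorted({g for e in sim.edges for g in e})
    rep = train_evaluate(sim.expr, sim.labels, panel, seed=seed, positive_label="disease")

    null_aucs = []
    for i in range(n_permutation_seeds):
        rng = np.random.default_rng([seed, i])
        permuted = pd.Series(rng.permutation(sim.labels.values), index=sim.labels.index)
        null = train_evaluate(sim.expr, permuted, panel, seed=i, positive_label="disease")
        null_aucs.append(null.auc)
    return {
        "auc_separable": float(rep.auc),
        "auc_permuted_mean": float(np.mean(null_aucs)),
        "auc_permuted_values": [float(a) for a in null_aucs],
    }


def annotation_study(seed: int = 0, n_cells_per_type: int = 60,
                     marker_fold: float = 4.0) -> dict:
    """Clustering + marker annotation recovery of the six planted brain types."""
    cfg = SimConfig(seed=seed, n_cells_per_type=n_cells_per_type, marker_fold=marker_fold)
    adata = simulate.simulate_sc(
        cfg, [{"sample": "S1", "disease": "AD"}, {"sample": "S2", "disease": "normal"}])
    adata = preprocess.normalize_log(preprocess.filter_cells(adata))
    hvgs = preprocess.select_hvg(adata, n=100)
    labels = preprocess.embed_cluster(adata, hvgs=hvgs, seed=seed)
    preprocess.annotate_clusters(adata, simulate.DEFAULT_MARKERS)

    truth = adata.obs["true_cell_type"].astype(str)
    called = adata.obs["cell_type"].astype(str)
    correct_types = 0
    for t in BRAIN_TYPES:
        mask = called == t
        if mask.any() and (truth[mask] == t).mean() > 0.5 and \
                (called[truth == t] == t).mean() > 0.5:
            correct_types += 1
    return {
        "n_types": len(BRAIN_TYPES),
        "n_types_correct": correct_types,
        "cluster_ari": float(adjusted_rand_score(truth, labels)),
        "cell_accuracy": float((truth == called).mean()),
    }
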