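"""Disease-status prediction from communication genes (gradient-boosted trees).

A deliberately off-the-shelf closing stage: expression of the
condition-specific communication genes feeds an XGBoost classifier with a
stratified 75/25 train/test split; performance is the test-set AUC computed by
the rank (Mann-Whitney) formulation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

DEFAULT_XGB_PARAMS = {
    "n_estimators": 200,
    "max_depth": 3,
    "learning_rate": 0.1,
    # row/column subsampling decorrelates the trees so the ensemble votes
    # across the whole gene panel instead of latching onto a single split
    "subsample": 0.8,
    "colsample_bytree": 0.5,
    "n_jobs": 1,
    "eval_metric": "logloss",
}


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation (ties get average ranks)."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class PredictionReport:
    genes_used: list[str]
    genes_missing: list[str]
    train_samples: list[str]
    test_samples: list[str]
    auc: float
    probabilities: dict[str, float]
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def train_evaluate(
    expr: pd.DataFrame,
    labels: pd.Series,
    genes: Sequence[str],
    train_frac: float = 0.75,
    seed: int = 0,
    positive_label: str | None = None,
    params: dict | None = None,
) -> PredictionReport:
    """Fit a gradient-boosted classifier on a gene panel and report test AUC.

    ``expr`` is genes x samples; ``labels`` maps sample -> class (two classes).
    Genes absent from ``expr`` are dropped with a warning. The split is
    stratified at ``train_frac``; a class missing from either side raises.
    """
    from xgboost import XGBClassifier

    labels = labels.loc[expr.columns]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if positive_label is None:
        positive_label = classes[1]
    y = (labels == positive_label).astype(int).values

    present = [g for g in genes if g in expr.index]
    missing = [g for g in genes if g not in expr.index]
    if missing:
        logger.warning("train_evaluate: %d/%d panel genes missing from matrix",
                       len(missing), len(genes))
    if not present:
        raise ValueError("no panel gene present in the expression matrix")
    X = expr.loc[present].T.values

    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, stratify=y, random_state=seed
    )
    for name, part in (("train", train_idx), ("test", test_idx)):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"a class is absent from the {name} split; try another seed")

    xgb_params = dict(DEFAULT_XGB_PARAMS)
    xgb_params.update(params or {})
    model = XGBClassifier(random_state=seed, **xgb_params)
    model.fit(X[train_idx], y[train_idx])
    probs = model.predict_proba(X[test_idx])[:, 1]
    auc = rank_auc(y[test_idx], probs)

    samples = expr.columns.to_numpy()
    return PredictionReport(
        genes_used=present,
        genes_missing=missing,
        train_samples=samples[train_idx].tolist(),
        test_samples=samples[test_idx].tolist(),
        auc=auc,
        probabilities={str(s): float(p) for s, p in zip(samples[test_idx], probs)},
        seed=seed,
        params=xgb_params,
    )
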