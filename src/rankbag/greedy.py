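"""Greedy baseline: pick one overall winner by k-fold CV and a single
rank aggregation, then refit it on all training data.

Per fold, all M components are trained on the other k-1 folds and scored on
the held-out fold under the K measures; scores are averaged across folds,
ranked per measure, and one weighted rank aggregation names the winner.  No
model averaging happens at prediction time — the single refitted winner
predicts.  This is the naive alternative the adaptive ensemble is measured
against: it tends to overfit the training data's fold noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import adapters
from .ensemble import _rank_and_aggregate, _score_measures

__all__ = ["GreedyModel", "train_greedy", "predict_greedy"]

log = logging.getLogger(__name__)


@dataclass
class GreedyModel:
    """Winner of one cross-validated rank aggregation, refitted on all data."""

    winner_id: str
    model: adapters.FittedClassifier
    score_table: pd.DataFrame  # fold-averaged, specs x measures
    positive_class: object

    def predict(self, X) -> np.ndarray:
        return self.model.predict(X)

    def decision_score(self, X) -> np.ndarray:
        return self.model.decision_score(X)


def train_greedy(
    X,
    y,
    specs,
    k: int = 10,
    measures=("accuracy", "sensitivity", "specificity"),
    weights=None,
    distance: str = "footrule",
    aggregator: str = "brute",
    positive_class=None,
    seed: int | None = None,
) -> GreedyModel:
    """Cross-validate all specs, aggregate the fold-averaged ranks once,
    and refit the winner on the full training data.

    Folds are stratified by class so small samples keep both classes in every
    held-out fold.  A spec failing on any fold is excluded from the ranking
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {len(classes)}")
    pos = positive_class if positive_class is not None else classes[-1]
    rng = np.random.default_rng(seed)
    splitter = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    needs_scores = "auc" in measures

    fold_scores = {s.id: [] for s in specs}
    failed = set()
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        Xt, yt = X[train_idx], y[train_idx]
        Xv, yv = X[test_idx], y[test_idx]
        for spec in specs:
            if spec.id in failed:
                continue
            try:
                model = adapters.fit(spec, Xt, yt, positive_class=pos, rng=rng)
            except adapters.AdapterFitError as exc:
                log.warning("fold %d: %s excluded from greedy ranking (%s)", fold, spec.id, exc)
                failed.add(spec.id)
                continue
            y_pred = model.predict(Xv)
            scores = model.decision_score(Xv) if needs_scores else None
            fold_scores[spec.id].append(
                _score_measures(measures, yv, y_pred, scores, pos)
            )
    surviving = [s for s in specs if s.id not in failed]
    if not surviving:
        raise RuntimeError("every component algorithm failed during greedy CV")

    avg = {
        s.id: {
            m: float(np.nanmean([f[m] for f in fold_scores[s.id]]))
            for m in measures
        }
        for s in surviving
    }
    result = _rank_and_aggregate(avg, tuple(measures), weights, distance, aggregator, rng)
    winner_id = result.best_order[0]
    winner_spec = next(s for s in surviving if s.id == winner_id)
    model = adapters.fit(winner_spec, X, y, positive_class=pos, rng=rng)
    table = pd.DataFrame(avg).T.loc[[s.id for s in surviving], list(measures)]
    log.info("greedy winner: %s (fold-averaged scores:\n%s)", winner_id, table)
    return GreedyModel(winner_id, model, table, pos)


def predict_greedy(model: GreedyModel, X) -> np.ndarray:
    """Predict with the single refitted winner."""
    return model.predict(X)
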