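"""The adaptive bagged rank-aggregation ensemble.

For each of N bootstrap samples, all M component algorithms are fitted
in-bag, scored on the out-of-bag (OOB) rows under K performance measures,
ranked per measure, and the per-bootstrap winner is chosen by weighted rank
aggregation of the K orderings.  Prediction runs a new sample through the N
locally-best fitted models and takes a majority vote; the vote proportion is
the class probability.  Permutation variable importance averages, over the N
winners, the increase in OOB misclassification error when one feature is
shuffled within the OOB rows.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass


import joblib
import numpy as np

from . import adapters, performance, rank_aggregation as ra

__all__ = [
    "EnsembleConfig",
    "BootstrapDraw",
    "EnsembleMember",
    "EnsembleModel",
    "draw_bootstrap",
    "train_ensemble",
]

log = logging.getLogger(__name__)

MEASURES = ("accuracy", "sensitivity", "specificity", "auc")


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of the adaptive ensemble.

    Defaults follow the standard setup: N = 101 bootstrap samples and the
    three measures accuracy, sensitivity, specificity with equal weights,
    aggregated under the Spearman footrule distance by exact enumeration.
    """

    specs: tuple
    n_bootstrap: int = 101
    measures: tuple = ("accuracy", "sensitivity", "specificity")
    weights: tuple | None = None
    distance: str = "footrule"
    aggregator: str = "brute"
    positive_class: object = None
    seed: int | None = None
    max_redraws: int = 1000

    def __post_init__(self):
        object.__setattr__(self, "specs", tuple(self.specs))
        object.__setattr__(self, "measures", tuple(self.measures))
        if not self.specs:
            raise ValueError("need at least one classifier spec")
        ids = [s.id for s in self.specs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate spec ids: {ids}")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not self.measures:
            raise ValueError("need at least one performance measure")
        for m in self.measures:
            if m not in MEASURES:
                raise ValueError(f"unknown measure {m!r}; known: {MEASURES}")
        w = self.weights
        if w is not None:
            w = tuple(float(x) for x in w)
            if len(w) != len(self.measures) or any(x <= 0 for x in w):
                raise ValueError("weights must be positive, one per measure")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class BootstrapDraw:
    """In-bag indices (size n, with replacement) and their OOB complement."""

    in_bag: np.ndarray
    oob: np.ndarray


def draw_bootstrap(y, rng, max_redraws: int = 1000) -> BootstrapDraw:
    """Simple random sample of size n with replacement, redrawn entirely
    until every class appears in-bag and the OOB set is non-empty.

    A draw with no OOB rows cannot be scored, and one missing a class cannot
    fit every component, so both are rejected wholesale rather than patched.
    """
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)
    if n < len(classes):
        raise ValueError("fewer samples than classes")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    for _ in range(max_redraws):
        in_bag = rng.integers(n, size=n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if oob.size and len(np.unique(y[in_bag])) == len(classes):
            return BootstrapDraw(in_bag=in_bag, oob=oob)
    raise RuntimeError(
        f"no admissible bootstrap sample in {max_redraws} attempts "
        "(degenerate class frequencies?)"
    )


def _score_measures(measures, y_true, y_pred, scores, positive_class):
    cc = performance.confusion(y_true, y_pred, positive_class)
    out = {}
    for m in measures:
        if m == "accuracy":
            out[m] = performance.accuracy(cc)
        elif m == "sensitivity":
            out[m] = performance.sensitivity(cc)
        elif m == "specificity":
            out[m] = performance.specificity(cc)
        elif m == "auc":
            out[m] = performance.roc_auc(y_true, scores, positive_class)
    return out


@dataclass
class EnsembleMember:
    """One bootstrap round: the winning algorithm and its fitted model."""

    winner_id: str
    model: adapters.FittedClassifier
    draw: BootstrapDraw
    oob_scores: dict  # spec id -> {measure -> value} for this bootstrap
    oob_error: float  # winner's OOB misclassification error


class EnsembleModel:
    """N locally-best fitted models plus the configuration that produced them."""

    def __init__(self, config: EnsembleConfig, members: list, classes: np.ndarray,
                 positive_class, n_features: int):
        self.config = config
        self.members = members
        self.classes_ = classes
        self.positive_class = positive_class
        self.n_features_ = n_features

    @property
    def n_members(self) -> int:
        return len(self.members)

    def winner_ids(self) -> list:
        return [m.winner_id for m in self.members]

    def selection_counts(self) -> dict:
        """How often each component algorithm won; counts sum to N."""
        counts = Counter(self.winner_ids())
        return {s.id: counts.get(s.id, 0) for s in self.config.specs}

    def _votes(self, X) -> np.ndarray:
        """(N, r) member predictions."""
        return np.stack([m.model.predict(X) for m in self.members])

    def predict_proba(self, X) -> np.ndarray:
        """Vote proportions per class, columns ordered as ``classes_``.

        Each entry is a multiple of 1/N and rows sum to 1.
        """
        votes = self._votes(X)
        out = np.empty((votes.shape[1], len(self.classes_)))
        for j, c in enumerate(self.classes_):
            out[:, j] = (votes == c).mean(axis=0)
        return out

    def predict(self, X) -> np.ndarray:
        """Majority vote over the N members; exact ties go to positive_class."""
        proba = self.predict_proba(X)
        pos_col = int(np.nonzero(self.classes_ == self.positive_class)[0][0])
        neg_col = 1 - pos_col
        pred = np.where(
            proba[:, pos_col] >= proba[:, neg_col],
            self.classes_[pos_col],
            self.classes_[neg_col],
        )
        return pred.astype(self.classes_.dtype)

    def decision_score(self, X) -> np.ndarray:
        """Positive-class vote proportion (the probability formula's score)."""
        pos_col = int(np.nonzero(self.classes_ == self.positive_class)[0][0])
        return self.predict_proba(X)[:, pos_col]

    def variable_importance(self, X, y, rng=None, n_repeats: int = 1) -> np.ndarray:
        """Permutation importance I_m for each feature m.

        For member i with OOB rows O_i: I_m averages, over members, the OOB
        error with feature m shuffled within O_i minus the unpermuted OOB
        error.  One permutation per (member, feature) by default;
        ``n_repeats`` averages several.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] != self.n_features_:
            raise ValueError("X does not match the training feature count")
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        p = X.shape[1]
        diffs = np.zeros((self.n_members, p))
        for i, member in enumerate(self.members):
            oob = member.draw.oob
            Xo, yo = X[oob], y[oob]
            base_err = float(np.mean(member.model.predict(Xo) != yo))
            for m in range(p):
                err = 0.0
                for _ in range(n_repeats):
                    Xp = Xo.copy()
                    Xp[:, m] = Xp[rng.permutation(len(oob)), m]
                    err += float(np.mean(member.model.predict(Xp) != yo))
                diffs[i, m] = err / n_repeats - base_err
        return diffs.mean(axis=0)

    def save(self, path) -> None:
        """Persist config, winner ids and fitted adapters as a joblib bundle."""
        joblib.dump(
            {
                "format": "rankbag-ensemble-v1",
                "config": self.config,
                "members": self.members,
                "classes": self.classes_,
                "positive_class": self.positive_class,
                "n_features": self.n_features_,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        bundle = joblib.load(path)
        if bundle.get("format") != "rankbag-ensemble-v1":
            raise ValueError(f"{path} is not a rankbag ensemble bundle")
        return cls(
            bundle["config"], bundle["members"], bundle["classes"],
            bundle["positive_class"], bundle["n_features"],
        )


def _rank_and_aggregate(score_table, measures, weights, distance, aggregator, rng):
    """Build one ranked list per defined measure and aggregate them.

    A measure undefined (NaN) for every algorithm on this bootstrap — e.g.
    sensitivity when the OOB set holds no positives — is dropped rather than
    imputed, so it cannot bias the aggregation.
    """
    lists, w = [], []
    weights = weights or tuple(1.0 for _ in measures)
    for m, wm in zip(measures, weights):
        col = {aid: s[m] for aid, s in score_table.items()}
        if all(not performance.is_defined(v) for v in col.values()):
            continue
        lists.append(performance.rank_algorithms(col, rng=rng))
        w.append(wm)
    if not lists:
        # every measure undefined: fall back to a random strict ordering
        lists = [performance.rank_algorithms({aid: 0.0 for aid in score_table}, rng=rng)]
        w = [1.0]
    problem = ra.AggregationProblem(tuple(lists), tuple(w), distance)
    seed = int(rng.integers(2**31 - 1))
    if aggregator == "brute":
        return ra.aggregate_brute_force(problem)
    return ra.aggregate(problem, aggregator, seed=seed)


def train_ensemble(X, y, config: EnsembleConfig) -> EnsembleModel:
    """Run the full bootstrap / OOB-scoring / rank-aggregation loop.

    Component algorithms that fail to fit on a given bootstrap (e.g. a
    singular QDA covariance) are excluded from that round's ranking with a
    logged warning; a round where every component fails aborts training.
    Fully reproducible given ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {len(classes)}")
    pos = config.positive_class if config.positive_class is not None else classes[-1]
    rng = np.random.default_rng(config.seed)
    needs_scores = "auc" in config.measures

    members = []
    for j in range(config.n_bootstrap):
        draw = draw_bootstrap(y, rng, config.max_redraws)
        Xb, yb = X[draw.in_bag], y[draw.in_bag]
        Xo, yo = X[draw.oob], y[draw.oob]
        fitted, score_table = {}, {}
        for spec in config.specs:
            try:
                model = adapters.fit(spec, Xb, yb, positive_class=pos, rng=rng)
            except adapters.AdapterFitError as exc:
                log.warning("bootstrap %d: %s excluded (%s)", j, spec.id, exc)
                continue
            y_pred = model.predict(Xo)
            scores = model.decision_score(Xo) if needs_scores else None
            fitted[spec.id] = model
            score_table[spec.id] = _score_measures(
                config.measures, yo, y_pred, scores, pos
            )
        if not fitted:
            raise RuntimeError(
                f"all {len(config.specs)} component algorithms failed on "
                f"bootstrap {j}; cannot continue"
            )
        result = _rank_and_aggregate(
            score_table, config.measures, config.weights,
            config.distance, config.aggregator, rng,
        )
        winner = result.best_order[0]
        acc = score_table[winner].get("accuracy")
        if acc is None or not performance.is_defined(acc):
            cc = performance.confusion(yo, fitted[winner].predict(Xo), pos)
            acc = performance.accuracy(cc)
        members.append(
            EnsembleMember(
                winner_id=winner,
                model=fitted[winner],
                draw=draw,
                oob_scores=score_table,
                oob_error=1.0 - acc,
            )
        )
        log.debug("bootstrap %d: winner=%s oob=%s", j, winner, score_table[winner])
    log.info(
        "trained ensemble: N=%d, selection counts %s",
        len(members),
        Counter(m.winner_id for m in members),
    )
    return EnsembleModel(config, members, classes, pos, X.shape[1])
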