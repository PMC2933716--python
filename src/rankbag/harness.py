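"""Repeated train/test benchmarks, external cross-validation, results tables.

A benchmark draws a fresh training and testing set per replicate, fits every
competing method on the training set, scores accuracy / sensitivity /
specificity / AUC on the testing set, and reports the mean and standard
error (sd / sqrt(R)) of each measure across replicates.  Replicates are
seeded from a master seed through ``numpy.random.SeedSequence.spawn``, so
serial and parallel execution produce identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.model_selection import StratifiedKFold

from . import adapters, performance
from .datasets import LabeledDataset, simulated_microarray, threenorm
from .ensemble import EnsembleConfig, train_ensemble
from .greedy import train_greedy

__all__ = [
    "Method",
    "single_method",
    "ensemble_method",
    "greedy_method",
    "ExperimentPlan",
    "threenorm_plan",
    "microarray_plan",
    "run_simulation_benchmark",
    "run_external_cv",
    "report",
    "save_table",
    "load_table",
]

log = logging.getLogger(__name__)

TEST_MEASURES = ("accuracy", "sensitivity", "specificity", "auc")


@dataclass(frozen=True)
class Method:
    """A named competitor: ``fit(X, y, seed) -> model`` with predict +
    decision_score, evaluated on a held-out set."""

    name: str
    fit: Callable

    def evaluate(self, X_train, y_train, X_test, y_test, seed) -> dict:
        model = self.fit(X_train, y_train, seed)
        y_pred = model.predict(X_test)
        scores = model.decision_score(X_test)
        cc = performance.confusion(y_test, y_pred)
        return {
            "accuracy": performance.accuracy(cc),
            "sensitivity": performance.sensitivity(cc),
            "specificity": performance.specificity(cc),
            "auc": performance.roc_auc(y_test, scores),
        }


def single_method(spec: adapters.ClassifierSpec, name: str | None = None) -> Method:
    """One component algorithm fitted directly on the training data."""

    def fit(X, y, seed):
        return adapters.fit(spec, X, y, rng=seed)

    return Method(name or spec.id, fit)


def ensemble_method(specs, name: str = "Ensemble", **config_kwargs) -> Method:
    """The adaptive ensemble over ``specs``; AUC uses vote proportions."""

    def fit(X, y, seed):
        config = EnsembleConfig(specs=tuple(specs), seed=seed, **config_kwargs)
        return train_ensemble(X, y, config)

    return Method(name, fit)


def greedy_method(specs, name: str = "Greedy", k: int = 10, **kwargs) -> Method:
    """The greedy k-fold baseline over the same ``specs``."""

    def fit(X, y, seed):
        return train_greedy(X, y, tuple(specs), k=k, seed=seed, **kwargs)

    return Method(name, fit)


@dataclass(frozen=True)
class ExperimentPlan:
    """A repeated train/test simulation benchmark.

    ``make_data(rng)`` returns a (train, test) pair of
    :class:`~rankbag.datasets.LabeledDataset`; each of the ``replicates``
    draws uses a child seed spawned from ``seed``.
    """

    make_data: Callable
    methods: tuple
    replicates: int = 100
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "methods", tuple(self.methods))
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        names = [m.name for m in self.methods]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate method names: {names}")


def _run_replicate(plan: ExperimentPlan, child_seed: np.random.SeedSequence):
    rng = np.random.default_rng(child_seed)
    train, test = plan.make_data(rng)
    out = {}
    for method in plan.methods:
        seed = int(rng.integers(2**31 - 1))
        try:
            out[method.name] = method.evaluate(train.X, train.y, test.X, test.y, seed)
        except Exception as exc:
            log.warning("replicate dropped for %s: %s", method.name, exc)
            out[method.name] = None
    return out


def _summarize(per_method: dict) -> pd.DataFrame:
    """Mean and SE per method x measure; SE is NaN for a single replicate."""
    rows = {}
    n_used = {}
    for name, results in per_method.items():
        ok = [r for r in results if r is not None]
        n_used[name] = len(ok)
        row = {}
        for m in TEST_MEASURES:
            vals = np.array([r[m] for r in ok], dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                row[(m, "mean")], row[(m, "se")] = np.nan, np.nan
            else:
                row[(m, "mean")] = vals.mean()
                row[(m, "se")] = (
                    vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
                )
        rows[name] = row
    table = pd.DataFrame(rows).T
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["measure", "stat"])
    table.attrs["n_replicates"] = n_used
    return table


def run_simulation_benchmark(plan: ExperimentPlan, n_jobs: int = 1) -> pd.DataFrame:
    """Run the repeated train/test benchmark and summarize it.

    Returns a DataFrame indexed by method with (measure, mean/se) columns.
    A method failing on a replicate loses that replicate (logged); the
    effective replicate count per method is in ``table.attrs["n_replicates"]``.
    """
    children = np.random.SeedSequence(plan.seed).spawn(plan.replicates)
    if n_jobs == 1:
        results = [_run_replicate(plan, c) for c in children]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_run_replicate)(plan, c) for c in children
        )
    per_method = {
        m.name: [r[m.name] for r in results] for m in plan.methods
    }
    return _summarize(per_method)


def run_external_cv(X, y, methods: Sequence[Method], k: int = 10, seed=None) -> pd.DataFrame:
    """Outer stratified k-fold CV around each method's own internal selection.

    For the adaptive ensemble the "inner cross-validation" is its bootstrap /
    OOB loop; for greedy, its inner k-fold.  Fold scores are averaged and the
    SE is taken across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    splitter = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    per_method = {m.name: [] for m in methods}
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        fold_seed = int(rng.integers(2**31 - 1))
        for method in methods:
            try:
                res = method.evaluate(
                    X[train_idx], y[train_idx], X[test_idx], y[test_idx], fold_seed
                )
            except Exception as exc:
                log.warning("fold %d dropped for %s: %s", fold, method.name, exc)
                res = None
            per_method[method.name].append(res)
    return _summarize(per_method)


# ---------------------------------------------------------------------------
# canonical benchmark plans
# ---------------------------------------------------------------------------


def threenorm_plan(
    replicates: int = 100,
    n_train: int = 100,
    n_test: int = 100,
    d: int = 1000,
    n_bootstrap: int = 101,
    rf_trees: int = 500,
    greedy_k: int = 10,
    seed: int | None = None,
) -> ExperimentPlan:
    """The threenorm benchmark: eight components + ensemble + greedy.

    Defaults reproduce the full-scale study (100 replicates, 101 bootstraps,
    d = 1000, 100 train / 100 test).  Pass smaller ``replicates`` /
    ``n_bootstrap`` / ``rf_trees`` for a desk-scale run.
    """
    specs = adapters.threenorm_specs(rf_trees=rf_trees)
    methods = [single_method(s) for s in specs]
    methods.append(greedy_method(specs, k=greedy_k))
    methods.append(ensemble_method(specs, n_bootstrap=n_bootstrap))

    def make_data(rng):
        return (
            threenorm(n=n_train, d=d, rng=rng),
            threenorm(n=n_test, d=d, rng=rng),
        )

    return ExperimentPlan(make_data, tuple(methods), replicates, seed)


def microarray_plan(
    replicates: int = 50,
    n_cases: int = 50,
    n_controls: int = 50,
    d: int = 5000,
    frac_informative: float = 0.1,
    delta: float = 0.3,
    n_bootstrap: int = 101,
    greedy_k: int = 10,
    seed: int | None = None,
) -> ExperimentPlan:
    """The simulated-microarray benchmark: four SVM kernels + ensemble + greedy."""
    specs = adapters.svm_kernel_specs()
    methods = [single_method(s) for s in specs]
    methods.append(greedy_method(specs, k=greedy_k))
    methods.append(ensemble_method(specs, n_bootstrap=n_bootstrap))

    def make_data(rng):
        kw = dict(
            n_cases=n_cases, n_controls=n_controls, d=d,
            frac_informative=frac_informative, delta=delta,
        )
        return simulated_microarray(rng=rng, **kw), simulated_microarray(rng=rng, **kw)

    return ExperimentPlan(make_data, tuple(methods), replicates, seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def report(table: pd.DataFrame, fmt: str = "text") -> str:
    """Render a results table as aligned text, CSV, or markdown.

    The text and markdown styles show "mean (se)" per cell, matching the
    conventional presentation of repeated-benchmark tables.
    """
    if fmt == "csv":
        flat = table.copy()
        flat.columns = [f"{m}_{s}" for m, s in table.columns]
        return flat.to_csv(float_format="%.6f")
    measures = table.columns.get_level_values(0).unique()

    def cell(name, m):
        mean = table.loc[name, (m, "mean")]
        se = table.loc[name, (m, "se")]
        if np.isnan(mean):
            return "--"
        return f"{mean:.6f} ({se:.5f})" if not np.isnan(se) else f"{mean:.6f}"

    if fmt == "markdown":
        lines = ["| method | " + " | ".join(measures) + " |"]
        lines.append("|" + "---|" * (len(measures) + 1))
        for name in table.index:
            lines.append(
                f"| {name} | " + " | ".join(cell(name, m) for m in measures) + " |"
            )
        return "\n".join(lines)
    if fmt == "text":
        width = max((len(str(i)) for i in table.index), default=6) + 2
        colw = 22
        lines = ["".ljust(width) + "".join(str(m).ljust(colw) for m in measures)]
        for name in table.index:
            lines.append(
                str(name).ljust(width)
                + "".join(cell(name, m).ljust(colw) for m in measures)
            )
        return "\n".join(lines)
    raise ValueError(f"unknown format {fmt!r}")


def save_table(table: pd.DataFrame, path) -> None:
    """Write a results table as flat CSV (6-decimal round trip)."""
    flat = table.copy()
    flat.columns = [f"{m}_{s}" for m, s in table.columns]
    flat.to_csv(path, float_format="%.6f")


def load_table(path) -> pd.DataFrame:
    """Read a table written by :func:`save_table`."""
    flat = pd.read_csv(path, index_col=0)
    cols = [tuple(c.rsplit("_", 1)) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(cols, names=["measure", "stat"])
    return flat
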