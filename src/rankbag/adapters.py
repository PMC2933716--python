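"""Uniform adapters over the component classification algorithms.

Each component algorithm — SVM (four kernels), random forest, lasso-penalized
logistic regression (PLR), LDA, QDA, PLS used directly as a classifier, and
the compositions PCA+{LDA,QDA} and PLS+{LDA,QDA,RF} — is wrapped behind one
contract: ``fit(spec, X, y) -> FittedClassifier`` with ``predict`` and a
monotone ``decision_score`` (larger = more positive-class).  Core fitting
delegates to scikit-learn; only the adapter contract and the reducer +
classifier compositions are bespoke.

Decision scores per family
--------------------------
svm        signed distance from the separating hyperplane (cutpoint 0)
rf / plr / lda / qda
           positive-class probability (cutpoint 0.5, exact ties -> negative)
pls        continuous PLS prediction of the 0/1-coded label (cutpoint 0.5,
           the midpoint of the two coded values)

Dimension reducers (PCA: top-variance projection; PLS: response-covariance
projection) are fitted on the training rows only and stored, so test data are
projected through the identical map — no information from prediction-time
rows ever reaches the projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.decomposition import PCA
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

__all__ = [
    "ClassifierSpec",
    "FittedClassifier",
    "AdapterFitError",
    "SingularCovarianceError",
    "fit",
    "default_specs",
    "make_spec",
    "threenorm_specs",
    "svm_kernel_specs",
]

FAMILIES = ("svm", "rf", "plr", "lda", "qda", "pls")
REDUCERS = (None, "pca", "pls")


class AdapterFitError(RuntimeError):
    """A component algorithm failed to fit; carries the offending spec id."""

    def __init__(self, spec_id: str, message: str):
        super().__init__(f"[{spec_id}] {message}")
        self.spec_id = spec_id


class SingularCovarianceError(AdapterFitError):
    """Within-class covariance is singular (QDA with too few samples/class)."""


@dataclass(frozen=True)
class ClassifierSpec:
    """A named component algorithm with optional dimension reduction.

    Parameters
    ----------
    id : unique name within an ensemble configuration.
    family : one of {"svm", "rf", "plr", "lda", "qda", "pls"}.
    reducer : None, "pca" or "pls"; fitted on training rows only.
    n_components : latent dimensions for the reducer (clipped to the
        available rank with a warning).
    params : family hyperparameters, e.g. {"kernel": "linear"} for svm or
        {"n_trees": 100} for rf.  Defaults mirror the classical R defaults:
        SVM cost 1, gamma 1/p, degree 3; RF 500 trees, mtry = sqrt(p); PLR
        lasso penalty chosen by internal 3-fold cross-validation.
    """

    id: str
    family: str
    reducer: str | None = None
    n_components: int = 5
    params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.reducer not in REDUCERS:
            raise ValueError(f"unknown reducer {self.reducer!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def _derive_seed(rng) -> int | None:
    if rng is None:
        return None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return int(rng.integers(2**31 - 1))


_PLR_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


def _build_estimator(spec: ClassifierSpec, n_features: int, seed):
    p = dict(spec.params)
    if spec.family == "svm":
        return SVC(
            C=p.get("C", 1.0),
            kernel=p.get("kernel", "rbf"),
            degree=p.get("degree", 3),
            gamma=p.get("gamma", "auto"),  # 1/p, the classical default
            coef0=p.get("coef0", 0.0),
        )
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=p.get("n_trees", 500),
            max_features=p.get("max_features", "sqrt"),
            random_state=seed,
        )
    if spec.family == "plr":
        base = LogisticRegression(
            solver="liblinear", l1_ratio=1.0, max_iter=p.get("max_iter", 500)
        )
        return GridSearchCV(
            base,
            {"C": list(p.get("C_grid", _PLR_C_GRID))},
            cv=p.get("cv", 3),
            n_jobs=1,
        )
    if spec.family == "lda":
        return LinearDiscriminantAnalysis()
    if spec.family == "qda":
        # slight covariance shrinkage: the svd solver refuses the near-singular
        # within-class covariances that classical QDA routines tolerate, and
        # reduced scores (PLS/PCA) routinely sit near that edge
        return QuadraticDiscriminantAnalysis(reg_param=p.get("reg_param", 1e-3))
    raise AssertionError(spec.family)


class FittedClassifier:
    """A fitted component algorithm, carrying its fitted reducer (if any).

    Predicts only the two labels seen at fit time.  ``decision_score``
    returns a per-row score monotone in the positive-class tendency; for
    probabilistic families this is the positive-class probability.
    """

    def __init__(self, spec, classes, positive_class, n_features, reducer, estimator, pls_coded=None):
        self.spec = spec
        self.classes_ = classes
        self.positive_class = positive_class
        self.n_features_ = n_features
        self._reducer = reducer
        self._est = estimator
        self._pls_coded = pls_coded  # (neg_label, pos_label) for family "pls"

    def _transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} feature columns, got shape {X.shape}"
            )
        if self._reducer is not None:
            return np.asarray(self._reducer.transform(X))
        return X

    def decision_score(self, X) -> np.ndarray:
        """Per-row score, larger = more positive-class."""
        Z = self._transform(X)
        if Z.shape[0] == 0:
            return np.empty(0)
        if self.spec.family == "svm":
            df = self._est.decision_function(Z)
            # SVC orients its decision function toward classes_[1]
            return df if self.positive_class == self._est.classes_[1] else -df
        if self.spec.family == "pls":
            return np.asarray(self._est.predict(Z)).ravel()
        proba = self._est.predict_proba(Z)
        est_classes = (
            self._est.best_estimator_.classes_
            if isinstance(self._est, GridSearchCV)
            else self._est.classes_
        )
        pos_col = int(np.nonzero(est_classes == self.positive_class)[0][0])
        return proba[:, pos_col]

    def predict(self, X) -> np.ndarray:
        Z = self._transform(X)
        if Z.shape[0] == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        if self.spec.family == "pls":
            score = np.asarray(self._est.predict(Z)).ravel()
            neg, pos = self._pls_coded
            return np.where(score > 0.5, pos, neg).astype(self.classes_.dtype)
        return np.asarray(self._est.predict(Z))


def _fit_reducer(spec: ClassifierSpec, X, y01, rng_seed):
    n, p = X.shape
    k = min(spec.n_components, n - 1, p)
    if k < spec.n_components:
        warnings.warn(
            f"[{spec.id}] n_components reduced from {spec.n_components} to {k} "
            f"(data rank limit, n={n}, p={p})"
        )
    if spec.reducer == "pca":
        red = PCA(n_components=k, random_state=rng_seed)
        red.fit(X)
    else:
        red = PLSRegression(n_components=k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # y residual warnings on easy fits
            red.fit(X, y01)
    return red


def fit(spec: ClassifierSpec, X, y, positive_class=None, rng=None) -> FittedClassifier:
    """Fit a component algorithm (reducer first, if composite) on (X, y).

    ``rng`` seeds any internal randomness (random forest).  Raises
    :class:`AdapterFitError` (or :class:`SingularCovarianceError`) naming the
    spec when fitting is impossible on this sample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    classes = np.unique(y)
    if len(classes) != 2:
        raise AdapterFitError(spec.id, f"need exactly two classes, got {len(classes)}")
    pos = classes[-1] if positive_class is None else positive_class
    if pos not in classes:
        raise AdapterFitError(spec.id, f"positive_class {pos!r} not present in y")
    seed = _derive_seed(rng)
    y01 = (y == pos).astype(float)

    reducer = None
    Z = X
    if spec.reducer is not None:
        reducer = _fit_reducer(spec, X, y01, seed)
        Z = np.asarray(reducer.transform(X))

    if spec.family == "qda":
        min_class = int(min(np.sum(y == c) for c in classes))
        if Z.shape[1] >= min_class:
            raise SingularCovarianceError(
                spec.id,
                f"singular within-class covariance: {Z.shape[1]} features vs "
                f"smallest class of {min_class} samples",
            )

    try:
        if spec.family == "pls":
            k = min(spec.n_components, Z.shape[0] - 1, Z.shape[1])
            est = PLSRegression(n_components=k)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Z, y01)
            neg = [c for c in classes if c != pos][0]
            return FittedClassifier(spec, classes, pos, X.shape[1], reducer, est, (neg, pos))
        est = _build_estimator(spec, Z.shape[1], seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=UserWarning)
            est.fit(Z, y)
    except AdapterFitError:
        raise
    except Exception as exc:  # singularities, solver failures, ...
        raise AdapterFitError(spec.id, f"{type(exc).__name__}: {exc}") from exc
    return FittedClassifier(spec, classes, pos, X.shape[1], reducer, est)


# ---------------------------------------------------------------------------
# registry of the standard component set
# ---------------------------------------------------------------------------

_REGISTRY = {
    "SVM": dict(family="svm"),
    "SVM-linear": dict(family="svm", params={"kernel": "linear"}),
    "SVM-polynomial": dict(family="svm", params={"kernel": "poly"}),
    "SVM-radial": dict(family="svm", params={"kernel": "rbf"}),
    "SVM-sigmoid": dict(family="svm", params={"kernel": "sigmoid"}),
    "RF": dict(family="rf"),
    "PLR": dict(family="plr"),
    "LDA": dict(family="lda"),
    "QDA": dict(family="qda"),
    "PLS": dict(family="pls"),
    "PLS+LDA": dict(family="lda", reducer="pls"),
    "PLS+QDA": dict(family="qda", reducer="pls"),
    "PLS+RF": dict(family="rf", reducer="pls"),
    "PCA+LDA": dict(family="lda", reducer="pca"),
    "PCA+QDA": dict(family="qda", reducer="pca"),
}


def make_spec(name: str, **overrides) -> ClassifierSpec:
    """Build a registered spec by name, optionally overriding hyperparameters.

    Keyword overrides go into ``params`` except ``n_components`` and
    ``reducer`` which replace the spec fields.
    """
    try:
        base = dict(_REGISTRY[name])
    except KeyError:
        raise KeyError(
            f"unknown spec {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    params = dict(base.pop("params", {}))
    n_components = overrides.pop("n_components", 5)
    reducer = overrides.pop("reducer", base.pop("reducer", None))
    params.update(overrides)
    return ClassifierSpec(
        id=name,
        family=base["family"],
        reducer=reducer,
        n_components=n_components,
        params=params,
    )


def default_specs() -> tuple:
    """All registered spec names."""
    return tuple(_REGISTRY)


def threenorm_specs(rf_trees: int = 500) -> list[ClassifierSpec]:
    """The eight-component set used on the threenorm benchmark.

    SVM (radial, the classical default kernel), PLR, RF, PLS+RF, PLS+LDA,
    PLS+QDA, PCA+LDA and PLS-as-classifier, all with 5 latent components
    where a reducer is involved.
    """
    names = ["SVM", "PLR", "RF", "PLS+RF", "PLS+LDA", "PLS+QDA", "PCA+LDA", "PLS"]
    return [
        make_spec(n, n_trees=rf_trees) if "RF" in n else make_spec(n) for n in names
    ]


def svm_kernel_specs() -> list[ClassifierSpec]:
    """Four SVMs differing only in kernel: linear, polynomial, radial, sigmoid."""
    return [
        make_spec(n)
        for n in ("SVM-linear", "SVM-polynomial", "SVM-radial", "SVM-sigmoid")
    ]
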