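"""Synthetic benchmark generators and delimited-text dataset I/O.

Two simulation designs drive the benchmarks:

* ``threenorm`` — one class is an equal mixture of N((a,...,a), I) and
  N((-a,...,-a), I); the other is N((a,-a,a,-a,...), I), with a = 2/sqrt(d).
  A hard, nearly-symmetric problem where linear methods on raw coordinates
  struggle and supervised projection (PLS) helps.
* ``simulated_microarray`` — d independent unit-variance probes; a fraction
  of them (default 10% of d = 5000) have their case-group mean shifted by
  delta = 0.3, emulating differential expression against a null background.

Generators are seed-deterministic and record enough metadata to regenerate
the draw exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "threenorm",
    "simulated_microarray",
    "dominant_spec_toy",
    "load_csv",
]


@dataclass
class LabeledDataset:
    """An n x d feature matrix with binary labels and regeneration metadata."""

    X: np.ndarray
    y: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_frame(self, label: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"f{i}" for i in range(self.d)])
        df[label] = self.y
        return df

    def save_csv(self, path, label: str = "label") -> None:
        """Write samples-as-rows CSV plus a one-line JSON metadata sidecar."""
        path = Path(path)
        self.to_frame(label).to_csv(path, index=False)
        meta = dict(self.metadata)
        meta["label_column"] = label
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, default=str) + "\n"
        )


def load_csv(path, label: str = "label") -> LabeledDataset:
    """Read a samples-as-rows delimited file with a named label column."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if label not in df.columns:
        raise ValueError(f"label column {label!r} not found in {path}")
    y = df[label].to_numpy()
    X = df.drop(columns=[label]).to_numpy(dtype=float)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return LabeledDataset(X, y, meta)


def _rng_and_seed(rng):
    if isinstance(rng, np.random.Generator):
        return rng, None
    return np.random.default_rng(rng), rng


def threenorm(n: int = 200, d: int = 1000, a: float | None = None, rng=None) -> LabeledDataset:
    """Draw a balanced threenorm sample: n/2 per class, unit variances.

    Class 0 is the symmetric two-component mixture (mean +-(a,...,a) with
    equal probability per sample); class 1 has alternating-sign mean
    (a,-a,a,-a,...).  ``a`` defaults to 2/sqrt(d).
    """
    if n < 2 or d < 1:
        raise ValueError("need n >= 2 and d >= 1")
    rng, seed = _rng_and_seed(rng)
    if a is None:
        a = 2.0 / np.sqrt(d)
    n0 = n // 2
    n1 = n - n0
    X = rng.standard_normal((n, d))
    signs = rng.choice([-1.0, 1.0], size=n0)  # mixture component per class-0 row
    X[:n0] += signs[:, None] * a
    alt = a * (-1.0) ** np.arange(d)  # (a, -a, a, -a, ...)
    X[n0:] += alt
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    perm = rng.permutation(n)
    return LabeledDataset(
        X[perm],
        y[perm],
        metadata={"design": "threenorm", "n": n, "d": d, "a": a, "seed": seed},
    )


def simulated_microarray(
    n_cases: int = 50,
    n_controls: int = 50,
    d: int = 5000,
    frac_informative: float = 0.1,
    delta: float = 0.3,
    rng=None,
) -> LabeledDataset:
    """Independent-probe expression design with a planted mean shift.

    The first ``d * frac_informative`` probes are N(delta, 1) in cases and
    N(0, 1) in controls; the remainder are N(0, 1) in both groups.  Cases are
    labelled 1, controls 0; informative probe indices are recorded in the
    metadata.
    """
    k = d * frac_informative
    if abs(k - round(k)) > 1e-9 or k < 0:
        raise ValueError("d * frac_informative must be a non-negative integer")
    k = int(round(k))
    rng, seed = _rng_and_seed(rng)
    n = n_cases + n_controls
    X = rng.standard_normal((n, d))
    X[:n_cases, :k] += delta
    y = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    perm = rng.permutation(n)
    return LabeledDataset(
        X[perm],
        y[perm],
        metadata={
            "design": "simulated_microarray",
            "n_cases": n_cases,
            "n_controls": n_controls,
            "d": d,
            "frac_informative": frac_informative,
            "delta": delta,
            "informative_features": list(range(k)),
            "seed": seed,
        },
    )


def dominant_spec_toy(n: int = 100, rng=None) -> LabeledDataset:
    """Two-feature fixture where one linear direction carries all the signal.

    Feature 0 sits in +-[0.5, 1.5] with the sign equal to the class, leaving
    a margin of 1 around zero, so any sensible linear method is near-perfect;
    feature 1 is pure noise.  Used to verify that model selection picks a
    dominant component and that permutation importance singles out feature 0.
    """
    if n < 20:
        raise ValueError("need n >= 20")
    rng, seed = _rng_and_seed(rng)
    n1 = n // 2
    y = np.concatenate([np.zeros(n - n1, dtype=int), np.ones(n1, dtype=int)])
    sign = np.where(y == 1, 1.0, -1.0)
    x0 = sign * rng.uniform(0.5, 1.5, size=n)
    x1 = rng.standard_normal(n)
    X = np.column_stack([x0, x1])
    perm = rng.permutation(n)
    return LabeledDataset(
        X[perm], y[perm], metadata={"design": "dominant_spec_toy", "n": n, "seed": seed}
    )
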