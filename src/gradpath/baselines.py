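"""Baseline (reference point) construction for attribution.

Attribution explains a prediction relative to a counterfactual reference
x'. Group-agnostic choices (all-zero, or the decoder image of the zero
latent vector) need no class information; group-specific choices (random,
k-means, median, close) draw reference points from a designated baseline
class so attributions highlight what distinguishes the class of interest
from it. All selection happens in the original feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .models import LatentCodec

__all__ = [
    "BaselineSet",
    "zero_baseline",
    "encoded_zero_baseline",
    "random_baseline",
    "kmeans_baseline",
    "median_baseline",
    "close_baseline",
    "write_baselines",
    "read_baselines",
]

STRATEGIES = ("zero", "encoded_zero", "random", "kmeans", "median", "close")


@dataclass
class BaselineSet:
    """A set of reference points with provenance.

    ``per_sample`` is True only for the ``close`` strategy, whose points
    depend on the sample being explained; such sets carry the baseline-class
    matrix so points can be recomputed per sample.
    """

    points: np.ndarray
    strategy: str
    params: dict = field(default_factory=dict)
    per_sample: bool = False
    class_points: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.points.shape[0] < 1:
            raise ValueError("need at least one baseline point")

    @property
    def m(self) -> int:
        return self.points.shape[0]

    @property
    def p(self) -> int:
        return self.points.shape[1]

    def points_for(self, sample: np.ndarray) -> np.ndarray:
        """Baseline points to use for one sample (recomputed when close)."""
        if not self.per_sample:
            return self.points
        if self.class_points is None:
            raise ValueError("per-sample baseline lost its class points")
        return close_baseline(
            self.class_points, sample, self.params.get("m", 3)
        ).points


def zero_baseline(p: int) -> BaselineSet:
    """The classic all-zero reference point."""
    if p < 1:
        raise ValueError("feature space must have p >= 1")
    return BaselineSet(np.zeros((1, p)), "zero", {"p": p})


def encoded_zero_baseline(codec: LatentCodec) -> BaselineSet:
    """Decoder image of the all-zero latent vector.

    For an autoencoder trained on centered data this point sits near the
    training mean in feature space, so attributions against it capture
    deviation from "typical" rather than from literal zero.
    """
    point = np.atleast_2d(codec.decode(np.zeros((1, codec.q))))
    if not np.all(np.isfinite(point)):
        raise FloatingPointError("decoder produced non-finite baseline")
    return BaselineSet(point, "encoded_zero", {"q": codec.q})


def random_baseline(class_points: np.ndarray, m: int, seed: int) -> BaselineSet:
    """``m`` rows sampled uniformly without replacement from the class."""
    X = np.atleast_2d(np.asarray(class_points, dtype=float))
    n = X.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m={m} <= n={n}")
    idx = np.random.default_rng(seed).choice(n, size=m, replace=False)
    return BaselineSet(X[idx], "random", {"m": m, "seed": seed})


def kmeans_baseline(class_points: np.ndarray, k: int = 3, seed: int = 0) -> BaselineSet:
    """Centroids of a seeded k-means clustering of the baseline class.

    Default k=3: a handful of clusters suffices to represent subgroups of a
    baseline class without fragmenting it.
    """
    X = np.atleast_2d(np.asarray(class_points, dtype=float))
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k={k} <= n={n}")
    for attempt_seed in (seed, seed + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=attempt_seed).fit(X)
        if len(np.unique(km.labels_)) == k:
            return BaselineSet(km.cluster_centers_, "kmeans",
                               {"k": k, "seed": seed})
    raise RuntimeError(f"k-means produced an empty cluster for k={k}")


def median_baseline(class_points: np.ndarray, m: int = 3) -> BaselineSet:
    """The ``m`` class points closest to the coordinate-wise median.

    Guards interpretation against outliers in the baseline class; ties are
    broken by input order (stable sort).
    """
    X = np.atleast_2d(np.asarray(class_points, dtype=float))
    n = X.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m={m} <= n={n}")
    med = np.median(X, axis=0)
    d = np.linalg.norm(X - med, axis=1)
    order = np.argsort(d, kind="stable")
    return BaselineSet(X[order[:m]], "median", {"m": m})


def close_baseline(class_points: np.ndarray, sample: np.ndarray, m: int = 3) -> BaselineSet:
    """The near-but-not-nearest class points to one sample.

    Ranks class points by distance to the sample, discards the single
    closest (an outlier guard) and returns the next ``m``.
    """
    X = np.atleast_2d(np.asarray(class_points, dtype=float))
    n = X.shape[0]
    if n <= m:
        raise ValueError(f"need n={n} > m={m} (one point is discarded)")
    d = np.linalg.norm(X - np.asarray(sample, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")
    sel = BaselineSet(X[order[1 : m + 1]], "close", {"m": m}, per_sample=True)
    sel.class_points = X
    return sel


def write_baselines(path: str | Path, bs: BaselineSet) -> None:
    """TSV with a header comment recording strategy and params."""
    path = Path(path)
    params = " ".join(f"{k}={v}" for k, v in sorted(bs.params.items()))
    header = f"# strategy={bs.strategy} per_sample={bs.per_sample} {params}".rstrip()
    with path.open("w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, bs.points, delimiter="\t")


def read_baselines(path: str | Path) -> BaselineSet:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(item.split("=", 1) for item in header)
        points = np.loadtxt(fh, delimiter="\t", ndmin=2)
    strategy = meta.pop("strategy")
    per_sample = meta.pop("per_sample", "False") == "True"
    params = {}
    for k, v in meta.items():
        try:
            params[k] = int(v)
        except ValueError:
            params[k] = v
    return BaselineSet(points, strategy, params, per_sample=per_sample)
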