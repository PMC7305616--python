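"""Predictive-power evaluation of reported feature subsets.

If a method's significant features really carry the class signal, a fresh
model trained on only the top-s of them should approach full-feature
performance quickly, while equally sized random subsets should lag. The
subset curve makes that comparison explicit across increasing s.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .significance import MetaFeatureMap

__all__ = ["SubsetCurve", "feature_subset_curve", "holdout_binary_task"]


DEFAULT_MODEL = {"kind": "logistic", "C": 1.0, "max_iter": 2000}


def _fit_metric(
    X_train, y_train, X_test, y_test, model_config: dict, metric: str, seed: int
) -> float:
    cfg = {**DEFAULT_MODEL, **(model_config or {})}
    clf = LogisticRegression(
        C=cfg["C"], max_iter=cfg["max_iter"], random_state=seed
    )
    clf.fit(X_train, y_train)
    if metric == "accuracy":
        return float(accuracy_score(y_test, clf.predict(X_test)))
    if metric == "auc":
        return float(roc_auc_score(y_test, clf.decision_function(X_test)))
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class SubsetCurve:
    """Test metric at increasing feature-subset sizes, both arms."""

    table: pd.DataFrame  # subset_size, metric_significant, metric_random
    metric: str
    repeats: int
    seed: int

    def write(self, file: str | Path) -> None:
        file = Path(file)
        with file.open("w") as fh:
            fh.write(f"# metric={self.metric} repeats={self.repeats} seed={self.seed}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def feature_subset_curve(
    features: pd.DataFrame,
    labels: Sequence,
    ranked_features: Sequence[str],
    sizes: Sequence[int],
    model_config: dict | None = None,
    repeats: int = 20,
    seed: int = 0,
    metric: str = "auc",
    test_size: float = 0.2,
    mmap: MetaFeatureMap | None = None,
) -> SubsetCurve:
    """Retrain on top-s ranked vs random feature subsets and compare.

    A fresh classifier is trained per subset (no warm starts) on a fixed
    80/20 train/test split. Ranked names may be meta-features when a map is
    given; each subset then expands to all member features before training.
    The random arm draws ``repeats`` uniform subsets of the same size from
    the same universe and reports the mean metric.
    """
    ranked_features = list(ranked_features)
    universe = ranked_features if mmap is None else list(mmap.groups)
    missing = [f for f in ranked_features if mmap is None and f not in features.columns]
    if missing:
        raise ValueError(f"ranked feature(s) missing from dataset: {missing[:5]}")
    sizes = sorted(set(int(s) for s in sizes))
    if sizes[-1] > len(universe):
        raise ValueError(
            f"subset size {sizes[-1]} exceeds {len(universe)} available features"
        )
    y = np.asarray(labels)
    X_train, X_test, y_train, y_test = train_test_split(
        features, y, test_size=test_size, random_state=seed, stratify=y
    )

    def expand(names: Sequence[str]) -> list[str]:
        if mmap is None:
            return list(names)
        cols = []
        for g in names:
            cols.extend(m for m in mmap.groups[g] if m in features.columns)
        return cols

    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        cols = expand(ranked_features[:s])
        m_sig = _fit_metric(
            X_train[cols], y_train, X_test[cols], y_test, model_config, metric, seed
        )
        rand_vals = []
        for r in range(repeats):
            draw = [universe[i] for i in rng.choice(len(universe), s, replace=False)]
            cols_r = expand(draw)
            rand_vals.append(
                _fit_metric(
                    X_train[cols_r], y_train, X_test[cols_r], y_test,
                    model_config, metric, seed + r + 1,
                )
            )
        rows.append(
            {
                "subset_size": s,
                "metric_significant": m_sig,
                "metric_random": float(np.mean(rand_vals)),
                "metric_random_sd": float(np.std(rand_vals)),
            }
        )
    return SubsetCurve(pd.DataFrame(rows), metric, repeats, seed)


def holdout_binary_task(
    features: pd.DataFrame,
    labels: Sequence,
    class_a,
    class_b,
    feature_subset: Sequence[str],
    model_config: dict | None = None,
    seed: int = 0,
    test_size: float = 0.2,
) -> dict[str, float]:
    """Held-out accuracy and AUC-ROC of a binary classifier on a subset."""
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise ValueError("feature subset must be non-empty")
    labels = np.asarray(labels)
    mask = (labels == class_a) | (labels == class_b)
    X = features.loc[mask, feature_subset]
    y = (labels[mask] == class_a).astype(int)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
        raise ValueError("degenerate single-class split")
    return {
        "accuracy": _fit_metric(
            X_train, y_train, X_test, y_test, model_config, "accuracy", seed
        ),
        "auc": _fit_metric(
            X_train, y_train, X_test, y_test, model_config, "auc", seed
        ),
    }
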