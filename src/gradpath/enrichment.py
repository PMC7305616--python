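"""Hypergeometric enrichment of reported features against a known set.

A method that reports significant features is judged by how strongly its
top-ranked features overlap an independently constructed set of known
(biologically validated) features. The known set is built from the data
itself: per feature, a hypergeometric test for enrichment or depletion of
its presence in the positive class versus a negative class, admitting only
features passing a highly conservative -log10(p) threshold. Ranked
enrichment curves then report the overlap p-value at every prefix of the
method's ranked feature list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .attribution import AttributionMatrix
from .significance import MetaFeatureMap

__all__ = [
    "KnownFeatureSet",
    "hypergeom_p",
    "known_feature_set",
    "enrichment_curve",
    "rank_by_relative_attribution",
]


def hypergeom_p(overlap: int, selected: int, known: int, universe: int) -> float:
    """Upper-tail P[X >= overlap] for X ~ Hypergeom(universe, known, selected)."""
    if not (0 <= overlap <= min(selected, known)):
        raise ValueError("overlap must be <= min(selected, known) and >= 0")
    if selected > universe or known > universe:
        raise ValueError("selected and known must not exceed the universe")
    return float(hypergeom.sf(overlap - 1, universe, known, selected))


def _two_sided_hypergeom(k: int, N: int, K: int, n: int) -> float:
    """Two-sided p as 2 * min(upper tail, lower tail), capped at 1."""
    upper = hypergeom.sf(k - 1, N, K, n)
    lower = hypergeom.cdf(k, N, K, n)
    return float(min(1.0, 2.0 * min(upper, lower)))


@dataclass
class KnownFeatureSet:
    members: set[str]
    construction: pd.DataFrame = field(default_factory=pd.DataFrame)
    threshold: float = 20.0

    def __contains__(self, name: str) -> bool:
        return name in self.members

    def __len__(self) -> int:
        return len(self.members)


def known_feature_set(
    features: pd.DataFrame,
    labels: Sequence,
    positive_class,
    negative_class,
    threshold: float = 20.0,
    mmap: MetaFeatureMap | None = None,
) -> KnownFeatureSet:
    """Features whose presence is extremely skewed between two classes.

    Feature presence is binarized at value > 0 (continuous columns are
    binarized with a warning). Per feature, a two-sided hypergeometric test
    compares presence counts in the positive versus negative class; features
    with -log10(p) > threshold (default 20, a deliberately conservative
    cutoff) form the known set. With a meta-feature map, the known set is
    reported at meta-feature level with p = min over members.
    """
    labels = np.asarray(labels)
    pos = features[labels == positive_class]
    neg = features[labels == negative_class]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    X = pd.concat([pos, neg])
    non_binary = [
        c for c in X.columns if not set(np.unique(X[c])) <= {0.0, 1.0}
    ]
    if non_binary:
        warnings.warn(
            f"{len(non_binary)} continuous feature(s) binarized at > 0",
            stacklevel=2,
        )
    present = (X.to_numpy(dtype=float) > 0).astype(int)
    n_pos = len(pos)
    N = len(X)
    pvals = {}
    for j, col in enumerate(X.columns):
        K = int(present[:, j].sum())  # presence count in the universe
        k = int(present[:n_pos, j].sum())  # presence in the positive class
        pvals[col] = _two_sided_hypergeom(k, N, K, n_pos)

    construction = pd.DataFrame(
        {"p": pd.Series(pvals)}
    )
    construction["minus_log10_p"] = -np.log10(
        np.clip(construction["p"], 1e-320, None)
    )
    if mmap is not None:
        meta_p = {
            g: min(pvals[m] for m in members if m in pvals)
            for g, members in mmap.groups.items()
            if any(m in pvals for m in members)
        }
        construction = pd.DataFrame({"p": pd.Series(meta_p)})
        construction["minus_log10_p"] = -np.log10(
            np.clip(construction["p"], 1e-320, None)
        )
    members = set(construction.index[construction["minus_log10_p"] > threshold])
    return KnownFeatureSet(members, construction, threshold)


def rank_by_relative_attribution(
    meta_attrs: AttributionMatrix | pd.DataFrame,
) -> pd.Series:
    """Meta-features ordered by mean |attribution| share across the class.

    The relative attribution of a meta-feature is its mean absolute
    attribution over the class-of-interest samples normalized by the sum
    over all meta-features, giving a scale-free ranking weight.
    """
    df = meta_attrs.values if isinstance(meta_attrs, AttributionMatrix) else meta_attrs
    mean_abs = df.abs().mean(axis=0)
    rel = mean_abs / mean_abs.sum() if mean_abs.sum() > 0 else mean_abs
    return rel.sort_values(ascending=False, kind="stable")


def enrichment_curve(
    ranked: Sequence[str],
    known: KnownFeatureSet,
    universe: int,
) -> pd.DataFrame:
    """-log10 hypergeometric overlap p at every prefix of a ranked list.

    Row s reports the upper-tail p for the overlap of the top-s ranked
    features with the known set out of ``universe`` candidates; s=0 is
    defined as p=1.
    """
    ranked = list(ranked)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked list contains duplicates")
    if len(ranked) > universe:
        raise ValueError("ranked list larger than the universe")
    rows = [{"subset_size": 0, "overlap": 0, "minus_log10_p": 0.0}]
    overlap = 0
    for s, name in enumerate(ranked, start=1):
        overlap += name in known
        p = hypergeom_p(overlap, s, len(known), universe)
        rows.append(
            {
                "subset_size": s,
                "overlap": overlap,
                "minus_log10_p": float(-np.log10(max(p, 1e-320))),
            }
        )
    return pd.DataFrame(rows)
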