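"""Class-level significant features via a one-sided test on attributions.

Per-feature attributions are noisy at the single-sample level; the question
that matters is whether a (meta-)feature's absolute attribution is
systematically larger for a class of interest than for a similarly sized
random draw of events. For each meta-feature we compare the two sets with a
one-sided Welch t-test (positive tail) and Bonferroni-correct over the
number of meta-features tested.

Meta-features group highly correlated input features (e.g., variants of one
RNA-binding-protein motif) so attribution spread across near-duplicates is
pooled, not diluted: the attribution of a meta-feature is the sum of its
members' signed attributions, taken in absolute value at test time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, ttest_ind

from .attribution import AttributionMatrix

__all__ = [
    "MetaFeatureMap",
    "SignificanceTable",
    "build_meta_features",
    "meta_attributions",
    "significance_test",
    "sample_random_set",
    "write_meta_features",
    "read_meta_features",
]


@dataclass
class MetaFeatureMap:
    """Partition of feature names into named meta-features."""

    groups: dict[str, list[str]]  # meta-feature name -> member features
    linkage: dict = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for members in self.groups.values():
            for m in members:
                if m in seen:
                    raise ValueError(f"feature {m!r} appears in two groups")
                seen.add(m)
        self._feature_to_group = {
            m: g for g, members in self.groups.items() for m in members
        }

    @property
    def features(self) -> set[str]:
        return set(self._feature_to_group)

    def group_of(self, feature: str) -> str:
        return self._feature_to_group[feature]

    def __len__(self) -> int:
        return len(self.groups)


def build_meta_features(
    features: pd.DataFrame, threshold: float = 0.8
) -> MetaFeatureMap:
    """Single-linkage grouping of features with |Pearson r| >= threshold.

    Single linkage means groups are the connected components of the
    thresholded absolute-correlation graph, so chains A~B~C merge even when
    r(A, C) is weak. Constant columns have undefined correlation and are
    placed in singleton groups with a warning.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if features.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) placed in "
            "singleton groups",
            stacklevel=2,
        )
    live = np.flatnonzero(~constant)
    groups: dict[str, list[str]] = {}
    if live.size >= 2:
        C = np.abs(np.corrcoef(X[:, live], rowvar=False))
        np.fill_diagonal(C, 1.0)
        D = squareform(1.0 - np.clip(C, 0.0, 1.0), checks=False)
        Z = linkage(D, method="single")
        labels = fcluster(Z, t=1.0 - threshold, criterion="distance")
        # deterministic naming: order groups by first member's column order
        order: dict[int, list[int]] = {}
        for pos, lab in zip(live, labels):
            order.setdefault(lab, []).append(pos)
        for members in sorted(order.values(), key=lambda ms: ms[0]):
            groups[f"mf{len(groups):04d}"] = [names[i] for i in members]
    elif live.size == 1:
        groups[f"mf{len(groups):04d}"] = [names[live[0]]]
    for pos in np.flatnonzero(constant):
        groups[f"mf{len(groups):04d}"] = [names[pos]]
    return MetaFeatureMap(groups, {"threshold": threshold, "method": "single"})


def meta_attributions(
    attrs: AttributionMatrix, mmap: MetaFeatureMap
) -> AttributionMatrix:
    """Sum member features' signed attributions per meta-feature."""
    missing = set(attrs.feature_names) - mmap.features
    if missing:
        raise ValueError(f"unmapped feature column(s): {sorted(missing)[:5]}")
    cols = {}
    for g, members in mmap.groups.items():
        present = [m for m in members if m in attrs.values.columns]
        if present:
            cols[g] = attrs.values[present].sum(axis=1)
    values = pd.DataFrame(cols)
    prov = dict(attrs.provenance)
    prov["meta_features"] = len(cols)
    return AttributionMatrix(values, attrs.diagnostics, prov)


@dataclass
class SignificanceTable:
    """Per-meta-feature test results, sorted by adjusted p."""

    table: pd.DataFrame
    fwer: float

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def write(self, file: str | Path) -> None:
        file = Path(file)
        with file.open("w") as fh:
            fh.write(f"# fwer={self.fwer}\n")
            self.table.to_csv(fh, sep="\t", index_label="meta_feature")


def significance_test(
    G: AttributionMatrix | pd.DataFrame,
    R: AttributionMatrix | pd.DataFrame,
    fwer: float = 0.05,
    rank_variant: bool = False,
    abs_of_sum: bool = True,
) -> SignificanceTable:
    """One-sided Welch t-test per meta-feature, Bonferroni-corrected.

    ``G`` holds (meta-)attributions for the class of interest, ``R`` for a
    similarly sized random set of events. A meta-feature is significant when
    the mean absolute attribution in G exceeds that in R with adjusted
    p <= fwer. With ``rank_variant`` the absolute attributions are replaced
    by their within-column ranks across the pooled samples before testing.
    ``abs_of_sum=False`` switches the meta-attribution statistic from
    |sum of signed member attributions| to the sum of |member attributions|
    (only meaningful when called through a pipeline retaining members).
    """
    if not 0 < fwer <= 1:
        raise ValueError("fwer must lie in (0, 1]")
    gdf = G.values if isinstance(G, AttributionMatrix) else G
    rdf = R.values if isinstance(R, AttributionMatrix) else R
    if list(gdf.columns) != list(rdf.columns):
        raise ValueError("G and R must share meta-feature columns")
    if len(gdf) < 2 or len(rdf) < 2:
        raise ValueError("each set needs at least 2 rows")

    n_tests = gdf.shape[1]
    rows = []
    for col in gdf.columns:
        set_g = np.abs(gdf[col].to_numpy(dtype=float))
        set_r = np.abs(rdf[col].to_numpy(dtype=float))
        if rank_variant:
            pooled = rankdata(np.concatenate([set_g, set_r]))
            set_g, set_r = pooled[: len(set_g)], pooled[len(set_g):]
        if set_g.std() == 0 and set_r.std() == 0:
            t, p = 0.0, 1.0  # no variance anywhere: no evidence either way
        else:
            res = ttest_ind(set_g, set_r, equal_var=False, alternative="greater")
            t, p = float(res.statistic), float(res.pvalue)
        p_adj = min(1.0, p * n_tests)
        rows.append(
            {
                "mean_abs_G": float(set_g.mean()),
                "mean_abs_R": float(set_r.mean()),
                "t_stat": t,
                "p_raw": p,
                "p_adj": p_adj,
                "significant": p_adj <= fwer,
            }
        )
    table = pd.DataFrame(rows, index=gdf.columns).sort_values("p_adj")
    return SignificanceTable(table, fwer)


def sample_random_set(
    events: pd.DataFrame, size: int | None = None, seed: int = 0,
    class_size: int | None = None,
) -> pd.DataFrame:
    """Uniform without-replacement row sample across all classes.

    Default size matches the class of interest (``class_size``) so the two
    arms of the significance test are similarly sized.
    """
    n = len(events)
    size = size if size is not None else class_size
    if size is None:
        raise ValueError("either size or class_size must be given")
    if size > n:
        raise ValueError(f"size={size} exceeds the {n} available events")
    idx = np.random.default_rng(seed).choice(n, size=size, replace=False)
    return events.iloc[np.sort(idx)]


def write_meta_features(mmap: MetaFeatureMap, file: str | Path) -> None:
    """Two-column TSV: feature, group."""
    file = Path(file)
    with file.open("w") as fh:
        fh.write("feature\tgroup\n")
        for g, members in mmap.groups.items():
            for m in members:
                fh.write(f"{m}\t{g}\n")


def read_meta_features(file: str | Path) -> MetaFeatureMap:
    df = pd.read_csv(file, sep="\t")
    groups: dict[str, list[str]] = {}
    for feature, group in zip(df["feature"], df["group"]):
        groups.setdefault(str(group), []).append(str(feature))
    return MetaFeatureMap(groups, {"method": "external"})
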