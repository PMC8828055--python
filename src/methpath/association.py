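"""GC-sorted binned associations, genotype change statistics, correlation
matrices, PCA and group comparisons.

Per-TE enrichment values are noisy; sorting TEs by GC content and averaging
blocks of 100 turns scatter into readable trends. Genotype effects are
summarized as per-feature deltas and class-level fold changes of means.
Boxplot-style group contrasts use the two-sided Mann-Whitney rank-sum test
(the enrichment distributions are skewed), with a Benjamini-Hochberg column
alongside the raw p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

__all__ = [
    "BinnedAssociation",
    "GenotypeChange",
    "PCAResult",
    "gc_sorted_binning",
    "genotype_change",
    "correlation_matrix",
    "pca",
    "group_compare",
]


@dataclass
class BinnedAssociation:
    """Block means of two variables over the GC-sorted feature order."""

    table: pd.DataFrame  # columns bin, mean_gc, mean_x, mean_y, n
    ids: list[list[str]]
    bin_size: int


@dataclass
class GenotypeChange:
    delta: pd.Series  # per-feature b - a
    fold: dict[str, float]  # class -> mean(b)/mean(a); NaN when mean(a) == 0
    fold_defined: dict[str, bool]


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    column_means: pd.Series
    column_stds: pd.Series


def gc_sorted_binning(
    gc: pd.Series,
    values_x: pd.Series,
    values_y: pd.Series,
    bin_size: int = 100,
) -> BinnedAssociation:
    """Sort features by GC, cut into consecutive blocks, average per block.

    The sort is stable with feature id as tie-break, so results do not
    depend on input row order. Only the final block may be smaller than
    ``bin_size``; it is retained, not merged.
    """
    ids = gc.index
    if not (set(ids) == set(values_x.index) == set(values_y.index)):
        raise KeyError("gc, values_x and values_y must share the same feature ids")
    if len(ids) < bin_size:
        warnings.warn(
            f"only {len(ids)} features for bin_size {bin_size}; single bin",
            stacklevel=2,
        )
    order = sorted(ids, key=lambda i: (gc.loc[i], i))
    rows = []
    id_blocks: list[list[str]] = []
    for b, start in enumerate(range(0, len(order), bin_size)):
        block = order[start : start + bin_size]
        id_blocks.append(list(block))
        rows.append(
            {
                "bin": b,
                "mean_gc": float(gc.loc[block].mean()),
                "mean_x": float(values_x.loc[block].mean()),
                "mean_y": float(values_y.loc[block].mean()),
                "n": len(block),
            }
        )
    return BinnedAssociation(table=pd.DataFrame(rows), ids=id_blocks, bin_size=bin_size)


def genotype_change(
    values_a: pd.Series,
    values_b: pd.Series,
    class_labels: pd.Series | None = None,
) -> GenotypeChange:
    """Per-feature delta (b - a) and per-class fold change mean(b)/mean(a).

    With no ``class_labels`` a single fold over all features is returned
    under the key "all". A zero denominator leaves the fold NaN and flags it
    in ``fold_defined``.
    """
    if set(values_a.index) != set(values_b.index):
        raise KeyError("values_a and values_b must share the same feature ids")
    values_b = values_b.reindex(values_a.index)
    delta = values_b - values_a
    if class_labels is None:
        groups = {"all": list(values_a.index)}
    else:
        groups = {
            str(cls): list(class_labels.index[class_labels == cls])
            for cls in pd.unique(class_labels)
        }
    fold: dict[str, float] = {}
    defined: dict[str, bool] = {}
    for cls, members in groups.items():
        ma = float(values_a.loc[members].mean())
        mb = float(values_b.loc[members].mean())
        if ma == 0:
            fold[cls] = float("nan")
            defined[cls] = False
        else:
            fold[cls] = mb / ma
            defined[cls] = True
    return GenotypeChange(delta=delta, fold=fold, fold_defined=defined)


def correlation_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of matrix columns.

    Constant columns carry no correlation; they are excluded and listed in
    ``result.attrs["excluded_columns"]``. Requires at least 3 rows.
    """
    if len(m) < 3:
        raise ValueError("correlation requires at least 3 rows")
    stds = m.std(ddof=0)
    excluded = stds.index[stds == 0].tolist()
    if excluded:
        warnings.warn(f"excluding constant columns: {excluded}", stacklevel=2)
    kept = m.drop(columns=excluded)
    corr = pd.DataFrame(
        np.corrcoef(kept.to_numpy(dtype=float), rowvar=False),
        index=kept.columns,
        columns=kept.columns,
    )
    np.fill_diagonal(corr.values, 1.0)
    corr.attrs["excluded_columns"] = excluded
    return corr


def pca(m: pd.DataFrame, n_components: int) -> PCAResult:
    """Principal components of z-scored columns.

    Columns are standardized first because the features mix log-ratios,
    proportions and densities. Loadings are orthonormal; explained variances
    are non-increasing. Scores reconstruct the (standardized) input exactly
    when all components are retained.
    """
    if n_components > m.shape[1]:
        raise ValueError(
            f"n_components {n_components} exceeds column count {m.shape[1]}"
        )
    means = m.mean()
    stds = m.std(ddof=0)
    if (stds == 0).any():
        bad = stds.index[stds == 0].tolist()
        raise ValueError(f"constant columns cannot be z-scored: {bad}")
    z = (m - means) / stds
    sk = _SKPCA(n_components=n_components, svd_solver="full")
    scores = sk.fit_transform(z.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.index, columns=comp_names),
        loadings=pd.DataFrame(sk.components_.T, index=m.columns, columns=comp_names),
        explained_variance=sk.explained_variance_,
        explained_variance_ratio=sk.explained_variance_ratio_,
        column_means=means,
        column_stds=stds,
    )


def group_compare(
    values: pd.Series,
    group_labels: pd.Series,
    test: str = "ranksum",
) -> pd.DataFrame:
    """Pairwise two-sided group comparison.

    ``test`` is "ranksum" (Mann-Whitney U; the U statistic reported is for
    the first-named group, so {1,2,3} vs {4,5,6} gives U = 0) or "ttest"
    (Welch). Reports raw p-values and a Benjamini-Hochberg column.
    """
    if test not in {"ranksum", "ttest"}:
        raise ValueError("test must be 'ranksum' or 'ttest'")
    values = values.reindex(group_labels.index)
    groups = {}
    for cls in pd.unique(group_labels):
        vals = values[group_labels == cls].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"group {cls!r} is empty")
        groups[cls] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for a, b in combinations(groups, 2):
        if test == "ranksum":
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        else:
            res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(groups[a]),
                "n_b": len(groups[b]),
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = stats.false_discovery_control(out["p_value"].to_numpy())
    return out
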