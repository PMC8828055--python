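"""Threshold-and-test grouping rules for TEs and sRNA clusters.

The central rule assigns each transposable element to the methylation
pathway its CHH methylation depends on: a TE with more than 2% mCHH in wild
type is a CMT target if mCHH collapses below 2% in *cmt2* (chromomethylase
mutant) with a significant Fisher test, a DRM target if it collapses in
*drm2* (RdDM mutant), "both_depleted" if it collapses in both, and
intermediate otherwise. Companion rules classify MET1 dependence, group sRNA
clusters by H3K9 methylation and mCHH, and bin clusters by non-CG
methylation retention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable2x2",
    "PathwayClassLabel",
    "fisher_exact_two_sided",
    "classify_pathway",
    "classify_pathway_table",
    "classify_met1_dependence",
    "group_clusters_HL",
    "classify_mch_retention",
    "overlap_counts",
    "threshold_count",
]

PATHWAY_LABELS = ("CMT", "DRM", "both_depleted", "intermediate", "unclassified")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Methylated/unmethylated read counts for one TE in two genotypes."""

    meth_wt: int
    unmeth_wt: int
    meth_mut: int
    unmeth_mut: int

    def __post_init__(self):
        if min(self.meth_wt, self.unmeth_wt, self.meth_mut, self.unmeth_mut) < 0:
            raise ValueError("counts must be non-negative")

    def as_tuple(self):
        return (self.meth_wt, self.unmeth_wt, self.meth_mut, self.unmeth_mut)


@dataclass(frozen=True)
class PathwayClassLabel:
    label: str
    p_cmt2: float = float("nan")
    p_drm2: float = float("nan")
    reason: str = ""


_EXACT_TABLE_LIMIT = 400  # grand total above which log-space weights are used


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities not exceeding the observed table's. For small tables the
    weights are exact integers (products of binomial coefficients), so ties
    are handled exactly and the single final division is the only
    floating-point step; for large tables the same enumeration runs in log
    space with a tie tolerance far below any attainable p-value difference.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.as_tuple()
    else:
        (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("all-zero contingency table")
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    if n <= _EXACT_TABLE_LIMIT:
        weights = [
            math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)
        ]
        w_obs = weights[a - kmin]
        num = sum(w for w in weights if w <= w_obs)
        return num / math.comb(n, c1)
    from scipy.special import gammaln

    k = np.arange(kmin, kmax + 1)
    logw = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - c1 + k + 1)
    )
    log_obs = logw[a - kmin]
    keep = logw <= log_obs + 1e-9
    log_z = gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)
    return float(np.exp(logw[keep] - log_z).sum())


def classify_pathway(
    mchh_wt: float,
    mchh_cmt2: float,
    mchh_drm2: float,
    counts_wt: tuple[int, int],
    counts_cmt2: tuple[int, int],
    counts_drm2: tuple[int, int],
    te_length: int,
    alpha: float = 0.01,
    wt_min: float = 0.02,
    mut_max: float = 0.02,
    min_length: int = 200,
) -> PathwayClassLabel:
    """Assign one TE to CMT/DRM/both_depleted/intermediate/unclassified.

    ``counts_*`` are the TE's pooled (methylated, unmethylated) CHH read
    counts per genotype, the 2x2 rows of the Fisher test. Gates: the TE must
    be longer than ``min_length`` and have wild-type mCHH strictly above
    ``wt_min``; a mutant "loses" methylation when its level is below
    ``mut_max`` AND the wt-vs-mutant Fisher p is below ``alpha``.
    """
    if te_length <= min_length:
        return PathwayClassLabel("unclassified", reason="short")
    if any(math.isnan(x) for x in (mchh_wt,)):
        return PathwayClassLabel("unclassified", reason="missing_wt_level")
    if not mchh_wt > wt_min:
        return PathwayClassLabel("unclassified", reason="low_wt_mchh")
    if math.isnan(mchh_cmt2) or math.isnan(mchh_drm2):
        return PathwayClassLabel("unclassified", reason="missing_mutant_level")
    p_cmt2 = fisher_exact_two_sided(
        [[counts_wt[0], counts_wt[1]], [counts_cmt2[0], counts_cmt2[1]]]
    )
    p_drm2 = fisher_exact_two_sided(
        [[counts_wt[0], counts_wt[1]], [counts_drm2[0], counts_drm2[1]]]
    )
    lost_cmt2 = (mchh_cmt2 < mut_max) and (p_cmt2 < alpha)
    lost_drm2 = (mchh_drm2 < mut_max) and (p_drm2 < alpha)
    if lost_cmt2 and lost_drm2:
        label = "both_depleted"
    elif lost_cmt2:
        label = "CMT"
    elif lost_drm2:
        label = "DRM"
    else:
        label = "intermediate"
    return PathwayClassLabel(label, p_cmt2=p_cmt2, p_drm2=p_drm2)


def classify_pathway_table(
    df: pd.DataFrame,
    alpha: float = 0.01,
    wt_min: float = 0.02,
    mut_max: float = 0.02,
    min_length: int = 200,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Vector version of :func:`classify_pathway` over a per-TE table.

    Required columns: length, mCHH_wt, mCHH_cmt2, mCHH_drm2, meth_wt,
    unmeth_wt, meth_cmt2, unmeth_cmt2, meth_drm2, unmeth_drm2 (pooled CHH
    read counts). ``bh_correct=True`` applies Benjamini-Hochberg to each
    mutant's p-values before thresholding (off by default; the stated rule
    uses raw p-values).
    """
    labels = []
    for row in df.itertuples():
        lab = classify_pathway(
            row.mCHH_wt,
            row.mCHH_cmt2,
            row.mCHH_drm2,
            (row.meth_wt, row.unmeth_wt),
            (row.meth_cmt2, row.unmeth_cmt2),
            (row.meth_drm2, row.unmeth_drm2),
            row.length,
            alpha=alpha,
            wt_min=wt_min,
            mut_max=mut_max,
            min_length=min_length,
        )
        labels.append((row.Index, lab.label, lab.p_cmt2, lab.p_drm2, lab.reason))
    out = pd.DataFrame(
        labels, columns=["id", "label", "p_cmt2", "p_drm2", "reason"]
    ).set_index("id")
    if bh_correct:
        from scipy.stats import false_discovery_control

        for col, mut in (("p_cmt2", "cmt2"), ("p_drm2", "drm2")):
            mask = out[col].notna()
            q = out.loc[mask, col].copy()
            if len(q):
                out.loc[mask, f"q_{mut}"] = false_discovery_control(q.to_numpy())
        # re-threshold using q-values
        relab = []
        for row, (_, orig) in zip(out.itertuples(), out.iterrows()):
            if row.label in {"CMT", "DRM", "both_depleted", "intermediate"}:
                lost_c = (df.loc[row.Index, "mCHH_cmt2"] < mut_max) and (
                    row.q_cmt2 < alpha
                )
                lost_d = (df.loc[row.Index, "mCHH_drm2"] < mut_max) and (
                    row.q_drm2 < alpha
                )
                new = (
                    "both_depleted"
                    if lost_c and lost_d
                    else "CMT" if lost_c else "DRM" if lost_d else "intermediate"
                )
                relab.append(new)
            else:
                relab.append(row.label)
        out["label"] = relab
    return out


def classify_met1_dependence(mchh_wt: float, mchh_met1: float) -> str:
    """MET1 dependence of a TE's CHH methylation.

    dependent: wt >= 0.05 and met1 < 0.02; independent: wt >= 0.05 and
    met1 >= 0.05; anything else (including undefined levels) unassigned.
    """
    if math.isnan(mchh_wt) or math.isnan(mchh_met1):
        return "unassigned"
    if mchh_wt >= 0.05 and mchh_met1 < 0.02:
        return "dependent"
    if mchh_wt >= 0.05 and mchh_met1 >= 0.05:
        return "independent"
    return "unassigned"


def group_clusters_HL(
    h3k9me1: float,
    h3k9me2: float,
    mchh: float,
    scheme: str = "me1_and_me2",
) -> str:
    """Two-letter H/L group of an sRNA cluster.

    First letter: high H3K9me. Scheme "me1_and_me2" requires H3K9me1 > 0.5
    and H3K9me2 > 0; scheme "me2_only" requires H3K9me2 > 0. Second letter:
    high mCHH when mCHH > 0.05.
    """
    if scheme == "me1_and_me2":
        k9_high = (h3k9me1 > 0.5) and (h3k9me2 > 0)
    elif scheme == "me2_only":
        k9_high = h3k9me2 > 0
    else:
        raise ValueError("scheme must be 'me1_and_me2' or 'me2_only'")
    return ("H" if k9_high else "L") + ("H" if mchh > 0.05 else "L")


def classify_mch_retention(
    mch_wt: float,
    mch_mut: float,
    keep_thresh: float = 0.01,
    lose_thresh: float = 0.005,
) -> str:
    """kept / lost / intermediate non-CG methylation in a mutant.

    Only defined for clusters with wild-type mCH above ``keep_thresh``.
    """
    if not mch_wt > keep_thresh:
        raise ValueError(
            f"retention classes require wt mCH > {keep_thresh}, got {mch_wt}"
        )
    if mch_mut > keep_thresh:
        return "kept"
    if mch_mut < lose_thresh:
        return "lost"
    return "intermediate"


def overlap_counts(set_a: Iterable, set_b: Iterable) -> tuple[int, int, int]:
    """(|A only|, |A intersect B|, |B only|) for two id collections."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    return (len(a - inter), len(inter), len(b - inter))


def threshold_count(values, thresh: float) -> int:
    """Number of features with value strictly above ``thresh`` (NaN-safe)."""
    arr = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    return int(np.count_nonzero(arr > thresh))
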