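"""Cytosine context assignment and weighted methylation summaries.

Cytosines are classified by the two bases downstream of the C in strand
orientation: CG if the next base is G; CHG if the next base is H (A, C or T)
and the second is G; CHH otherwise. CHG splits into CCG and CWG (W = A or T)
and CHH into CWA and non-CWA by the identity of the H bases; mCH pools CHG
and CHH. A feature's level in a context is the weighted methylation level
(sum of methylated read counts over sum of total read counts across covered
sites), the convention that is robust to uneven bisulfite coverage. The
methylation density of a feature is the number of called methylated sites
per base pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CYTOSINE_COLUMNS, FeatureInterval, GenomeSequence

__all__ = [
    "MethylationSummary",
    "SiteCallParams",
    "assign_context",
    "annotate_contexts",
    "call_methylated_sites",
    "summarize_feature_methylation",
    "summarize_features_methylation",
    "genome_window_methylation",
]

CONTEXTS = ("CG", "CHG", "CHH", "CH")
SUBCONTEXTS = ("CG", "CCG", "CWG", "CWA", "nonCWA")

_A, _C, _G, _T = (np.uint8(ord(b)) for b in "ACGT")


@dataclass(frozen=True)
class SiteCallParams:
    """Parameters of the per-site methylation call used for densities.

    A covered site is called methylated when a one-sided binomial test of its
    methylated read count against the bisulfite non-conversion error rate
    rejects at ``alpha``.
    """

    error_rate: float = 0.005
    alpha: float = 0.01
    min_cov: int = 3


@dataclass
class MethylationSummary:
    """Per-feature weighted levels, site counts and methylated-site densities.

    ``levels[c]`` is NaN (undefined, distinct from 0) when the feature has no
    covered site in context ``c``.
    """

    feature_id: str
    length: int
    levels: dict[str, float] = field(default_factory=dict)
    site_counts: dict[str, int] = field(default_factory=dict)
    covered_counts: dict[str, int] = field(default_factory=dict)
    methylated_counts: dict[str, int] = field(default_factory=dict)
    densities: dict[str, float] = field(default_factory=dict)
    pooled_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def level(self, context: str) -> float:
        return self.levels[context]

    def density(self, context: str) -> float:
        return self.densities[context]


def assign_context(
    genome: GenomeSequence, chrom: str, pos: int, strand: str
) -> tuple[str, str]:
    """Context and subcontext of the cytosine at (chrom, pos, strand).

    The base must read C on the given strand (G on the plus strand for a
    minus-strand cytosine). Returns ("undetermined", "undetermined") when the
    two downstream bases run off the chromosome or contain N.
    """
    seq = genome[chrom]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[pos]!r}, not C")
        tri = seq[pos : pos + 3]
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {seq[pos]!r}, not G on + strand")
        tri = _revcomp(seq[max(pos - 2, 0) : pos + 1])
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    from .io import context_from_trinucleotide

    return context_from_trinucleotide(tri)


def _revcomp(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGTN", "TGCAN"))


def _context_arrays(b1: np.ndarray, b2: np.ndarray):
    """Vectorized context/subcontext codes from downstream base arrays."""
    valid = np.isin(b1, (_A, _C, _G, _T)) & np.isin(b2, (_A, _C, _G, _T))
    is_cg = b1 == _G
    is_chg = ~is_cg & (b2 == _G)
    is_chh = ~is_cg & ~is_chg
    context = np.where(is_cg, "CG", np.where(is_chg, "CHG", "CHH"))
    w1 = (b1 == _A) | (b1 == _T)
    sub = np.where(
        is_cg,
        "CG",
        np.where(
            is_chg,
            np.where(b1 == _C, "CCG", "CWG"),
            np.where(w1 & (b2 == _A), "CWA", "nonCWA"),
        ),
    )
    return context, sub, valid


def annotate_contexts(
    genome: GenomeSequence,
    regions: Sequence[FeatureInterval] | None = None,
) -> pd.DataFrame:
    """Table of every unambiguous cytosine site with context and subcontext.

    Both strands are scanned; a minus-strand site is a G on the plus strand.
    Sites whose downstream dinucleotide is off-end or contains N are omitted.
    When ``regions`` is given only sites inside those intervals are returned.
    Columns: chrom, pos, strand, context, subcontext.
    """
    frames = []
    for chrom in genome.keys():
        arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        n = len(arr)
        # plus strand: C with two downstream bases to the right
        pos_p = np.flatnonzero(arr[: n - 2] == _C)
        ctx_p, sub_p, ok_p = _context_arrays(arr[pos_p + 1], arr[pos_p + 2])
        pos_p, ctx_p, sub_p = pos_p[ok_p], ctx_p[ok_p], sub_p[ok_p]
        # minus strand: G with two downstream bases to the left (complemented)
        pos_m = np.flatnonzero(arr[2:] == _G) + 2
        comp = np.zeros(256, dtype=np.uint8)
        for x, y in zip(b"ACGT", b"TGCA"):
            comp[x] = y
        ctx_m, sub_m, ok_m = _context_arrays(comp[arr[pos_m - 1]], comp[arr[pos_m - 2]])
        pos_m, ctx_m, sub_m = pos_m[ok_m], ctx_m[ok_m], sub_m[ok_m]
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.concatenate([pos_p, pos_m]),
                "strand": np.concatenate(
                    [np.full(len(pos_p), "+"), np.full(len(pos_m), "-")]
                ),
                "context": np.concatenate([ctx_p, ctx_m]),
                "subcontext": np.concatenate([sub_p, sub_m]),
            }
        ).sort_values(["pos", "strand"], kind="stable", ignore_index=True)
        if regions is not None:
            keep = np.zeros(len(df), dtype=bool)
            p = df["pos"].to_numpy()
            for r in regions:
                if r.chrom == chrom:
                    keep |= (p >= r.start) & (p < r.end)
            df = df[keep].reset_index(drop=True)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "subcontext"])
    return pd.concat(frames, ignore_index=True)


def call_methylated_sites(
    records: pd.DataFrame, params: SiteCallParams = SiteCallParams()
) -> np.ndarray:
    """Boolean per-record methylation call for density computation.

    One-sided binomial test of count_meth out of coverage against the
    non-conversion error rate; requires coverage >= ``params.min_cov``.
    """
    cm = records["count_meth"].to_numpy(dtype=np.int64)
    cov = cm + records["count_unmeth"].to_numpy(dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.binom.sf(cm - 1, np.maximum(cov, 1), params.error_rate)
    return (cov >= params.min_cov) & (cm > 0) & (p < params.alpha)


def _summarize_slice(
    sub: pd.DataFrame,
    is_meth: np.ndarray,
    feature: FeatureInterval,
    min_cov: int,
) -> MethylationSummary:
    ctx = sub["context"].to_numpy()
    cm = sub["count_meth"].to_numpy(dtype=np.int64)
    cu = sub["count_unmeth"].to_numpy(dtype=np.int64)
    cov = cm + cu
    covered = cov >= min_cov
    out = MethylationSummary(feature_id=feature.id, length=feature.length)
    for c in CONTEXTS:
        mask = (ctx == "CHG") | (ctx == "CHH") if c == "CH" else ctx == c
        n_sites = int(mask.sum())
        covd = mask & covered
        n_cov = int(covd.sum())
        tot_m = int(cm[covd].sum())
        tot_u = int(cu[covd].sum())
        n_meth = int((mask & is_meth).sum())
        out.site_counts[c] = n_sites
        out.covered_counts[c] = n_cov
        out.methylated_counts[c] = n_meth
        out.pooled_counts[c] = (tot_m, tot_u)
        out.levels[c] = tot_m / (tot_m + tot_u) if n_cov > 0 else float("nan")
        out.densities[c] = n_meth / feature.length
    return out


def summarize_feature_methylation(
    records: pd.DataFrame,
    feature: FeatureInterval,
    min_cov: int = 3,
    site_call: SiteCallParams = SiteCallParams(),
) -> MethylationSummary:
    """Weighted levels, counts and densities of one feature.

    ``records`` is the cytosine table (see :data:`methpath.io.CYTOSINE_COLUMNS`).
    A feature with no overlapping records yields an all-undefined summary.
    """
    return summarize_features_methylation([feature], records, min_cov, site_call)[
        feature.id
    ]


def summarize_features_methylation(
    features: Sequence[FeatureInterval],
    records: pd.DataFrame,
    min_cov: int = 3,
    site_call: SiteCallParams = SiteCallParams(),
) -> dict[str, MethylationSummary]:
    """Vectorized :func:`summarize_feature_methylation` over many features."""
    out: dict[str, MethylationSummary] = {}
    by_chrom: dict[str, pd.DataFrame] = {}
    calls: dict[str, np.ndarray] = {}
    if len(records):
        records = records.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
        for chrom, grp in records.groupby("chrom", sort=False):
            g = grp.reset_index(drop=True)
            by_chrom[chrom] = g
            calls[chrom] = call_methylated_sites(g, site_call)
    empty = records.iloc[0:0] if len(records) else pd.DataFrame(columns=CYTOSINE_COLUMNS)
    for f in features:
        grp = by_chrom.get(f.chrom)
        if grp is None:
            out[f.id] = _summarize_slice(empty, np.zeros(0, bool), f, min_cov)
            continue
        pos = grp["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [f.start, f.end])
        out[f.id] = _summarize_slice(
            grp.iloc[lo:hi], calls[f.chrom][lo:hi], f, min_cov
        )
    return out


def summaries_to_frame(summaries: dict[str, MethylationSummary]) -> pd.DataFrame:
    """Flatten summaries to one row per feature (columns mCG, ..., d_CH, ...)."""
    rows = []
    for fid, s in summaries.items():
        row: dict[str, object] = {"id": fid, "length": s.length}
        for c in CONTEXTS:
            row[f"m{c}"] = s.levels[c]
            row[f"d_{c}"] = s.densities[c]
            row[f"n_sites_{c}"] = s.site_counts[c]
            row[f"n_covered_{c}"] = s.covered_counts[c]
            row[f"n_meth_{c}"] = s.methylated_counts[c]
            row[f"meth_reads_{c}"] = s.pooled_counts[c][0]
            row[f"unmeth_reads_{c}"] = s.pooled_counts[c][1]
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def genome_window_methylation(
    records: pd.DataFrame,
    window_bp: int,
    step_bp: int,
    min_cov: int = 1,
) -> dict[str, pd.DataFrame]:
    """Per-context weighted level in sliding genomic windows.

    Returns one (chrom, start, end, value) track per context; windows with no
    covered site are omitted rather than reported as zero.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("require window_bp >= step_bp >= 1")
    tracks: dict[str, list] = {c: [] for c in CONTEXTS}
    if not len(records):
        return {c: pd.DataFrame(columns=["chrom", "start", "end", "value"]) for c in CONTEXTS}
    records = records.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
    for chrom, grp in records.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        cm = grp["count_meth"].to_numpy(dtype=np.int64)
        cu = grp["count_unmeth"].to_numpy(dtype=np.int64)
        covered = (cm + cu) >= min_cov
        ctx = grp["context"].to_numpy()
        last = int(pos.max())
        for c in CONTEXTS:
            cmask = ((ctx == "CHG") | (ctx == "CHH")) if c == "CH" else ctx == c
            m = cmask & covered
            p_sel, cm_sel, cu_sel = pos[m], cm[m], cu[m]
            if not len(p_sel):
                continue
            for w0 in range(0, last + 1, step_bp):
                lo, hi = np.searchsorted(p_sel, [w0, w0 + window_bp])
                if hi > lo:
                    tm, tu = cm_sel[lo:hi].sum(), cu_sel[lo:hi].sum()
                    tracks[c].append((chrom, w0, w0 + window_bp, tm / (tm + tu)))
    return {
        c: pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        for c, rows in tracks.items()
    }
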