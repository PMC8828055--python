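"""Size-selected sRNA quantification and ChIP/input enrichment.

24-nt (or 21-nt, or all 18-28 nt) small-RNA abundance is expressed as rpkm
normalized to the library's total 18-28 nt mapped fragments. ChIP enrichment
is log2(ChIP/input) on identical bins after (optionally) subsampling the
input library to a fixed fraction of the ChIP read total and depth-scaling
both tracks to equal totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FeatureInterval, GenomeSequence, SizedReadSet

__all__ = [
    "EnrichmentTrack",
    "srna_rpkm",
    "chip_log2_ratio",
    "bin_reads",
    "count_overlaps",
    "mean_track_over_features",
]

VALUE_KINDS = {"rpkm", "log2ratio", "raw"}


@dataclass
class EnrichmentTrack:
    """Binned genomic values tagged with what they are (rpkm/log2ratio/raw)."""

    bins: pd.DataFrame  # columns chrom, start, end, value
    value_kind: str

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if len(s) > 1 and (np.any(np.diff(s) < 0) or np.any(e[:-1] > s[1:])):
                raise ValueError(f"bins unsorted or overlapping on {chrom}")


def _select_size(reads: SizedReadSet, size_class) -> SizedReadSet:
    if isinstance(size_class, str):
        if size_class == "18-28":
            return reads.select_length(18, 28)
        size_class = int(size_class)
    if isinstance(size_class, (tuple, list)):
        return reads.select_length(size_class[0], size_class[1])
    return reads.select_length(int(size_class))


def count_overlaps(
    reads: SizedReadSet,
    features: Sequence[FeatureInterval],
    overlap_mode: str = "any",
) -> np.ndarray:
    """Reads per feature. "any" counts a read if >= 1 bp intersects the
    feature; "midpoint" requires the read midpoint inside it."""
    if overlap_mode not in {"any", "midpoint"}:
        raise ValueError("overlap_mode must be 'any' or 'midpoint'")
    counts = np.zeros(len(features), dtype=np.int64)
    chroms = np.asarray(reads.chrom)
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        if overlap_mode == "midpoint":
            mids = np.sort(reads.midpoint[m])
            for i, f in enumerate(features):
                if f.chrom == chrom:
                    lo, hi = np.searchsorted(mids, [f.start, f.end])
                    counts[i] = hi - lo
        else:
            starts = np.sort(reads.start[m])
            ends = np.sort(reads.end[m])
            for i, f in enumerate(features):
                if f.chrom == chrom:
                    # overlap iff read.start < f.end and read.end > f.start
                    n_before_end = np.searchsorted(starts, f.end, side="left")
                    n_ending_early = np.searchsorted(ends, f.start, side="right")
                    counts[i] = n_before_end - n_ending_early
    return counts


def srna_rpkm(
    reads: SizedReadSet,
    features: Sequence[FeatureInterval],
    size_class=24,
    overlap_mode: str = "any",
) -> pd.Series:
    """Per-feature rpkm of the chosen size class.

    rpkm(f) = overlapping size-class reads / (length(f)/1000)
              / (total 18-28 nt reads / 1e6).
    """
    total = reads.total_18_28
    if total == 0:
        raise ValueError("no mappable sRNA: total 18-28 nt read count is zero")
    sel = _select_size(reads, size_class)
    counts = count_overlaps(sel, features, overlap_mode=overlap_mode)
    lengths = np.array([f.length for f in features], dtype=float)
    vals = counts / (lengths / 1000.0) / (total / 1e6)
    return pd.Series(vals, index=[f.id for f in features], name="rpkm")


def bin_reads(
    reads: SizedReadSet,
    chrom_sizes: dict[str, int],
    bin_bp: int,
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Read counts in fixed bins tiling each chromosome (chrom,start,end,count)."""
    if anchor not in {"midpoint", "five_prime"}:
        raise ValueError("anchor must be 'midpoint' or 'five_prime'")
    frames = []
    chroms = np.asarray(reads.chrom)
    points = reads.midpoint if anchor == "midpoint" else reads.five_prime
    for chrom, size in chrom_sizes.items():
        edges = np.arange(0, size + bin_bp, bin_bp)
        pts = points[chroms == chrom]
        counts, _ = np.histogram(pts, bins=edges)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": edges[:-1],
                    "end": np.minimum(edges[1:], size),
                    "count": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def chip_log2_ratio(
    chip: pd.DataFrame,
    input_: pd.DataFrame,
    input_fraction: float = 0.25,
    pseudocount: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> EnrichmentTrack:
    """log2(ChIP/input) per bin with seeded input subsampling.

    ``chip`` and ``input_`` are (chrom, start, end, count) tables over
    identical bins. The input library is first subsampled without replacement
    to ``input_fraction`` x the ChIP read total (multivariate hypergeometric
    across bins), then scaled to the ChIP total before the pseudocounted
    ratio is taken.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    if not (
        chip["chrom"].tolist() == input_["chrom"].tolist()
        and (chip["start"].to_numpy() == input_["start"].to_numpy()).all()
        and (chip["end"].to_numpy() == input_["end"].to_numpy()).all()
    ):
        raise ValueError("chip and input bins differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = chip["count"].to_numpy(dtype=np.int64)
    i = input_["count"].to_numpy(dtype=np.int64)
    chip_total = int(c.sum())
    input_total = int(i.sum())
    if input_total == 0:
        raise ValueError("empty input library")
    n_sample = int(round(input_fraction * chip_total))
    if n_sample < 1:
        raise ValueError("input_fraction yields fewer than one input read")
    if n_sample >= input_total:
        sub = i.copy()
    else:
        sub = rng.multivariate_hypergeometric(i, n_sample)
    sub_total = sub.sum()
    scale = chip_total / sub_total if sub_total > 0 else 0.0
    with np.errstate(divide="ignore"):
        value = np.log2((c + pseudocount) / (sub * scale + pseudocount))
    bins = chip[["chrom", "start", "end"]].copy()
    bins["value"] = value
    return EnrichmentTrack(bins=bins, value_kind="log2ratio")


def mean_track_over_features(
    track: EnrichmentTrack | pd.DataFrame,
    features: Sequence[FeatureInterval],
) -> pd.Series:
    """Coverage-weighted mean track value over each feature interval."""
    bins = track.bins if isinstance(track, EnrichmentTrack) else track
    out = np.full(len(features), np.nan)
    for chrom, grp in bins.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        v = grp["value"].to_numpy(dtype=float)
        for idx, f in enumerate(features):
            if f.chrom != chrom:
                continue
            lo = np.searchsorted(e, f.start, side="right")
            hi = np.searchsorted(s, f.end, side="left")
            if hi <= lo:
                continue
            ov = np.minimum(e[lo:hi], f.end) - np.maximum(s[lo:hi], f.start)
            ov = np.clip(ov, 0, None).astype(float)
            if ov.sum() > 0:
                out[idx] = float(np.average(v[lo:hi], weights=ov))
    return pd.Series(out, index=[f.id for f in features])
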