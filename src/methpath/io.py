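"""Readers and writers for the interval, methylation and read formats the
pipeline consumes.

All internal coordinates are 0-based half-open; conversion from 1-based
conventions (GFF3, cytosine reports) happens here and only here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureInterval",
    "SizedReadSet",
    "GenomeSequence",
    "read_features",
    "write_features",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_bedgraph",
    "write_bedgraph",
    "read_sized_reads",
    "write_sized_reads",
    "CYTOSINE_COLUMNS",
]

#: Column order of the per-cytosine methylation table used throughout.
CYTOSINE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context",
    "subcontext",
    "count_meth",
    "count_unmeth",
]

_CONTEXTS = {"CG", "CHG", "CHH"}


@dataclass(frozen=True)
class FeatureInterval:
    """A genomic annotation (TE, gene, sRNA cluster, nucleosome dyad).

    Coordinates are 0-based half-open. ``feature_class`` carries an optional
    label such as a TE family or an assigned pathway class.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""
    feature_class: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.id!r}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"feature {self.id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_class(self, feature_class: str) -> "FeatureInterval":
        return replace(self, feature_class=feature_class)


def _check_unique_ids(features: Sequence[FeatureInterval]) -> None:
    seen: set[str] = set()
    for f in features:
        if f.id in seen:
            raise ValueError(f"duplicate feature id {f.id!r}")
        seen.add(f.id)


class SizedReadSet:
    """Aligned read intervals carrying read length, for size-selected sRNA.

    Stores parallel arrays (chrom, start, end, strand); ``length`` is always
    ``end - start``. ``total_18_28`` counts reads in the 18-28 nt window used
    as the rpkm normalizer. Multi-mapped reads, if present multiple times in
    the input, are counted once per reported alignment.
    """

    def __init__(self, chrom, start, end, strand=None):
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        if strand is None:
            strand = np.full(self.start.shape, "+", dtype=object)
        self.strand = np.asarray(strand, dtype=object)
        n = len(self.start)
        if not (len(self.chrom) == len(self.end) == len(self.strand) == n):
            raise ValueError("chrom/start/end/strand must have equal length")
        if np.any(self.end <= self.start):
            raise ValueError("zero- or negative-length read interval")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def length(self) -> np.ndarray:
        return self.end - self.start

    @property
    def total_18_28(self) -> int:
        ln = self.length
        return int(np.count_nonzero((ln >= 18) & (ln <= 28)))

    @property
    def five_prime(self) -> np.ndarray:
        """5' end position of each read (strand-aware)."""
        return np.where(np.asarray(self.strand) == "-", self.end - 1, self.start)

    @property
    def midpoint(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def select_length(self, lo: int, hi: int | None = None) -> "SizedReadSet":
        """Reads with length in [lo, hi] (hi defaults to lo)."""
        hi = lo if hi is None else hi
        m = (self.length >= lo) & (self.length <= hi)
        return SizedReadSet(self.chrom[m], self.start[m], self.end[m], self.strand[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "strand": self.strand,
                "length": self.length,
            }
        )


class GenomeSequence:
    """Uppercase per-chromosome nucleotide strings over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def keys(self):
        return self._seqs.keys()

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}


# ---------------------------------------------------------------------------
# features: BED6 / GFF3


def read_features(path: str | os.PathLike, fmt: str | None = None) -> list[FeatureInterval]:
    """Read BED6 or GFF3 annotations into :class:`FeatureInterval` records.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open;
    BED coordinates pass through. The format is taken from the extension
    unless ``fmt`` ("bed" or "gff3") is given.
    """
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "gff3" if ext in {".gff", ".gff3"} else "bed"
    if fmt not in {"bed", "gff3"}:
        raise ValueError(f"unknown feature format {fmt!r}")
    feats: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            cols = line.split("\t")
            try:
                if fmt == "bed":
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                    fid = cols[3] if len(cols) > 3 else f"feature_{lineno}"
                    strand = cols[5] if len(cols) > 5 else "."
                    fclass = None
                else:
                    if len(cols) < 8:
                        raise ValueError("fewer than 8 GFF3 columns")
                    chrom = cols[0]
                    start = int(cols[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(cols[4])
                    strand = cols[6] if cols[6] in {"+", "-"} else "."
                    attrs = dict(
                        kv.split("=", 1)
                        for kv in cols[8].split(";")
                        if "=" in kv
                    ) if len(cols) > 8 else {}
                    fid = attrs.get("ID", f"feature_{lineno}")
                    fclass = attrs.get("class") or cols[2] or None
                feats.append(
                    FeatureInterval(chrom, start, end, strand, fid, fclass)
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
    _check_unique_ids(feats)
    return feats


def write_features(
    features: Iterable[FeatureInterval], path: str | os.PathLike, fmt: str = "bed"
) -> None:
    """Write features as BED6 or GFF3 (inverse of :func:`read_features`)."""
    if fmt not in {"bed", "gff3"}:
        raise ValueError(f"unknown feature format {fmt!r}")
    with open(path, "w") as fh:
        for f in features:
            if fmt == "bed":
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")
            else:
                source = "methpath"
                ftype = f.feature_class or "feature"
                attrs = f"ID={f.id}"
                if f.feature_class:
                    attrs += f";class={f.feature_class}"
                fh.write(
                    f"{f.chrom}\t{source}\t{ftype}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# per-cytosine methylation reports

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def context_from_trinucleotide(tri: str) -> tuple[str, str]:
    """Context and subcontext from a cytosine's strand-oriented trinucleotide.

    ``tri`` is the cytosine plus the next two bases in 5'->3' orientation on
    the cytosine's strand. Returns ("undetermined", "undetermined") when any
    base is not in {A,C,G,T} or the string is shorter than 3.
    """
    tri = tri.upper()
    if len(tri) < 3 or any(b not in "ACGT" for b in tri[:3]) or tri[0] != "C":
        return "undetermined", "undetermined"
    n1, n2 = tri[1], tri[2]
    if n1 == "G":
        return "CG", "CG"
    if n2 == "G":
        return "CHG", ("CCG" if n1 == "C" else "CWG")
    if n1 in "AT" and n2 == "A":
        return "CHH", "CWA"
    return "CHH", "nonCWA"


def read_cytosine_report(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 7-column per-cytosine report into the internal cytosine table.

    Expected columns: chrom, pos (1-based), strand, count_meth, count_unmeth,
    context, trinucleotide. Positions are converted to 0-based; the context
    is recomputed from the trinucleotide and must agree with the stated one.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "tri"],
            dtype={"chrom": str, "strand": str, "context": str, "tri": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        return pd.DataFrame(columns=CYTOSINE_COLUMNS)
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        bad = df.index[(df["count_meth"] < 0) | (df["count_unmeth"] < 0)].tolist()
        raise ValueError(f"negative counts at rows {bad[:10]}")
    ctx_sub = df["tri"].map(context_from_trinucleotide)
    df["ctx_derived"] = [c for c, _ in ctx_sub]
    df["subcontext"] = [s for _, s in ctx_sub]
    mismatch = (df["ctx_derived"] != "undetermined") & (df["ctx_derived"] != df["context"])
    if mismatch.any():
        rows = (df.index[mismatch] + 1).tolist()
        raise ValueError(
            f"context/trinucleotide mismatch at rows {rows[:20]}"
            + ("..." if len(rows) > 20 else "")
        )
    out = df[df["ctx_derived"] != "undetermined"].copy()
    out["pos"] = out["pos"] - 1  # 1-based -> 0-based
    out["context"] = out["ctx_derived"]
    return out[CYTOSINE_COLUMNS].reset_index(drop=True)


def write_cytosine_report(records: pd.DataFrame, path: str | os.PathLike,
                          genome: GenomeSequence | None = None) -> None:
    """Write the internal cytosine table back to the 7-column report dialect.

    The trinucleotide column is reconstructed from ``genome`` when given,
    otherwise a canonical representative of the subcontext is written.
    """
    rep = {"CG": "CGN", "CCG": "CCG", "CWG": "CAG", "CWA": "CAA", "nonCWA": "CCA"}
    with open(path, "w") as fh:
        for row in records.itertuples(index=False):
            if genome is not None:
                seq = genome[row.chrom]
                if row.strand == "+":
                    tri = seq[row.pos : row.pos + 3]
                else:
                    tri = seq[max(row.pos - 2, 0) : row.pos + 1][::-1].translate(_COMPLEMENT)
            else:
                tri = rep[row.subcontext]
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{row.count_meth}\t"
                f"{row.count_unmeth}\t{row.context}\t{tri}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a (chrom, start, end, value) table as 4-column bedGraph.

    Bins must be sorted and non-overlapping within each chromosome. Values
    are printed with 6 significant digits, which the reader round-trips
    bit-exactly at that precision.
    """
    req = ["chrom", "start", "end", "value"]
    missing = [c for c in req if c not in track.columns]
    if missing:
        raise ValueError(f"track missing columns {missing}")
    for chrom, grp in track.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if np.any(np.diff(s) < 0) or np.any(e[:-1] > s[1:]):
            raise ValueError(f"bins unsorted or overlapping on {chrom}")
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    df = df[~df["chrom"].str.startswith(("track", "#"))].reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return df


# ---------------------------------------------------------------------------
# sized reads (BED)


def read_sized_reads(path: str | os.PathLike) -> SizedReadSet:
    """Read aligned read intervals from BED; length is taken as end - start."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            try:
                start, end = int(cols[1]), int(cols[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}") from exc
            if end <= start:
                raise ValueError(f"{path}: zero-length interval at line {lineno}")
            chroms.append(cols[0])
            starts.append(start)
            ends.append(end)
            strands.append(cols[5] if len(cols) > 5 else "+")
    return SizedReadSet(chroms, starts, ends, strands)


def write_sized_reads(reads: SizedReadSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c, s, e, st in zip(reads.chrom, reads.start, reads.end, reads.strand):
            fh.write(f"{c}\t{s}\t{e}\tread\t0\t{st}\n")
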