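"""Seeded synthetic epigenome generator.

Produces a toy genome with three TE classes and the statistical structure
the analysis modules assume, so the whole pipeline runs with no external
data:

* CMT-like TEs are long and GC-rich, DRM-like TEs short and AT-rich, with
  an intermediate class between them — the heterochromatic/euchromatic TE
  dichotomy in miniature.
* Nucleosome dyads tile each TE at a genotype-dependent repeat length
  (default 180 bp in wild type, 167 bp without linker histone H1) with
  Gaussian positioning jitter.
* Per-cytosine bisulfite calls follow a genotype x class x context
  methylation probability table with Poisson coverage, binomial read counts
  and a non-conversion error floor.
* 24-nt sRNA read 5' ends follow a per-bp intensity proportional to a
  class x genotype rate, redistributed within each TE toward linker DNA
  (between nucleosome core particles) by a configurable multiplier; losing
  H1 relocates sRNA production from AT-rich to GC-rich TEs.
* ChIP reads for H1/H3K9me1/H3K9me2 follow class-level enrichment ratios
  (H1 follows a logistic function of TE GC content) over a uniform input.

All numeric defaults are invented, documented values chosen to mirror the
qualitative genotype effects the analysis is meant to detect; they live in
one editable table (see ``default_config`` and ``data/default_sim.toml``).
Every output is a deterministic function of the seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence
from zlib import crc32

import numpy as np
import pandas as pd

from .io import CYTOSINE_COLUMNS, FeatureInterval, GenomeSequence, SizedReadSet
from .methylation import annotate_contexts

__all__ = [
    "TEClassConfig",
    "SimulationConfig",
    "SyntheticTruth",
    "default_config",
    "load_config",
    "build_genome",
    "simulate_methylome",
    "simulate_srna",
    "simulate_chip",
    "run_default_simulation",
]

TE_CLASSES = ("CMT", "DRM", "intermediate")
CORE_HALF = 73  # nucleosome core particle is 147 bp: dyad +/- 73


@dataclass(frozen=True)
class TEClassConfig:
    n: int
    length_range: tuple[int, int]
    gc_mean: float
    gc_sd: float = 0.04


# Invented default tables. Methylation probabilities are per genotype, per
# TE class, per context; sRNA rates are relative per-bp intensities; ChIP
# ratios are class enrichment over a uniform input.
_DEFAULT_METHYLATION = {
    "wt": {
        "CMT": {"CG": 0.85, "CHG": 0.55, "CHH": 0.10},
        "DRM": {"CG": 0.60, "CHG": 0.15, "CHH": 0.12},
        "intermediate": {"CG": 0.70, "CHG": 0.35, "CHH": 0.10},
    },
    "cmt2": {
        "CMT": {"CG": 0.85, "CHG": 0.55, "CHH": 0.0},
        "DRM": {"CG": 0.60, "CHG": 0.15, "CHH": 0.12},
        "intermediate": {"CG": 0.70, "CHG": 0.35, "CHH": 0.05},
    },
    "drm2": {
        "CMT": {"CG": 0.85, "CHG": 0.55, "CHH": 0.10},
        "DRM": {"CG": 0.60, "CHG": 0.05, "CHH": 0.0},
        "intermediate": {"CG": 0.70, "CHG": 0.30, "CHH": 0.05},
    },
    "h1": {
        "CMT": {"CG": 0.85, "CHG": 0.65, "CHH": 0.16},
        "DRM": {"CG": 0.60, "CHG": 0.15, "CHH": 0.08},
        "intermediate": {"CG": 0.70, "CHG": 0.40, "CHH": 0.12},
    },
    "c2c3": {
        "CMT": {"CG": 0.85, "CHG": 0.02, "CHH": 0.0},
        "DRM": {"CG": 0.60, "CHG": 0.10, "CHH": 0.12},
        "intermediate": {"CG": 0.70, "CHG": 0.10, "CHH": 0.05},
    },
    "h1c2c3": {
        "CMT": {"CG": 0.85, "CHG": 0.03, "CHH": 0.02},
        "DRM": {"CG": 0.60, "CHG": 0.10, "CHH": 0.10},
        "intermediate": {"CG": 0.70, "CHG": 0.12, "CHH": 0.08},
    },
    "met1": {
        "CMT": {"CG": 0.02, "CHG": 0.45, "CHH": 0.08},
        "DRM": {"CG": 0.02, "CHG": 0.12, "CHH": 0.10},
        "intermediate": {"CG": 0.02, "CHG": 0.25, "CHH": 0.06},
    },
    "h1met1": {
        "CMT": {"CG": 0.02, "CHG": 0.55, "CHH": 0.14},
        "DRM": {"CG": 0.02, "CHG": 0.12, "CHH": 0.08},
        "intermediate": {"CG": 0.02, "CHG": 0.30, "CHH": 0.10},
    },
}

_DEFAULT_SRNA_RATE = {
    "wt": {"CMT": 0.25, "DRM": 6.0, "intermediate": 1.0},
    "h1": {"CMT": 1.4, "DRM": 1.0, "intermediate": 0.25},
    "cmt2": {"CMT": 0.25, "DRM": 6.0, "intermediate": 1.0},
    "drm2": {"CMT": 0.25, "DRM": 5.0, "intermediate": 0.9},
    "c2c3": {"CMT": 0.3, "DRM": 6.0, "intermediate": 1.0},
    "h1c2c3": {"CMT": 1.2, "DRM": 1.2, "intermediate": 0.3},
    "met1": {"CMT": 0.3, "DRM": 5.0, "intermediate": 0.8},
    "h1met1": {"CMT": 1.6, "DRM": 2.0, "intermediate": 0.5},
}

_DEFAULT_CHIP = {
    "H3K9me1": {"CMT": 2.5, "DRM": 1.0, "intermediate": 1.6},
    "H3K9me2": {"CMT": 3.0, "DRM": 1.2, "intermediate": 2.0},
}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic epigenome (all defaults invented)."""

    genome_length: int = 2_000_000
    chrom_name: str = "chr1"
    background_gc: float = 0.36
    te_classes: dict[str, TEClassConfig] = field(
        default_factory=lambda: {
            "CMT": TEClassConfig(120, (1500, 4000), 0.44),
            "DRM": TEClassConfig(120, (300, 800), 0.36),
            "intermediate": TEClassConfig(60, (500, 1500), 0.40),
        }
    )
    min_gap: int = 200
    nrl: dict[str, int] = field(default_factory=lambda: {"wt": 180, "h1": 167})
    jitter_sd: float = 10.0
    methylation: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_METHYLATION)
    )
    coverage_mean: float = 12.0
    error_rate: float = 0.005  # bisulfite non-conversion
    srna_rate: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_SRNA_RATE))
    srna_depth: int = 150_000  # 24-nt reads per library
    background_21nt_fraction: float = 0.05
    srna_sigma: float = 0.5  # per-TE lognormal sd on sRNA rate
    linker_multiplier: float = 3.0
    chip_enrichment: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_CHIP))
    chip_sigma: float = 0.4  # per-TE lognormal sd on ChIP enrichment
    chip_depth: int = 200_000
    chip_fragment: int = 100
    # H1 occupancy as a logistic function of TE GC content
    h1_slope: float = 40.0
    h1_midpoint: float = 0.40
    h1_min_ratio: float = 0.8
    h1_max_ratio: float = 4.0

    def nrl_for(self, genotype: str) -> int:
        if genotype in self.nrl:
            return self.nrl[genotype]
        return self.nrl["h1"] if "h1" in genotype else self.nrl["wt"]

    def methylation_for(self, genotype: str) -> dict:
        if genotype not in self.methylation:
            raise KeyError(
                f"unknown genotype {genotype!r}; available: "
                f"{sorted(self.methylation)}"
            )
        return self.methylation[genotype]

    def srna_rate_for(self, genotype: str) -> dict:
        if genotype not in self.srna_rate:
            raise KeyError(
                f"unknown genotype {genotype!r}; available: {sorted(self.srna_rate)}"
            )
        return self.srna_rate[genotype]


@dataclass
class SyntheticTruth:
    """Generating parameters emitted alongside the data, never consumed by
    the analysis modules."""

    te_class: pd.Series  # id -> generating class
    te_gc: pd.Series  # id -> realized GC fraction
    nrl: dict[str, int]
    dyads: dict[str, list[FeatureInterval]]
    fold_config: dict[str, float]  # class -> configured h1/wt sRNA rate ratio
    expected_rpkm_fold: dict[str, float]  # class -> implied h1/wt rpkm fold
    seed: int


def default_config() -> SimulationConfig:
    return SimulationConfig()


def load_config(path) -> SimulationConfig:
    """Build a config from a TOML file; absent keys keep their defaults."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = SimulationConfig()
    simple = {
        "genome_length", "chrom_name", "background_gc", "min_gap", "jitter_sd",
        "coverage_mean", "error_rate", "srna_depth", "background_21nt_fraction",
        "srna_sigma", "linker_multiplier", "chip_sigma", "chip_depth",
        "chip_fragment", "h1_slope", "h1_midpoint", "h1_min_ratio", "h1_max_ratio",
    }
    for key, val in raw.items():
        if key in simple:
            setattr(cfg, key, val)
        elif key == "nrl":
            cfg.nrl.update({k: int(v) for k, v in val.items()})
        elif key == "te_classes":
            for cls, sub in val.items():
                cfg.te_classes[cls] = TEClassConfig(
                    n=int(sub["n"]),
                    length_range=tuple(sub["length_range"]),
                    gc_mean=float(sub["gc_mean"]),
                    gc_sd=float(sub.get("gc_sd", 0.04)),
                )
        elif key in {"methylation", "srna_rate", "chip_enrichment"}:
            table = getattr(cfg, key)
            for gk, sub in val.items():
                table.setdefault(gk, {})
                for ck, v in sub.items():
                    if isinstance(v, dict):
                        table[gk].setdefault(ck, {}).update(v)
                    else:
                        table[gk][ck] = v
        else:
            raise KeyError(f"unknown config key {key!r}")
    return cfg


def _child_seed(seed: int, *tags: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) % 2**31, *(crc32(t.encode()) for t in tags)])


def _rng(seed, *tags: str) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(_child_seed(seed, *tags))


# ---------------------------------------------------------------------------
# genome and annotations


def build_genome(
    cfg: SimulationConfig,
    seed: int,
    genotypes: Sequence[str] = ("wt", "h1"),
) -> tuple[GenomeSequence, list[FeatureInterval], dict[str, list[FeatureInterval]], SyntheticTruth]:
    """Genome sequence, non-overlapping TE annotations, per-genotype dyads
    and the ground truth, all deterministic under the seed."""
    rng = _rng(seed, "genome")
    chrom = cfg.chrom_name
    # sample TE lengths and per-TE GC, then place in a shuffled order
    te_specs = []
    for cls in TE_CLASSES:
        if cls not in cfg.te_classes:
            continue
        cc = cfg.te_classes[cls]
        lengths = rng.integers(cc.length_range[0], cc.length_range[1] + 1, cc.n)
        gcs = np.clip(rng.normal(cc.gc_mean, cc.gc_sd, cc.n), 0.2, 0.65)
        te_specs.extend(
            (cls, int(ln), float(gc)) for ln, gc in zip(lengths, gcs)
        )
    order = rng.permutation(len(te_specs))
    te_specs = [te_specs[i] for i in order]
    total_te = sum(ln for _, ln, _ in te_specs)
    n_gaps = len(te_specs) + 1
    free = cfg.genome_length - total_te - n_gaps * cfg.min_gap
    if free < 0:
        raise ValueError(
            f"cannot place {len(te_specs)} TEs ({total_te} bp) in a "
            f"{cfg.genome_length} bp genome; increase genome_length"
        )
    extra = rng.multinomial(free, np.full(n_gaps, 1.0 / n_gaps))
    # genome sequence: background GC everywhere, then per-TE GC
    base_codes = _draw_bases(rng, cfg.genome_length, cfg.background_gc)
    tes: list[FeatureInterval] = []
    pos = 0
    class_counters = {c: 0 for c in cfg.te_classes}
    for k, (cls, ln, gc) in enumerate(te_specs):
        pos += cfg.min_gap + int(extra[k])
        class_counters[cls] += 1
        fid = f"{cls}_te_{class_counters[cls]:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        base_codes[pos : pos + ln] = _draw_bases(rng, ln, gc)
        tes.append(FeatureInterval(chrom, pos, pos + ln, strand, fid, cls))
    seq = base_codes.tobytes().decode("ascii")
    genome = GenomeSequence({chrom: seq})
    # realized GC and dyads
    gc_real = {}
    for f in tes:
        sub = base_codes[f.start : f.end]
        gc_real[f.id] = float(
            np.count_nonzero((sub == ord("G")) | (sub == ord("C"))) / f.length
        )
    dyads: dict[str, list[FeatureInterval]] = {}
    for g in genotypes:
        nrl = cfg.nrl_for(g)
        drng = _rng(seed, "dyads", g)
        dyads[g] = _tile_dyads(tes, nrl, cfg.jitter_sd, drng)
    te_class = pd.Series({f.id: f.feature_class for f in tes}, name="te_class")
    fold_config = _fold_config(cfg)
    truth = SyntheticTruth(
        te_class=te_class,
        te_gc=pd.Series(gc_real, name="gc"),
        nrl={g: cfg.nrl_for(g) for g in genotypes},
        dyads=dyads,
        fold_config=fold_config,
        expected_rpkm_fold=_expected_rpkm_fold(cfg, tes),
        seed=int(seed),
    )
    return genome, tes, dyads, truth


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)
    return np.array(codes, dtype=np.uint8)


def _tile_dyads(
    tes: Sequence[FeatureInterval],
    nrl: int,
    jitter_sd: float,
    rng: np.random.Generator,
) -> list[FeatureInterval]:
    out = []
    for f in tes:
        grid = np.arange(f.start + nrl // 2, f.end - CORE_HALF, nrl)
        if not len(grid):
            continue
        jitter = np.rint(rng.normal(0, jitter_sd, len(grid))).astype(int)
        pos = np.clip(grid + jitter, f.start, f.end - 1)
        for k, p in enumerate(np.sort(pos)):
            out.append(
                FeatureInterval(f.chrom, int(p), int(p) + 1, "+", f"{f.id}_dyad_{k}")
            )
    return out


def _fold_config(cfg: SimulationConfig) -> dict[str, float]:
    if "h1" not in cfg.srna_rate or "wt" not in cfg.srna_rate:
        return {}
    return {
        cls: cfg.srna_rate["h1"][cls] / cfg.srna_rate["wt"][cls]
        for cls in cfg.srna_rate["wt"]
        if cfg.srna_rate["wt"][cls] > 0
    }


def _expected_rpkm_fold(
    cfg: SimulationConfig, tes: Sequence[FeatureInterval]
) -> dict[str, float]:
    """Implied h1/wt fold of class-mean rpkm, from config arithmetic only.

    rpkm is normalized within each library, so the implied fold is the rate
    ratio corrected by the ratio of total library intensity between the two
    genotypes.
    """
    if "h1" not in cfg.srna_rate or "wt" not in cfg.srna_rate:
        return {}
    area = {cls: 0.0 for cls in cfg.te_classes}
    for f in tes:
        area[f.feature_class] += f.length
    total = {
        g: sum(cfg.srna_rate[g][cls] * a for cls, a in area.items())
        for g in ("wt", "h1")
    }
    out = {}
    for cls in area:
        r_wt, r_h1 = cfg.srna_rate["wt"][cls], cfg.srna_rate["h1"][cls]
        if r_wt > 0 and total["h1"] > 0:
            out[cls] = (r_h1 / r_wt) * (total["wt"] / total["h1"])
    return out


# ---------------------------------------------------------------------------
# methylome


def simulate_methylome(
    genome: GenomeSequence,
    tes: Sequence[FeatureInterval],
    cfg: SimulationConfig,
    genotype: str,
    seed: int,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cytosine methylation table for one genotype (TE sites only).

    Coverage is Poisson(``coverage_mean``); methylated read counts are
    binomial at the configured probability raised by the non-conversion
    error floor. Pass a precomputed ``sites`` table (from
    :func:`methpath.methylation.annotate_contexts` over the TEs) to skip
    rescanning the genome.
    """
    table = cfg.methylation_for(genotype)
    if sites is None:
        sites = annotate_contexts(genome, regions=list(tes))
    rng = _rng(seed, "methylome", genotype)
    pos = sites["pos"].to_numpy()
    cls_of = _class_per_position(tes, pos, sites["chrom"].to_numpy())
    ctx = sites["context"].to_numpy()
    p = np.zeros(len(sites))
    for cls in cfg.te_classes:
        for context in ("CG", "CHG", "CHH"):
            m = (cls_of == cls) & (ctx == context)
            if m.any():
                p[m] = table[cls][context]
    p_obs = p + (1 - p) * cfg.error_rate
    cov = rng.poisson(cfg.coverage_mean, len(sites))
    meth = rng.binomial(cov, p_obs)
    out = sites[["chrom", "pos", "strand", "context", "subcontext"]].copy()
    out["count_meth"] = meth
    out["count_unmeth"] = cov - meth
    return out[CYTOSINE_COLUMNS]


def _class_per_position(
    tes: Sequence[FeatureInterval], pos: np.ndarray, chroms: np.ndarray
) -> np.ndarray:
    cls = np.full(len(pos), "", dtype=object)
    for f in tes:
        m = (chroms == f.chrom) & (pos >= f.start) & (pos < f.end)
        cls[m] = f.feature_class
    return cls


# ---------------------------------------------------------------------------
# sRNA


def _srna_intensity(
    genome_length: int,
    tes: Sequence[FeatureInterval],
    dyads: Sequence[FeatureInterval],
    rates: dict[str, float],
    effects: dict[str, float],
    linker_multiplier: float,
) -> np.ndarray:
    """Per-bp 24-nt sRNA intensity: class rate x per-TE effect, redistributed
    within each TE toward linker DNA (outside dyad +/- 73 bp cores), with the
    TE's total intensity held at rate x length x effect."""
    arr = np.zeros(genome_length)
    dyads_by_te: dict[str, list[int]] = {}
    for d in dyads:
        te_id = d.id.rsplit("_dyad_", 1)[0]
        dyads_by_te.setdefault(te_id, []).append(d.start)
    for f in tes:
        rate = rates[f.feature_class] * effects[f.id]
        if rate <= 0:
            continue
        seg = np.full(f.length, 1.0)
        centers = sorted(dyads_by_te.get(f.id, []))
        for d1, d2 in zip(centers, centers[1:]):
            lo = d1 + CORE_HALF + 1 - f.start
            hi = d2 - CORE_HALF - f.start
            if hi > lo:
                seg[max(lo, 0) : min(hi, f.length)] *= linker_multiplier
        seg *= rate * f.length / seg.sum()
        arr[f.start : f.end] = seg
    return arr


def simulate_srna(
    genome: GenomeSequence,
    tes: Sequence[FeatureInterval],
    dyads: Sequence[FeatureInterval],
    cfg: SimulationConfig,
    genotype: str,
    seed: int,
) -> SizedReadSet:
    """24-nt sRNA reads (plus ~5% 21-nt background) for one genotype."""
    rates = cfg.srna_rate_for(genotype)
    chrom = cfg.chrom_name
    glen = len(genome[chrom])
    rng = _rng(seed, "srna", genotype)
    effects = {
        f.id: float(np.exp(rng.normal(0.0, cfg.srna_sigma))) for f in tes
    }
    intensity = _srna_intensity(
        glen, tes, dyads, rates, effects, cfg.linker_multiplier
    )
    total_intensity = intensity.sum()
    if total_intensity <= 0:
        raise ValueError("zero total sRNA intensity; check rate table")
    p = intensity / total_intensity
    n24 = cfg.srna_depth
    pos24 = rng.choice(glen, size=n24, p=p)
    strand24 = np.where(rng.random(n24) < 0.5, "+", "-")
    n21 = int(round(n24 * cfg.background_21nt_fraction))
    pos21 = rng.integers(0, glen, n21)
    strand21 = np.where(rng.random(n21) < 0.5, "+", "-")
    starts, ends, strands = [], [], []
    for pos, strand, ln in ((pos24, strand24, 24), (pos21, strand21, 21)):
        s = np.where(strand == "+", pos, pos - (ln - 1))
        e = s + ln
        ok = (s >= 0) & (e <= glen)
        starts.append(s[ok])
        ends.append(e[ok])
        strands.append(strand[ok])
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    strand = np.concatenate(strands)
    return SizedReadSet(np.full(len(start), chrom, dtype=object), start, end, strand)


# ---------------------------------------------------------------------------
# ChIP


def simulate_chip(
    genome: GenomeSequence,
    tes: Sequence[FeatureInterval],
    cfg: SimulationConfig,
    mark: str,
    genotype: str,
    seed: int,
) -> tuple[SizedReadSet, SizedReadSet]:
    """(ChIP, input) read sets for one histone mark and genotype.

    Input is uniform over the genome at the same depth as ChIP. The ChIP
    intensity is the class enrichment ratio (for H1: a logistic function of
    the TE's realized GC content, flattened to 1 in h1-mutant genotypes),
    modulated by a per-TE lognormal effect.
    """
    if mark != "H1" and mark not in cfg.chip_enrichment:
        raise ValueError(
            f"unknown mark {mark!r}; available: H1, {sorted(cfg.chip_enrichment)}"
        )
    chrom = cfg.chrom_name
    glen = len(genome[chrom])
    rng = _rng(seed, "chip", mark, genotype)
    effects = np.exp(rng.normal(0.0, cfg.chip_sigma, len(tes)))
    intensity = np.ones(glen)
    seq = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
    for f, eff in zip(tes, effects):
        if mark == "H1":
            if "h1" in genotype:
                continue  # no linker histone left to pull down: flat track
            sub = seq[f.start : f.end]
            gc = np.count_nonzero((sub == ord("G")) | (sub == ord("C"))) / f.length
            logistic = 1.0 / (1.0 + np.exp(-cfg.h1_slope * (gc - cfg.h1_midpoint)))
            ratio = cfg.h1_min_ratio + (cfg.h1_max_ratio - cfg.h1_min_ratio) * logistic
        else:
            ratio = cfg.chip_enrichment[mark][f.feature_class]
        intensity[f.start : f.end] = ratio * eff
    frag = cfg.chip_fragment
    p = intensity[: glen - frag]
    p = p / p.sum()
    chip_pos = rng.choice(glen - frag, size=cfg.chip_depth, p=p)
    input_pos = rng.integers(0, glen - frag, cfg.chip_depth)
    chip = SizedReadSet(
        np.full(cfg.chip_depth, chrom, dtype=object), chip_pos, chip_pos + frag
    )
    inp = SizedReadSet(
        np.full(cfg.chip_depth, chrom, dtype=object), input_pos, input_pos + frag
    )
    return chip, inp


# ---------------------------------------------------------------------------
# one-call experiment


def run_default_simulation(
    seed: int,
    cfg: SimulationConfig | None = None,
    genotypes: Sequence[str] = ("wt", "h1", "cmt2", "drm2"),
    marks: Sequence[str] = ("H1", "H3K9me1", "H3K9me2"),
    with_chip: bool = True,
) -> dict:
    """Generate the default experiment: genome, TEs, dyads, methylomes and
    sRNA per genotype, and wild-type ChIP per mark. Returns a dict bundle."""
    cfg = cfg or default_config()
    genome, tes, dyads, truth = build_genome(cfg, seed, genotypes=("wt", "h1"))
    sites = annotate_contexts(genome, regions=tes)
    methylomes = {
        g: simulate_methylome(genome, tes, cfg, g, seed, sites=sites)
        for g in genotypes
        if g in cfg.methylation
    }
    srna = {}
    for g in genotypes:
        if g in cfg.srna_rate:
            dy = dyads["h1"] if "h1" in g else dyads["wt"]
            srna[g] = simulate_srna(genome, tes, dy, cfg, g, seed)
    chip = {}
    if with_chip:
        for mark in marks:
            chip[mark] = simulate_chip(genome, tes, cfg, mark, "wt", seed)
    return {
        "config": cfg,
        "genome": genome,
        "tes": tes,
        "dyads": dyads,
        "truth": truth,
        "sites": sites,
        "methylomes": methylomes,
        "srna": srna,
        "chip": chip,
    }
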