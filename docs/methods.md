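# Methods

## Scope and data model

All coordinates are 0-based half-open internally; GFF3 and cytosine-report
positions (1-based) are converted at the I/O boundary only. Cytosine records
carry strand, context (CG/CHG/CHH from the two downstream bases in strand
orientation) and subcontext (CCG/CWG inside CHG; CWA/non-CWA inside CHH,
W = A or T); sites whose downstream dinucleotide is off-end or contains N
are "undetermined" and excluded from every summary. Symmetric CG sites are
not pooled across strands: each strand's cytosine is its own site, matching
the granularity of per-cytosine reports. Reads arrive post-alignment as BED
intervals; multi-mapped reads present several times are counted once per
reported alignment (pre-filter the read set for unique-only counting).

## Methylation summaries

Feature levels are weighted (pooled-read) levels, Σmeth/Σtotal over covered
sites, not means of per-site fractions — the standard convention because it
is robust to uneven bisulfite coverage. A site counts as covered at ≥3 reads
(`min_cov`, configurable); contexts with no covered site yield an undefined
level (NaN), deliberately distinct from 0. Methylation **density** — called
methylated sites per bp — needs a per-site call: a covered site (≥3 reads)
is called methylated when a one-sided binomial test of its methylated count
against the bisulfite non-conversion error rate (default 0.005) rejects at
α = 0.01. Error rate, α and the coverage floor are parameters of
`SiteCallParams`.

## TE pathway classification

The TE universe keeps elements ≥250 bp; classification additionally gates at
length >200 bp (both filters are configurable and deliberately coexist).
A TE with wild-type mCHH strictly >0.02 is tested against each mutant: "lost"
means mutant mCHH <0.02 **and** two-sided Fisher p <0.01 on the 2×2 table of
pooled (methylated, unmethylated) CHH read counts, wild type vs mutant.
Loss in exactly one mutant gives CMT or DRM; loss in both gives the separate
`both_depleted` label (excluded from the CMT/DRM sets); loss in neither gives
`intermediate`. P-values are used raw, as the rule states; a
Benjamini–Hochberg variant is available but off by default. The Fisher
implementation enumerates the hypergeometric distribution with exact integer
weights (ties are exact) for grand totals ≤400 and runs the same enumeration
in log space (gammaln, relative tie tolerance 1e-9) above that, where pooled
per-TE read counts reach tens of thousands.

Companion rules implemented verbatim: MET1 dependence (dependent: wt ≥0.05
and met1 <0.02; independent: both ≥0.05; otherwise unassigned), sRNA-cluster
H/L groups (high H3K9me: H3K9me1 >0.5 and H3K9me2 >0, or H3K9me2 >0 alone
under the `me2_only` scheme; high mCHH: >0.05), and mCH retention in a
mutant (kept >0.01, lost <0.005, intermediate between), defined only for
clusters with wild-type mCH above the keep threshold.

## Coverage tracks

sRNA abundance of a size class (24-nt, 21-nt or the full 18–28 nt window) is
rpkm with the 18–28 nt library total as the per-million denominator, so the
normalizer is the same for every size class of a library. A read counts
toward a feature when ≥1 bp overlaps (`midpoint` mode available). ChIP
enrichment subsamples the input library without replacement (multivariate
hypergeometric across bins, seeded) to 25% of the ChIP read total, scales
the subsample to the ChIP total, and reports log2((chip+ψ)/(input+ψ)) with
pseudocount ψ = 0.5 to keep empty bins finite.

## Metaplots and phasing

Ends metaplots lay fixed bins from −flank to +flank around each feature's 5'
and 3' ends in strand orientation (minus-strand features flipped) and average
per offset; when the values are sRNA rpkm, bins above 200 rpkm are excluded
from the average so single hot loci cannot dominate. Dyad profiles count
24-nt read 5' ends (midpoint optional) in 10-bp bins over ±1000 bp around
each 1-bp dyad, convert to rpkm and average over dyads. The autocorrelation
is the mean-centered, biased (divide-by-n) sample estimator, normalized so
lag 0 = 1. The NRL estimate is the first local autocorrelation maximum in
the 100–300 bp range that clears the 95% white-noise band (1.96/√n).

Because the profile is binned at 10 bp, the discrete peak lag quantizes the
estimate to multiples of 10 bp, which is coarser than the repeat-length
difference the analysis cares about (~180 vs 167 bp), and the slowly decaying
correlation envelope can pull the discrete argmax down one bin. The
estimator therefore refines the peak by quadratic interpolation through the
maximum and its two neighbours (standard sub-bin peak localization);
`refine=False` restores the plain lag×bin estimate.

## Feature matrix and random forest

Rows are TEs; columns are per-context weighted levels and densities, any
supplied per-TE tracks (H1, H3K9me1/2, sRNA rpkm, ...), GC content, and
per-subcontext cytosine sequence densities computed from the genome (sites
per bp, both strands). Rows with an undefined methylation level are dropped
and reported. The classifier is a bagged decision-tree ensemble with
per-tree bootstrap and √p feature subsampling (scikit-learn's
RandomForestClassifier, 500 trees by default). The train/validation split is
50/50, stratified by class, and assigned by a seeded hash of feature ids so
results are independent of row order. The held-out error is reported (with
the out-of-bag error alongside); variable importance is reported both as
permutation accuracy decrease on the validation rows and as impurity
decrease.

## Association statistics

GC-sorted binning stably sorts features by GC (ties broken by id), cuts
consecutive blocks of 100 and averages per block; the final partial block is
retained. Genotype change reports per-feature deltas and class-level fold
changes of means (undefined when the denominator is 0). Correlation matrices
are Pearson, with constant columns excluded and reported. PCA z-scores
columns first (the features mix log-ratios, proportions and densities);
loadings are orthonormal and retained-rank reconstruction is exact. Group
comparisons use the two-sided Mann–Whitney U test (chosen for the skewed
enrichment distributions; Welch t by flag), with raw p-values plus a BH
column; the reported U is for the first-named group.

## Synthetic epigenome

The generator emulates the statistical structure the analysis assumes, on
one 2 Mb chromosome so full-pipeline tests finish in seconds. Every default
is an invented, documented number (see `data/default_sim.toml`), fixed as
the package's study conditions:

* **TE classes.** 120 CMT-like (1500–4000 bp, GC 0.44), 120 DRM-like
  (300–800 bp, GC 0.36), 60 intermediate (500–1500 bp, GC 0.40); per-TE GC
  drawn with sd 0.04, sequence bases i.i.d. at that GC; non-overlapping
  placement with ≥200 bp gaps.
* **Nucleosomes.** Dyads tile each TE at the genotype's repeat length
  (180 bp wild type, 167 bp h1-mutant backgrounds) with i.i.d. Gaussian
  positioning jitter (sd 10 bp) around the grid.
* **Methylomes.** Per-cytosine coverage ~ Poisson(12); methylated counts ~
  Binomial(coverage, p + (1−p)·0.005) with p from the genotype × class ×
  context table (wt, h1, cmt2, drm2, c2c3, h1c2c3, met1, h1met1). Only TE
  cytosines are emitted.
* **sRNA.** 150k 24-nt read 5' ends per library drawn from a per-bp
  intensity: class × genotype rate × per-TE lognormal effect (sd 0.5),
  multiplied by 3 in linker DNA (outside dyad ±73 bp cores) and renormalized
  within each TE, so linker geometry shapes the within-TE distribution while
  the rate table alone sets class-level abundance. Rates (wt: CMT 0.25,
  DRM 6.0, intermediate 1.0; h1: 1.4, 1.0, 0.25) encode sRNA relocation from
  AT-rich to GC-rich TEs with a configured CMT fold gain of 5.6 and
  near-equal total library intensity, so rpkm folds track rate folds. 5% of
  reads are uniform 21-nt background.
* **ChIP.** Input uniform; ChIP intensity per TE is a class ratio
  (H3K9me1/2 tables) or, for H1, a logistic function of realized TE GC
  (slope 40, midpoint 0.40, range 0.8–4.0; flat in h1 genotypes), times a
  lognormal per-TE effect (sd 0.4); 200k 100-bp fragments each.

Ground truth (class labels, realized GC, dyads, configured NRLs and folds)
is emitted beside the data and never consumed by analysis code. All outputs
are deterministic functions of the seed (child seeds are derived per task
and genotype, so adding one simulation never shifts another).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: alignment artifacts and mappability, read-position
biases, chromosome-scale heterochromatin organisation, overlapping or nested
TE annotations, cross-TE methylation spreading, overdispersed coverage
(Poisson, not negative binomial, by default), and any mechanistic model of
Pol IV recruitment. Parameter-recovery results show the estimators are
correct under the stated model, not that the biology has these effect sizes.

## Problem sizes and runtime

The test suite and the acceptance script run the default 2 Mb / 300-TE
genome, 150k-read sRNA libraries and 200k-read ChIP libraries, with
three-seed medians where a ranking is asserted; these sizes were chosen so a
full from-scratch run of every stage completes in well under a minute on a
single CPU while keeping all recovery margins wide (sampling error on class
means ≤ a few percent).

## Known limitations

* `both_depleted` TEs never arise under the default tables; the category is
  exercised only through direct rule tests unless a config adds a
  dual-dependent class.
* The NRL estimator assumes one dominant periodicity in 100–300 bp; mixtures
  of repeat lengths yield the first peak, not an average.
* ChIP log2 ratios are compressed toward 0 by whole-library depth scaling
  when a large genome fraction is enriched; class differences are preserved.
* The ends metaplot excludes bins extending past the chromosome start/end
  rather than padding them.
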