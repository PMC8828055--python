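# methpath

Tools for asking how plant heterochromatin chooses between its two
CHH-methylation pathways, and what that has to do with linker histone H1 and
nucleosome spacing.

In *Arabidopsis*, transposable elements (TEs) keep their asymmetric CHH
methylation through one of two routes: the chromomethylase CMT2, which works
on H3K9-methylated heterochromatin, or the RNA-directed DNA methylation
(RdDM) pathway, in which 24-nt siRNAs guide DRM2. `methpath` implements the
computational side of a study design that separates these routes:

* classify each TE as a **CMT target** (loses mCHH in *cmt2*), a **DRM
  target** (loses mCHH in *drm2*), both, or neither, using level thresholds
  plus Fisher's exact test on pooled read counts;
* quantify 24-nt siRNA abundance (rpkm over 18–28 nt totals) and ChIP
  enrichment (log2 ChIP/input with seeded input subsampling);
* ask with a random forest which chromatin features — H1, H3K9me1/2, sRNA,
  methylation, sequence composition — predict the pathway;
* measure how nucleosomes structure sRNA production: average 24-nt read 5'
  ends in 10-bp bins around nucleosome dyads, autocorrelate, and read the
  nucleosome repeat length (NRL) off the first correlation peak;
* companion statistics: GC-sorted 100-TE binning, genotype fold changes,
  correlation matrices, PCA, rank-sum group comparisons, MET1-dependence and
  sRNA-cluster grouping rules.

Because the real experiments need deep sequencing, the package ships a
seeded **synthetic epigenome generator** that emulates the study conditions
(class-specific methylomes per genotype, linker-biased sRNA, GC-coupled H1,
NRL 180 bp in wild type vs 167 bp in *h1*), so every stage runs and is
tested without any external data.

## The core statistics

For a feature with covered cytosines *i* of context *c* (CG, CHG, CHH; CH =
CHG+CHH), the weighted methylation level is

    m_c = Σ_i meth_i / Σ_i (meth_i + unmeth_i)

and the methylation density is the number of binomially-called methylated
sites per bp. A TE with m_CHH > 0.02 in wild type is a CMT target when in
*cmt2* m_CHH < 0.02 and Fisher's exact test (pooled meth/unmeth CHH counts,
wt vs mutant) gives p < 0.01 — symmetrically for DRM in *drm2*; TEs passing
in both mutants form a separate `both_depleted` class, and the rest are
`intermediate`. sRNA abundance is rpkm normalized to the library's 18–28 nt
total; ChIP enrichment is log2((chip+ψ)/(input+ψ)) on matched bins after
subsampling the input to 25% of the ChIP total. The NRL estimate is the
first local maximum of the autocorrelation of the dyad-anchored mean sRNA
profile, refined to sub-bin resolution by quadratic peak interpolation.

## Worked example

```python
import pandas as pd
import methpath as mp
from methpath.methylation import summarize_features_methylation, summaries_to_frame
from methpath.profiles import phasing_profile
from methpath.association import genotype_change
from methpath.coverage import srna_rpkm

sim = mp.run_default_simulation(seed=1, with_chip=False)
tes, truth = sim["tes"], sim["truth"]

# per-TE mCHH and pooled CHH read counts per genotype -> pathway labels
summ = {g: summaries_to_frame(summarize_features_methylation(tes, sim["methylomes"][g]))
        for g in ("wt", "cmt2", "drm2")}
table = pd.DataFrame({"length": summ["wt"]["length"]})
for g in summ:
    table[f"mCHH_{g}"] = summ[g]["mCHH"]
    table[f"meth_{g}"] = summ[g]["meth_reads_CHH"]
    table[f"unmeth_{g}"] = summ[g]["unmeth_reads_CHH"]
labels = mp.classify_pathway_table(table)
print(labels["label"].value_counts().to_string())
print("recovery:", (labels["label"] == truth.te_class).mean())

for g in ("wt", "h1"):
    prof = phasing_profile(sim["srna"][g], sim["dyads"][g])
    print(f"{g} NRL estimate: {prof.nrl.nrl_bp:.1f} bp")

change = genotype_change(
    srna_rpkm(sim["srna"]["wt"], tes, 24),
    srna_rpkm(sim["srna"]["h1"], tes, 24),
    class_labels=truth.te_class,
)
print(f"CMT-TE sRNA fold change (h1/wt): {change.fold['CMT']:.2f}")
```

prints

```
label
CMT             120
DRM             120
intermediate     60
recovery: 1.0
wt NRL estimate: 175.8 bp
h1 NRL estimate: 166.7 bp
CMT-TE sRNA fold change (h1/wt): 4.99
```

Every one of the 300 synthetic TEs is assigned back to its generating
pathway; the phasing analysis recovers a longer repeat length in wild type
(configured 180 bp) than in *h1* (configured 167 bp); and losing H1 raises
24-nt sRNA output of CMT-class TEs about five-fold (configured relocation
5.6×, measured through the full rpkm pipeline).

## Command line

`methpath` exposes the same pipeline as subcommands: `simulate` (write a
synthetic epigenome: FASTA, BED, cytosine reports, truth JSON), `methylation`,
`srna`, `chip`, `classify`, `rf`, `profile` (ends metaplots / dyad phasing),
`associate` (bin/corr/pca/compare), `convert` and `validate`. For example:

```sh
methpath simulate --outdir sim --seed 3 --genotypes wt,h1
methpath srna --reads sim/srna_wt.bed --features sim/tes.bed --size 24 --out rpkm.tsv
methpath profile --mode dyads --reads sim/srna_wt.bed --features sim/dyads_wt.bed --out prof.tsv
```

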