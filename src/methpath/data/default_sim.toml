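# Default synthetic-epigenome configuration.
#
# Every number here is an invented default chosen to mirror the qualitative
# genotype effects the pipeline detects (class-specific methylation loss in
# cmt2/drm2, sRNA relocation from AT-rich to GC-rich TEs without H1, and a
# shorter nucleosome repeat length in h1). Edit freely; absent keys keep the
# package defaults. Loaded with methpath.load_config().

genome_length = 2000000
chrom_name = "chr1"
background_gc = 0.36
min_gap = 200

jitter_sd = 10.0          # nucleosome positioning jitter, bp (sd)
coverage_mean = 12.0      # mean bisulfite coverage per cytosine
error_rate = 0.005        # bisulfite non-conversion rate
srna_depth = 150000       # 24-nt reads per library
background_21nt_fraction = 0.05
srna_sigma = 0.5          # per-TE lognormal sd on sRNA rate
linker_multiplier = 3.0   # sRNA intensity gain in linker DNA
chip_sigma = 0.4          # per-TE lognormal sd on ChIP enrichment
chip_depth = 200000
chip_fragment = 100
h1_slope = 40.0           # H1 occupancy = logistic of TE GC content
h1_midpoint = 0.40
h1_min_ratio = 0.8
h1_max_ratio = 4.0

[nrl]                     # nucleosome repeat length per genotype, bp
wt = 180
h1 = 167

[te_classes.CMT]          # long, GC-rich, heterochromatic
n = 120
length_range = [1500, 4000]
gc_mean = 0.44
gc_sd = 0.04

[te_classes.DRM]          # short, AT-rich, RdDM-targeted
n = 120
length_range = [300, 800]
gc_mean = 0.36
gc_sd = 0.04

[te_classes.intermediate]
n = 60
length_range = [500, 1500]
gc_mean = 0.40
gc_sd = 0.04

# Methylation probability per genotype x TE class x context.
[methylation.wt.CMT]
CG = 0.85
CHG = 0.55
CHH = 0.10
[methylation.wt.DRM]
CG = 0.60
CHG = 0.15
CHH = 0.12
[methylation.wt.intermediate]
CG = 0.70
CHG = 0.35
CHH = 0.10

[methylation.cmt2.CMT]
CG = 0.85
CHG = 0.55
CHH = 0.0
[methylation.cmt2.DRM]
CG = 0.60
CHG = 0.15
CHH = 0.12
[methylation.cmt2.intermediate]
CG = 0.70
CHG = 0.35
CHH = 0.05

[methylation.drm2.CMT]
CG = 0.85
CHG = 0.55
CHH = 0.10
[methylation.drm2.DRM]
CG = 0.60
CHG = 0.05
CHH = 0.0
[methylation.drm2.intermediate]
CG = 0.70
CHG = 0.30
CHH = 0.05

# Relative per-bp 24-nt sRNA intensity per genotype x class. The h1/wt CMT
# ratio (1.4 / 0.25 = 5.6) is the configured sRNA relocation fold gain.
[srna_rate.wt]
CMT = 0.25
DRM = 6.0
intermediate = 1.0
[srna_rate.h1]
CMT = 1.4
DRM = 1.0
intermediate = 0.25

# ChIP enrichment ratio over input per class (H1 is computed from GC).
[chip_enrichment.H3K9me1]
CMT = 2.5
DRM = 1.0
intermediate = 1.6
[chip_enrichment.H3K9me2]
CMT = 3.0
DRM = 1.2
intermediate = 2.0
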