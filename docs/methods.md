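# Methods

## The genetic model

The simulated cross is an F2 between two fully inbred parents that differ at
every retained SNP. The F1 is heterozygous genome-wide; each F2 gamete is an
independent recombinant mosaic of the two parental haplotypes. Crossovers
follow the Haldane model: the count per gamete and chromosome is Poisson with
mean L_cM/100 (L_cM = physical length × a uniform cM/Mb rate), and crossover
positions are uniform. There is no interference, no selfing-generation
lineage structure, and no sequencing-error model — gametes, not reads, are
simulated.

One biallelic causal locus is dominant: a plant with at least one mutant
allele shows the mutant (speltoid-spike-like) phenotype. Penetrance is
complete by default; a misclassification rate is exposed for null scans
(setting it to 0.5 destroys the genotype–phenotype link and yields a
signal-free scan).

## Pooled sequencing model

Bulks are drawn without replacement from the phenotype classes (50 plants
each by default, matching common practice). At each SNP and bulk the total
depth is Poisson(depth_lambda) and mutant-allele reads are
Binomial(depth, f), where f is the realized mutant-allele frequency among the
bulk's 100 chromosomes. This two-stage model captures the two noise sources
that matter for the scan: finite bulk composition (spatially correlated along
the chromosome — smoothing does not average it away) and finite read
sampling (independent per locus). Parents are sequenced as fixed opposite
homozygotes with their own Poisson depth.

Expected values used throughout the tests come from genotype-class
enumeration: among dominant-phenotype plants AA:Aa = 1:2, so the mutant-bulk
allele frequency at the causal locus is 2/3 and the wild-type bulk's is 0;
an unlinked locus gives 1/2 in either bulk. At map distance r the expected
dSNP-index is 2/3 − 4r/3.

## Key defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| genome | 21 chromosomes (1A–7D) × 50 Mb | the hexaploid wheat karyotype at desk scale. The candidate-region threshold is a genome-wide quantile, so the genome fraction occupied by the causal chromosome (~5%) determines how far candidate regions extend down the dome of elevated dSNP-index; a two-chromosome toy genome would turn the 99th percentile into a crest-level cutoff and make region calls needlessly brittle |
| map rate | 1 cM/Mb | a round, realistic plant-genome average |
| SNP density | 10 SNPs/Mb (500/chromosome) | enough loci for a stable LOESS fit per chromosome while keeping 100-replicate experiments cheap |
| n_f2 / bulk size | 642 / 50 | the population and bulk sizes of the motivating experimental design |
| depth_lambda | 50× per bulk | typical pooled whole-exome depth |
| LOESS | span 0.1, degree 1, 2 bisquare iterations | one smooth peak per chromosome arm at the default density; all configurable |
| region threshold | 99th percentile of fitted values, ≥ inclusive | simple, calibrated by construction (null scans flag ~1% of loci); a phenotype-shuffling permutation alternative can be built with the misclassification knob |
| NB dispersion | 0.01 | the standard biological coefficient of variation (BCV ≈ 0.1) for genetically identical, jointly grown organisms such as inbred wheat lines |
| DEG rule | Welch on log2(FPKM+1), BH, |log2FC| ≥ 1, q < 0.05, mean-FPKM ≥ 1 floor | the twofold + FDR rule on a transparent, dependency-light test; no claim of equivalence to shrinkage-based DE frameworks, which are deliberately out of scope |
| purity for parental homozygote calls | ≥ 0.9 major-allele fraction | inbred parents; apparent heterozygosity is treated as artifact and discarded with the monomorphic class |
| depth filter | < 4 in **either** parent | a cross-informative genotype cannot be trusted if one parent is shallow; an either/both switch is exposed |

All randomness flows from one integer seed; each operation derives a child
stream keyed by its name, so stages are independently reproducible and whole
runs are byte-identical under a fixed (config, seed).

## Marker design

CAPS assays are found by screening an editable packaged enzyme table (IUPAC
recognition + cut offset; DdeI is CTNAG cut after the first base) for enzymes
whose site count differs between the two alleles of an amplicon. Heterozygote
banding is the exact union of the homozygote band sets — no partial-digest or
heteroduplex bands — which reproduces the three-band co-dominant pattern.
Predicted fragment lengths always sum to the amplicon length; gel-estimated
sizes in the wet-lab literature need not (sizing imprecision), so printed gel
sizes are not used as exact oracles. Primer thermodynamics (Tm, GC clamps,
genome-wide uniqueness) are out of scope; KASP design is pure sequence
assembly with the standard FAM (GAAGGTGACCAAGTTCATGCT) and HEX
(GAAGGTCGGAGTCAACGGATT) tails and the SNP at the 3' terminus.

## Coding and splice effects

Gene models are exon coordinate sets over a supplied genomic sequence with
protein-coordinate domain annotations (domains are inputs, not predictions).
SNV classification recomputes the full translation; a nonsense effect
reports every domain whose interval extends beyond the truncated product.
Splice events (exon skip, intron retention) are declared, not predicted —
there is no splice-site strength model. miRNA target-site mismatches use
binary antiparallel Watson–Crick pairing with G:U wobble counted as a
mismatch by default (configurable), and no gapped alignment.

The packaged synthetic gene mirrors a 447-aa, 10-exon, two-domain
architecture with an in-frame 117-nt exon 9 (so the skip isoform encodes
408 aa), an intron 8 that opens with an in-frame stop (the retention isoform
terminates at 350 aa), and a G-to-A SNV that simultaneously creates a stop
at codon 224 and a DdeI site. It is a synthetic stand-in: the architecture,
not the base sequence, is what it reproduces.

## Peak-to-target assignment and motif ranking

Peaks are anchored at their interval midpoint (a summit column can replace
this) and assigned to the gene with the smallest |signed TSS distance|
(negative = upstream, strand-aware; ties broken lexicographically and
logged). Window flags follow the inclusive conventions −10 kb/+5 kb (genic)
and −2 kb/+500 bp (putative direct target). Motif ranking is a deliberately
simple k-mer scheme — counts collapsed with reverse complements, background
from per-sequence Altschul–Erickson dinucleotide shuffles (10 per sequence),
score log2((c_fg+1)/(c_bg/n_shuffles+1)) — a self-contained alternative to
PWM/EM motif discovery, adequate for recovering a strong implanted core
motif but not for subtle or degenerate motifs.

## Numerical and degenerate-input choices

- LOESS windows are the k nearest points (k = ceil(span·n), contiguous in
  sorted position); fits use centred Vandermonde least squares; fitted
  scan values are clipped to [0, 1] after smoothing. Chromosomes with fewer
  points than the window are skipped with a warning. The implementation
  matches statsmodels' lowess at degree 1 to ~5e-3 (cross-checked in tests).
- A fitted track with all values tied cannot be thresholded; each chromosome
  is returned whole, flagged degenerate, with a warning.
- Loci with zero depth in a bulk get a missing SNP-index and are excluded
  from smoothing but retained in output.
- Interval delimitation resolves ties in the minimal recombinant count
  toward the wider interval; heterozygous markers in dominant-phenotype
  plants are scored non-recombinant (they are compatible with A_), the
  asymmetry the dominant model forces.
- Pearson chi-square p-values are compared to exact binomial enumeration
  with the mid-p convention in tests; at n = 30 they agree within 0.02,
  while the raw (non-mid-p) comparison can differ by up to ~0.17 from
  discreteness alone — an intrinsic property of discrete GOF tests, not an
  implementation artifact.
- DEG calling with identical groups yields zero-variance t-statistics; their
  p-values are set to 1.

## What the synthetic data does and does not show

The generator reproduces the statistical skeleton of the experiment:
Mendelian segregation, linkage decay of the dSNP-index, pooled sampling
noise, NB count dispersion, TSS-proximal binding with a core motif. It does
not model alignment or variant-calling artifacts, repeat-induced mapping
errors, segregation distortion, incomplete penetrance (unless enabled),
batch effects in expression, or peak-calling noise. Passing tests therefore
demonstrate that the *analysis chain* is correct and well-calibrated under
its stated assumptions — not that those assumptions hold for any particular
real dataset. Real-data quantities that depend on deposited sequencing runs
(peak counts, exact interval bounds, DEG overlaps) are correspondingly not
reproduced here; the simulation-backed recovery properties in
`tests/test_acceptance.py` stand in for them.

## Problem sizes

Default experiment simulations use 642 plants, 10,500 SNPs and 50× bulk
depth; recovery properties are measured over 100 seeded replicates (the
full battery runs in a few minutes). The segregation check uses 10,000
plants on the causal chromosome, and the filter-accounting check runs the
vectorized filters over 1.8 million loci.
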