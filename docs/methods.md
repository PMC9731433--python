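# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Variant classification

A variant is *archaic* when at least one haplotype carrying its derived
allele lies inside an archaic tract at that position; tract coverage alone
is not enough, and the derived allele is defined by polarisation against the
ancestral-allele table (sites without an ancestral call, or whose ancestral
allele matches neither observed allele, are excluded — the mismatch case is
excluded rather than force-polarised). The *main introgressed allele* (MIA)
is the most frequent allele among tract-covered haplotypes at the site,
ties broken toward the alternative allele for determinism.

Two denominator conventions coexist deliberately. MIAF and DAF divide by
all genotyped chromosomes at the site — they are population frequencies used
for the low vs common-to-high split at 0.05 (boundary inclusive:
≥ 0.05 is common-to-high). The archaic / non-archaic class frequencies
divide by the number of haplotypes of that class at the site — they feed the
frequency-difference filter, which removes archaic calls whose signed
difference (archaic minus non-archaic) is below 0.25; a negative difference
(the allele commoner outside tracts) is therefore always removed. An
`abs_diff` flag offers the unsigned variant. The outgroup filter is
inclusive at 0.005 and treats alleles absent from the panel as frequency 0.

Dual-ancestry sites (incomplete lineage sorting) are resolved by the class
frequency of the MIA within Denisovan-class vs Neanderthal-class haplotypes,
compared as integer cross-products so exact ties are exact; ties fall back
to matching the MIA against the Altai reference genotypes, and a variant
matching both (or neither, with no reference data) is ambiguous and
excluded. Cascade order: biallelic → singleton (minor-allele count exactly
1, the conservative reading of "singleton") → polarisation → ancestry →
frequencies (all-missing sites excluded here) → frequency difference →
outgroup → frequency class. Every input variant lands in exactly one
terminal bucket; the ledger stores survivors per step.

## SFS matching

Binning defaults to exact integer allele counts of the focal allele (MIA
copies within archaic haplotypes for archaic calls, derived copies within
non-archaic haplotypes for controls), with a fixed-width frequency binning
(0.02) available for cohorts of unequal call rate. The target allocation
uses largest-remainder rounding so per-bin totals are exact; sampling is
uniform without replacement within bins and fully determined by the seed.
Matching is to the *pooled* archaic SFS by default (the per-ancestry option
is a caller-side filter); a bin with fewer controls than requested yields
everything it has, a warning, and a smaller total — never replacement
sampling.

## Chromatin annotation and enrichment

Segmentations are 0-based half-open tilings, one per cell type; 1-based
variant positions are converted before lookup, and a position outside every
segment of a cell type is flagged and excluded from counts rather than
guessed. Pleiotropy is the number of cell types annotating a variant in the
same state. eQTL overlap matches on (chrom, pos, ref, alt) strictly — no
allele flipping — and counts a variant once regardless of eGene
multiplicity. The CRE state set is fixed to {TssA, TssAFlnk, TxFlnk, Enh,
EnhG}.

Enrichment counts default to (variant, cell-type) annotation pairs pooled
within a combination, the only unit that uses all annotations; a
`distinct_variants` unit (≥ 1 supporting cell type) is available. The odds
ratio is the sample estimate ad/bc with Haldane-Anscombe +0.5 on every cell
only when a cell is zero (the p-value never uses the correction); a zero
margin gives OR = NA, p = 1. Fisher's two-sided p follows the
point-probability rule on the conditional hypergeometric. BH families are
all combinations within one ancestry. Tissue-level odds ratios compare
shares of pooled CRE annotations, so a genuine concentration in one tissue
appears as mild depletion of the others; the planted-effect recovery
therefore measures the (state × tissue) combination within its tissue.

## Motif scoring

Window scores are log-odds: Σᵢ log₂(pᵢ(bᵢ)/bg(bᵢ)) with bg(A) = bg(T) =
0.3, bg(C) = bg(G) = 0.2. A declared background with a "sum of
log-probabilities" rule is ambiguous between raw log-probability and
log-odds; log-odds is used because it is the only reading in which the
background participates in scoring. Count matrices get pseudocount 1;
probabilities are floored at 1e-4 and renormalised.

Match thresholds are exact p-value cutoffs: the score distribution under
the background is computed by dynamic programming after rounding each
matrix entry to a grid of (score range)/10⁴; the cutoff is the smallest
grid score whose tail probability is ≤ the target (10⁻⁵ by default).
Rounding accumulates to at most width/2 grid bins, which is the tolerance
used when checking the DP against exhaustive 4^w enumeration. Windows with
ambiguous bases are skipped. Each allele takes its best score over all
windows covering the SNP on both strands — alleles may pick different
windows — and a record is emitted only if at least one allele passes the
threshold. ΔPWM subtracts the non-focal from the focal (introgressed or
derived) allele score and is exactly antisymmetric under allele swap.
Consolidation keeps one record per (variant, TF): largest |ΔPWM|, ties by
database priority (JASPAR before HOCOMOCO) then motif name. The cluster
excess test is a global χ² on the clusters × {case, control} table of
disrupting calls (motifs without a cluster assignment are dropped), with a
seeded fixed-margin Monte-Carlo p (10⁴ draws) when more than 20% of
expected counts fall below 5.

## Fst

Per-site Weir-Cockerham (1984) for two diploid populations: variance
components a (among populations), b (among individuals within populations)
and c (within individuals) from sample sizes, allele frequencies and
observed heterozygosities; Fst = a/(a+b+c). Negative estimates are kept
(they carry information about the null), sites monomorphic in both
populations are NA, individuals with any missing allele are dropped at that
site, and the estimator is invariant under ref/alt relabelling. Per-site
values (not windowed means) are reported because the downstream comparisons
are of per-SNP distributions.

## Gene targets

Distance is measured to the strand-aware TSS; each variant gets at most one
gene (nearest TSS within 1 Mb, inclusive), exact ties resolved to the
lexicographically smaller gene id. Term enrichment is a one-sided
hypergeometric upper tail over genes — not genomic regions — because the
background is a gene set; BH across terms, significance at q < 0.01, and a
target gene missing from the background is a contract violation, not a
silent drop.

## Reporter quantification

Technical replicates are collapsed by arithmetic mean of Ct before
anything else. Efficiency comes from the least-squares slope of mean Ct vs
log₁₀ relative input (E = 10^(−1/slope); a non-negative slope is an error
with the offending series in the message). Expression per transfection
replicate is E^(Ct_pDNA − Ct_cDNA); the allelic ratio is the geometric-mean
ratio and the test is a one-sample t of per-replicate log₂ ratios against 0
— log scale because ratio noise is multiplicative and the null is then
symmetric — paired by transfection replicate when both alleles share the
replicate structure, otherwise an unpaired two-sample t on log₂ expressions
(flagged). BH runs across all constructs × cell lines of a run. A
constant, non-zero log-ratio vector has an undefined t statistic and
reports NA rather than a fabricated p.

## What the generators emulate — and what they do not

The cohort generator works at the level of shared tract loci: an interval
plus the set of carrier haplotypes, drawn so that expected per-haplotype
coverage matches the configured ancestry mix (defaults 4% Denisovan, 2.5%
Neanderthal — the Papuan regime) with exponential lengths (mean 50 kb).
Introgressed alleles ride on a locus's carriers, which realises the
configured allele-count spectrum (default 1/i over counts 2..N/2);
non-archaic derived alleles follow the neutral 1/i spectrum and avoid
tract-covered haplotypes. Dual-ancestry sites are planted at Denisovan ×
Neanderthal locus intersections (8% of archaic sites, the study-scale
dual fraction), a quarter of them as exact frequency ties so the Altai
tie-break is exercised; the Altai tables always support the planted truth.
Optional knobs leak archaic alleles into the outgroup panel (to exercise
the outgroup filter), onto non-archaic haplotypes (to exercise the
frequency-difference filter), and into ancestral-call gaps (polarisation
exclusions). One chromosome, no recombination maps, no phasing errors, no
genotyping error: passing tests demonstrate the *analysis* is correct under
its stated assumptions, not that tract inference on real data is.

The epigenome generator draws each (variant, cell type) state from a
baseline distribution dominated by quiescent chromatin and tilts the
planted (state, tissue) odds for case variants, then builds each cell
type's segmentation as the midpoint tiling around the variants so interval
lookup recovers the draws exactly. Real segmentations have length-dependent
segment structure and spatial autocorrelation; those are irrelevant to the
counting statistics under test and are not modelled. Motif libraries use
sharp random consensus matrices (default widths 10–14: any shorter all-A/T
consensus would be more probable than 10⁻⁵ under the background and could
never pass the match threshold). qPCR plates follow
Ct = intercept − log_E(quantity) + N(0, σ) with σ = 0.1 cycles by default.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to finish in
minutes while leaving planted effects statistically unambiguous: cohorts of
56 × 2,000 sites (classification), 28 × 3,000 sites with a 15% archaic
fraction for SFS matching (keeping the control pool several times the
archaic set, as in the source data), enrichment at 2,000 variants per group
× 4 cell types × 100 seeds, 12 planted motif disruptions × 100 seeds, and
reporter plates of 5 constructs × 2 cell lines × 100 seeds.

## Known limitations

Classification accuracy is measured against simulated truth; real tract
calls carry correlated errors the generator does not model. The Monte-Carlo
cluster test uses fixed-margin resampling, which conditions on the observed
disruption totals. The DP threshold is conservative by up to width/2 grid
bins. Sharing tallies compare classifications, so a variant filtered out in
one population for frequency reasons still counts as shared if classified
to the same ancestry.
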