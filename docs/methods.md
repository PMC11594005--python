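# Methods

This note documents the models, estimators and numerical choices behind
`cnvpop`, and what the synthetic cohorts do and do not emulate.

## Synthetic cohorts

The generator (`cnvpop.simdata`) produces a cohort in five seeded stages —
allele frequencies, genotypes, gene models, gene sets, depth tracks — all
drawn from one `numpy.random.default_rng(seed)` stream in that fixed order,
so an identical `SimConfig` reproduces byte-identical outputs.

**Loci.** `n_loci` non-overlapping biallelic CNV loci are placed on the
genome, each carrying either a loss allele (deletion) or a gain allele
(duplication); `frac_loss_loci` defaults to 0.8, matching the strong excess
of deleted over duplicated sequence reported for cattle cohorts. Lengths are
log-uniform on [5, 100] kb by default — multi-kilobase events on the scale
reported for cattle CNVs (mean ≈ 40 kb). Mixed CNVRs are not planted
directly; they emerge downstream when loss and gain loci are merged into one
region.

**Differentiation.** Background loci follow the Balding–Nichols model: an
ancestral frequency p0 ~ U(0.05, 0.95) and per-population frequencies
p_k ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F) with F = `F_bg`, so the expected
multi-locus Weir–Cockerham F_ST between populations equals F_bg. A fraction
`frac_selected` of loci (ceil(frac·L), default 1%) model **divergent
selection**: one randomly chosen population sweeps the variant allele up and
the others down, with frequencies drawn tightly (Beta, concentration
κ = 200) around means (1 ± δ)/2 where δ = √F_sel. This choice is deliberate:
drawing selected-locus frequencies independently at high drift (the naive
alternative) fixes the *same* allele in both populations about half the
time, leaving those loci undifferentiated and undetectable by any F_ST scan.
Divergent means guarantee that planted "selected" loci are actually
differentiated — per-locus F_ST ≈ F_sel — which is what a selection-scan
positive control must provide.

**Genotypes.** Ancestry Q is one-hot by breed (`admix_alpha = 0`) or
Dirichlet(α·1). The variant-allele count is x ~ Binomial(2, Σ_k Q_ik p_kl);
copy state is 2 − x at loss loci and 2 + x at gain loci, giving the five
diploid states {0, 1, 2, 3, 4}.

**Depth.** Per bin (200 bp default), the expected count is
`mean_depth_per_bin · (copy/2) · (1 + gc_amp·sin(2π·gc))` with a smooth GC
track in [0.3, 0.7] shared across samples; counts are Poisson (optionally
gamma-Poisson with an `overdispersion` parameter). Per-bin q0 (fraction of
mapping-quality-zero reads) is Beta(1, 19) (mean 0.05) except in designated
repeat runs (~1% of bins, in 2 kb stretches) where it is Beta(8, 2)
(mean 0.8), emulating repeat-driven artifacts the q0 filter must remove.

**What is not emulated.** Reads and alignment (no FASTQ/BAM), linkage
between loci, overlapping CNVs, sex chromosomes, breed-specific depth, and
reference errors. Passing tests therefore demonstrate correctness of the
estimators and the calling/merging logic under a Poisson depth model with
independent loci — not robustness to alignment artifacts or complex repeat
structure in real genomes.

## Read-depth caller

GC correction scales each bin by `global_median / stratum_median` within
1%-wide GC strata; strata with fewer than 100 bins borrow the nearest
populated stratum, and zero-median strata are left unchanged. Normalization
divides by the mean over placed chromosomes, so 1.0 is the diploid level.
Because the normalizer is the plain genome mean, cohorts whose CNVs cover a
large fraction of the genome (tens of percent) bias it; at realistic CNV
burdens (a few percent) the bias is negligible.

Segmentation minimizes Σ_seg Σ_b (x_b − mean_seg)² + β·#segments exactly,
with β = λ·σ̂²·log B, σ̂² the squared scaled median absolute deviation, and
λ = 2 by default. The optimum is found by PELT (pruned exact linear time, a
numba-jitted core); pruning with constant K = 0 is valid for this cost, so
the result equals full optimal partitioning — property-tested against
exhaustive enumeration for all signals up to 12 bins. Ties are resolved
toward fewer segments.

The caller locates changepoints on the square-root of the normalized signal.
For near-Poisson counts the square root is variance-stabilizing, which
roughly halves the rate of misplaced heterozygous-deletion boundaries
relative to segmenting the raw ratio; copy states, segment means and
p-values are computed on the natural scale. Even so, breakpoint precision at
10 reads per bin is noise-limited for single-copy changes: a
maximum-likelihood locator that knows the true levels still misses a ±2-bin
window at ~8% per boundary for 2→1 transitions and ~18% for 2→3 transitions
(direct simulation). Homozygous deletions and double gains are located
almost exactly. Consumers needing base-precise breakpoints at this depth
would require split-read evidence, which is out of scope.

Copy states use round-half-away-from-zero on 2d, capped at 4 ("two or more
copies gained"); diploid segments are dropped and adjacent same-state
segments merged. The per-call p-value is a two-sided one-sample t-test of
the segment's bins against 1.0; single-bin segments get p = 1
(conservative), and zero-variance segments with mean ≠ 1 (an all-zero
homozygous deletion) get p = 0, since the t statistic diverges and the
evidence is unambiguous. q0 per call is the count-weighted mean of bin q0
(unweighted if the segment has no reads). Filters are strict conjunctions:
p < 0.001, length > 1000 bp, q0 < 0.5, placed chromosome.

## CNVRs

CNVRs are transitive closures of ≥1 bp call overlap, taken per breed; the
region is the union span, its type is loss/gain if all constituent states
agree in direction and mixed otherwise, and regions carried by fewer than
`min_carriers` distinct individuals (default 4; a frequency mode
ceil(0.133·n) is provided) are dropped before breeds are merged with the
same closure rule. Genotyping assigns each individual its largest-overlap
call state per region (ties to the earlier call start; a call spanning two
regions counts toward its larger overlap), and individuals without calls are
diploid — a deterministic stand-in for statistical imputation, chosen so
that downstream matrices contain no missing data.

## Annotation

Gene-context classes follow the gene-based annotator convention with
precedence exonic > UTR > intronic > upstream > downstream > intergenic;
a region takes the highest class among everything it overlaps by ≥1 bp.
"Exonic" requires coding-sequence overlap (or any exon of a non-coding
gene); upstream/downstream use a strand-aware 1 kb window. Loss CNVRs
overlapping CDS are frameshift deletions iff the deleted CDS length is not a
multiple of 3; exonic overlaps touching no CDS are "unknown". A deletion
spanning a whole gene is classified by the same mod-3 rule on its total CDS
(necessarily non-frameshift, as complete CDSs are multiples of 3) and
flagged `whole_gene`.

## Population structure

CNVR states are recoded to variant-allele dosages (loss: 2 − copy; gain:
copy − 2; clipped to [0, 2]); mixed regions contribute one pseudo-locus per
allele. Distances are either 1 − IBS between individuals or pairwise
weighted F_ST between breeds (clamped at 0). Neighbor joining is the
Saitou–Nei agglomeration with Q_ij = (n−2)d_ij − r_i − r_j, ties broken by
the smallest index pair, branch lengths clamped at 0, Newick written with 6
decimals; on additive inputs the output path metric equals the input
exactly. PCA drops monomorphic loci, centers by 2p̂ and scales by
√(2p̂(1−p̂)), eigendecomposes ZZᵀ/L, and fixes signs so each eigenvector's
largest-magnitude entry is positive.

The admixture model maximizes Σ_il [g log π + (2−g) log(1−π)] with
π = QF over ancestry proportions Q and ancestral frequencies F, via the
classic EM updates (responsibility-weighted allele counts), which are
monotone in log-likelihood. F is clamped to [1e-6, 1−1e-6], convergence is
Δℓ < 1e-6 (max 2000 iterations), and the best of 5 seeded restarts is kept.
EM was chosen over quasi-Newton block relaxation for its monotonicity
guarantee and simplicity; it maximizes the same likelihood, only more
slowly — irrelevant at these problem sizes.

## Selection scan and enrichment

The Weir–Cockerham two-group estimator is computed from per-group sample
sizes, variant-allele frequencies and observed heterozygote (dosage-1)
proportions, exactly as the 1984 component formulas prescribe; loci
monomorphic in both groups (a+b+c = 0) or with a group of fewer than two
individuals are undefined and excluded from ranking. The genome-wide value
is the ratio of sums Σa/Σ(a+b+c). The selection threshold τ is the
linear-interpolation (type-7) 99th percentile of defined per-locus values;
loci with F_ST ≥ τ, ties included, are selected; negative estimates are kept
unclamped in the ranking. The threshold is a property of each dataset — the
synthetic cohorts here produce τ in the 0.4–0.65 range at the default
conditions.

Enrichment is the exact upper-tail hypergeometric P(X ≥ k) (an EASE-style
k−1 variant is available), with the universe defaulting to all genes in the
supplied annotation and Bonferroni/Benjamini–Hochberg applied within each
term namespace. Note the test is conservative under the null at these term
sizes (discrete tails reject at ~3.5–4% for α = 5%).

## Pipeline

`cnvpop.pipeline.run` executes simulate → call → merge → annotate →
structure → fst → enrich from a YAML config whose defaults encode the
standard settings (200 bp bins, p < 0.001 / >1 kb / q0 < 0.5 filters,
min_carriers = 4, top 1%, K = 2..10); stages communicate only through the
declared file formats (VCF 1-based, BED and depth tracks 0-based half-open,
GFF3 1-based inclusive — conversions centralized in `cnvpop.io`), and a JSON
manifest records the config hash, seed and SHA-256 checksums of every
output, making deterministic stages verifiable across re-runs. The default
F_ST grouping pools all non-focal breeds against the first breed, the
grouping used for focal-breed selection scans.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to keep every
stage's sampling error far below its tolerance: frequency-level checks use
L = 2000 loci and n = 30 per population (5 seeds); the caller is evaluated
on 6 Mb × 4-sample cohorts (planted recovery) and 20 CNV-free 10 Mb genomes
(false calls); admixture uses L = 1000, n = 40; exactness checks use 500–1000
randomized instances against brute-force oracles.

## Known limitations

Breakpoint precision at low depth (above); no multi-sample joint calling;
no reciprocal-overlap merge thresholds (1 bp only); quantile thresholding
without permutation significance; no cross-validation for choosing K; the
enrichment universe excludes unannotated genes by default.
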