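# Methods

This note documents the models and procedures implemented in `ggsig`,
the choices made where the design was genuinely open, and what the
synthetic data do and do not establish.

## Promoter model

Promoters span −1000..+500 bp around the TSS in transcription
orientation (minus-strand sequences are reverse-complemented before any
statistic is computed). Windows of 500 bp advance in 20-bp steps and
must be fully contained, giving 51 windows for an untruncated promoter;
fixed-length windows keep the CpG-ratio scale comparable across
windows. The CpG ratio is the observed/expected normalisation
`(n_CpG · L) / (n_C · n_G)` with `L = 500`, defined as 0 when the window
has no C or no G — the 0.45/0.65 class thresholds are only meaningful on
this scale. Windows with more than 10% N are skipped and the GC
denominator excludes N, to avoid spurious low-CpG calls inside assembly
gaps.

Classification order matters: the HCP rule (any window with ratio > 0.65
and GC > 0.55) is evaluated before the LCP rule (no window with
ratio > 0.45), so the three classes partition all classified promoters;
a promoter whose windows are all below one full window's length is NA.
All thresholds are strict inequalities. Duplicate `(chrom, tss, strand)`
entries collapse to one promoter listing all transcript ids, and a
gene's class is the strongest class over its promoters (HCP > ICP >
LCP) — an explicit aggregation choice, since isoform collapsing is
otherwise underdetermined.

Coordinates are 0-based half-open internally; BED input is used as-is
and GTF is converted on read. `cgi_size_bp` is the size of the largest
annotated CpG island overlapping the promoter (CGIs are consumed from an
annotation, never predicted).

## Chromatin signature

Coverage is read from 4-column bedGraph in RPM units; producing those
tracks (alignment, read extension, scaling) is upstream of this package.
Profiles cover `[tss − flank, tss + flank)` with the TSS base at column
`flank` on both strands (minus-strand windows are shifted by one base so
the TSS column matches, then reversed into transcription orientation).

The set-level statistic is the mean over promoters of per-promoter mean
coverage — equal weight per promoter regardless of missing bases — and
the enrichment is `log2((t + c)/(b + c))` with `c = 0.01` RPM. The
pseudocount keeps zero-coverage datasets finite and stable in ranking;
its cost is a bounded attenuation of `|log2FC|` of order
`c/(mean·ln 2)`, negligible for means ≥ 0.5 RPM. Mean (not median)
across promoters is a recorded choice. The inactive background is the
set of HCP promoters whose gene has FPKM < 1 (strict) in wild-type
cells. Ranking sorts by descending log2FC with lexicographic
tie-breaks, so reruns are deterministic.

Note that when the target promoters are themselves part of the
background (as in the real analysis, where the few dozen germline HCPs
sit inside thousands of inactive HCPs), the measured fold change is
diluted by the targets' share of the background. At synthetic scale
(40 targets among 85 inactive HCPs) this dilution is large, so planted
fold-change recovery is validated against the non-target background;
the pipeline's default background remains the full inactive set.

## Screen selection

Gene summaries follow the MAGeCK positive-selection convention: lower
rank and score mean stronger enrichment in the sorted (GFP-positive)
population, ranks are validated as a permutation of 1..n consistent
with ascending score. The filter chain is ordered: (1) olfactory
receptor genes (default: `Olfr` prefix, overridable by an explicit
list) are removed from every table and the remainder re-ranked; (2) the
100 best-ranked genes with positive-selection p < 0.05 (strict) are
taken from the full analysis — the p-threshold is exposed because the
published description is ambiguous between 0.05 and 0.005; (3) the 20
best-ranked genes of each two-replicate analysis are added (union,
provenance recorded); (4) genes with FPKM < 5 (strict) are removed,
missing genes counting as unexpressed. The output is ordered by rank in
the full analysis, then best pairwise rank, then name. Every removal is
logged with stage and reason.

## Gene-set statistics

Enrichment uses the upper-tail hypergeometric probability P(X ≥ k) for
k query genes in a K-member term within an N-gene universe, computed
through the log survival function for deep-tail stability, and BH
adjustment across the tested terms (flat term sets; no ontology
propagation). The universe defaults to the supplied annotation's genes.
DE filters compare on the linear fold-change scale with strict
inequalities; fold changes are consumed from input tables (shrinkage is
out of scope). `FPKM = counts / (length_kb · libsize_millions)`.

## TE quantification

Each read distributes unit weight over its alignments: 1/k per
alignment, with k taken from the NH tag when it matches the records
present, else the record count (with a warning) — so partially filtered
alignment sets still conserve weight. Any 1-bp overlap with a repeat
interval counts (minimum overlap exposed as a flag). An alignment
overlapping several intervals of one family contributes once to that
family; overlaps spanning distinct families split the weight equally,
preserving the invariant that total assigned weight never exceeds the
number of aligned reads. Mate pairs count once (read-1 records
represent the fragment). Family counts are rounded half-to-even before
the count-model test; the bias is bounded by 0.5 count and symmetric.

## RRBS methylation

A minus-strand call at position p belongs to the CpG whose plus-strand
C is at p − 1; counts are pooled and the ratio recomputed from pooled
counts (never averaged per-strand ratios, which would weight strands
equally regardless of depth). The depth filter is combined depth ≥ 8.
Conversion efficiency is T/(T + C) over the fill-in cytosines created
at MspI fragment ends during end repair — these are unmethylated by
construction, so residual C there measures incomplete conversion.
`correct_for_conversion` inverts
`observed = level + (1 − level)(1 − efficiency)` to recover the
underlying level. Region means are unweighted across sites (exposed as
a choice); coverage weighting would let a single deep CpG dominate a
promoter. Differential methylated-region calling is out of scope.

## IP-MS statistics

Size factors follow the median-of-ratios method: the per-sample median
of count/geometric-mean ratios over proteins detected in every sample.
No rescaling to unit geometric mean is applied (factor *ratios* are the
meaningful quantities). The two-group test conditions the split of the
normalised group sums on their total: with a common dispersion φ the
group sums are negative binomial with sizes n/φ and a shared success
probability, making the conditional law negative hypergeometric — free
of the unknown mean — and the two-sided p sums all outcomes no more
probable than the observed one. φ → 0 recovers the conditional binomial
(exact Poisson) test. φ is estimated by pooled method of moments
(`(variance − mean)` regressed on `mean²` across all protein/group
cells), clipped at 0. This is an intentionally transparent approximation
to an edgeR-style exact test; the published thresholds (fold change > 4,
padj < 0.05, both strict) dominate the final call set. Fold changes use
normalised group means with a 0.5 pseudocount so dropout controls (zero
counts in the knockout IP) give finite values. Calibration at the
default conditions: null type-I error ≈ 0.045 at nominal 0.05, power
1.0 for 8× partners at n = 3 vs 3 and mean 20 — both recomputed by the
acceptance script, not asserted as constants.

## Synthetic data

All generators are pure functions of `SimConfig` (seed included): the
same configuration reproduces byte-identical files. Default scale: 2
chromosomes × 1 Mb, 300 promoters (60% HCP, of which 40 are the
germline-like inactive target set), 20 chromatin marks with a planted
log2FC ladder {−2,−1,0,1,2}, a 2 000-gene × 4-gRNA screen in triplicate
with 15 planted hits at 6× enrichment plus olfactory and low-expression
decoys, 1 000 RNA genes with 50 planted 4× upregulations, 60 bisulfite
regions at levels {0.05, 0.5, 0.95} with depth 20 and conversion 0.99,
20 TE families × 8 copies with a planted 4× IAPEz fold and multimapping
multiplicities up to 4, and 400 proteins with 12 planted 8× partners.
Everything completes in well under two minutes on one CPU.

Promoter sequences are drawn from class-specific compositions (i.i.d.
GC-rich for HCP; CpG-depleted by breaking the G of a CpG with
probability 0.45/0.85 for ICP/LCP, mimicking genome-wide CpG depletion)
and each emitted promoter is verified against the package's own
classifier, resampling on failure — classifier tests are therefore
self-consistent rather than distribution-dependent. Count data are
negative binomial via gamma–Poisson mixing. Between-replicate
dispersions are 0.05 for screen gRNAs and RNA, 0.01 for abundant TE
families (CV ≈ 10%, typical of high-count features in cell-line
replicates), 0.1 for spectral counts.

What the generators do **not** emulate: real mammalian base composition
and repeat structure, mappability artefacts, gene–TE overlap, batch
effects, peptide-level identification noise, or isoform complexity.
Passing tests therefore demonstrate correctness of the statistical
machinery and bookkeeping, not performance on the idiosyncrasies of
real libraries.

## Numerical conventions

Strict inequalities at every published threshold (ratio 0.45/0.65, GC
0.55, FPKM 1 and 5, p 0.05, fold 2/3/4, padj 0.001/0.05, depth ≥ 8 as
stated). Ties in every ranking break lexicographically. Half-open
0-based intervals throughout; SAM positions converted on read. All
stochastic tests fix their seeds; the acceptance script derives every
random stream from `--seed`.

## Known limitations

- The NB test uses a single common dispersion; strong mean–dispersion
  trends would mis-calibrate extreme-count proteins (tagwise shrinkage
  is deliberately out of scope).
- The min-p gene scorer used to emulate screen gene summaries is a
  placeholder for α-RRA, adequate for exercising the filter chain but
  not a reimplementation of it.
- Orphan minus-strand CpG calls (no reference partner) are kept and
  flagged rather than resolved against the reference sequence.
- bedGraph tracks are assumed non-overlapping within a chromosome;
  overlapping intervals would silently take the later interval's value.
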