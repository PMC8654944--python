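# Methods

This note documents the models and procedures implemented in sng4kit, the
defaults and why they were chosen, what the synthetic world does and does
not emulate, and the numerical conventions that govern edge cases.

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention); chromosome order is
lexicographic throughout. A fragment overlaps a region iff they share at
least one base, so a fragment ending exactly at a region's start does not
count. The two Tn5 insertion ("cut") sites of a fragment are its `start`
and `end − 1`; no ATAC-style +4/−5 shift is applied, since the adapters
here are inserted directly by pA-Tn5 and the fragment bounds already are
the insertion positions. A fragment overlapping two disjoint regions counts
once in each. `(chrom, start, end, barcode)` is the deduplication key;
readers reject duplicate keys unless asked to collapse them (summing
`read_support`), so the dedup state of a library is always explicit.
Region-level signal is quantified as fragment-overlap counts per locus
rather than per-base pileup depth — the two are monotone-equivalent for the
rank-based statistics used downstream.

## The synthetic world

The simulator emulates a two-cell-type, droplet-barcoded G4 profiling
experiment. Its defaults are fixed and constitute the stated world of all
acceptance tests:

| parameter | default | rationale |
|---|---|---|
| genome | 3 chromosomes × 2 Mb | large enough that ~600 peaks occupy ~3% of it, as real G4 peak sets do relative to footprint |
| `n_peaks` / `peak_width_mean` | 600 / 300 bp | desk-scale stand-in for tens of thousands of G4 loci; widths gamma(4, 75), clipped to [50, 900] bp |
| `shared_fraction` | 0.5 | roughly half of G4 peaks are observed in both cell types in comparable data (the rest split evenly A/B-specific) |
| `shared_strength_factor` | 2.0 | loci detected in both cell types are systematically the stronger ones; the world must encode this for the common-vs-specific support comparison to have a defined direction (see below) |
| `n_cells_a/b` | 300 each | a 1:1 mixed population at desk scale |
| `median_frags_per_cell` | 800 | the observed regime of single-nucleus G4 libraries (median several hundred to ~1,200 unique fragments per cell). The negative-binomial mean is set to this value; with dispersion 10 the realized median sits ~5% below it |
| `frag_count_dispersion` | 10 | single-cell depth is overdispersed relative to Poisson; NB size 10 gives a realistic CV ≈ 0.3 |
| `frip` | 0.45 | bulk fraction of reads in G4 peaks above 40% in this assay |
| fragment length | lognormal(5.2, 0.45), clip [30, 1000] bp | ≈ 180 bp mode, tagmentation-like tail |
| `bulk_depth` | 200,000 × 2 replicates per type | deep enough that same-type replicate r_s > 0.9 at the reference loci |
| `n_genes` / `n_diff_promoters` | 200 / 20 | a differential signal small relative to the gene universe |
| `diff_rate_ratio` | 4.0 | differential peaks are boosted to 4× the mean peak strength |
| `cn_high_fraction` | 0.3 | a minority of differential genes sit in amplified regions (cn > 1.5); the rest draw Normal(1.0, 0.1) |
| `read_support` | 1 + Poisson(0.3) | exercises the dedup-vs-read distinction without modelling PCR |

Mechanics: peaks are placed uniformly without overlap (1,200 bp clear of
chromosome ends so targeted fragments never need clipping); strengths are
gamma(2, 1) draws, doubled for shared peaks. Each fragment is, with
probability `frip`, centred uniformly inside a peak of the cell's
repertoire (shared + own-type-specific, chosen proportionally to strength)
— so targeted fragments may spill over peak edges, matching half-open
overlap counting — and otherwise placed uniformly on the genome.
Differential promoter genes receive a TSS whose strand-aware promoter
window fully contains one A-specific peak; other promoters are placed to
avoid all type-specific peaks and one another. Every stage draws from its
own `default_rng([seed, stage])` stream, so outputs are byte-reproducible
and stages are individually re-runnable.

What the world does **not** emulate: chromatin-accessibility bias in the
background, per-cell FRiP variation, doublets, PCR duplication structure,
cell-cycle G4 dynamics, and realistic genome scale. A green test therefore
establishes algorithmic correctness and statistical behaviour under the
stated generative model, not performance on real libraries.

Why `shared_strength_factor` exists: with class-independent strengths the
within-cluster support distributions of shared and specific peaks would be
identical by construction, and the observed tendency of well-supported
peaks to be common to both cell types would be a coin flip in simulation.
The boost encodes that biological observation as part of the world; it is a
modelling statement, not a tuning knob.

## Signal transform for identity analysis

`transform_signal_matrix` operates on the regions × libraries RPM matrix:

1. z-score each region row across libraries (sample sd, ddof = 1, matching
   R's `scale`). Rows with zero variance carry no locus pattern; they are
   mapped to the global minimum z-value so that "flat" reads as "low
   signal" — mapping them to z = 0 would park silent loci mid-scale.
2. cap all entries above the global 75th percentile (linear interpolation)
   of the matrix at that percentile. The axis choices (per-row z-score,
   global cap) are declared conventions: the source procedure states only
   matrix-level operations.
3. min-max rescale the matrix to [0, 1] (all-equal input maps to zeros).

Consequences: at least the top quarter of entries equals 1 (exactly a
quarter when all pre-cap entries are distinct and their count is divisible
by 4), and constant rows land on the global minimum of the image.

## k-medoids: PAM and CLARA

PAM: BUILD greedily seeds k medoids (first the 1-medoid optimum, then the
candidate minimizing total dissimilarity); SWAP repeatedly evaluates every
(medoid, non-medoid) exchange and applies the single best strictly
improving one, ties toward the lowest item index, until none improves. The
procedure is deterministic given the dissimilarity matrix; total cost
decreases monotonically across swaps. Note that swap descent is a local
search: on small random instances it reaches the exhaustive optimum in
roughly 9 of 10 cases and otherwise terminates in a genuine swap-local
optimum — the same behaviour as the canonical R implementation, which it
matches on 97 of 100 random instances.

CLARA draws `n_samples` (5) subsamples of size `sample_size` (40 + 2k, the
original convention), always including the best medoids found so far, runs
PAM on each, scores candidate medoid sets by total dissimilarity over *all*
items, and returns the best. Subsample indices are kept sorted so that with
`sample_size ≥ n` CLARA is exactly PAM on the full set.

Cell clustering uses PAM on Euclidean distances of the LSI embedding up to
2,000 cells and CLARA beyond. The LSI stand-in for the original
graph-based pipeline claims cluster recovery, not algorithmic fidelity:
binarize counts, weight by term frequency × log(1 + n_cells/df), row-L2
normalize, dense SVD (deterministic signs: the largest-magnitude loading of
each component is made positive), drop the depth-correlated first
component, keep 15 dimensions by default.

## Identity imputation

Each single-cell cluster's pseudobulk RPM profile over the merged reference
set is correlated (Spearman, average ranks for ties; constant profiles are
flagged and recorded as r_s = 0) with every bulk reference library. The
cluster receives the label of the best-correlated reference; the margin is
best minus second-best label-level r_s, and calls under 0.05 are flagged
low-confidence rather than rejected. Average-linkage hierarchical
clustering on d = 1 − r_s and the CLARA locus-archetype partition (K = 4:
shared-high / A-specific / B-specific / low) are computed alongside as
concordance views.

## Peak calling

The caller is an explicit functional stand-in for MACS2-style calling, not
a clone: windows of 147 bp (the fragment-extension size of the original
invocation) are scanned at 73 bp stride; the per-window count is the number
of overlapping fragments; the background rate is the exact uniform-null
expectation for overlap counts, λ = (N·w + B)/G for N fragments of total
length B on genome length G — the fragment footprint term B/G matters: with
λ = N·w/G the null would be anti-conservative by roughly the ratio of mean
fragment length to window size. p is the upper-tail Poisson probability,
q is Benjamini–Hochberg over all scanned windows, and windows passing
p ≤ 1e−5 and −log10(q) ≥ 2 (defaults) are merged within 100 bp, scoring
each peak by its best window. The −log10(q) floor is configurable because
the bulk-scale analyses this mirrors used a far larger value (800) that is
unreachable at simulated depths; q-scores are capped at 300 where q
underflows. There is no local-background (peak-shadow) modelling and no
model building — the original pipeline ran model-free as well.

## Supporting cells and the common/specific comparison

A supporting cell of a peak is a barcode with ≥ 1 deduplicated fragment
overlapping it; multiplicities within a barcode never count twice. The two
clusters' peak sets are partitioned by ≥ 1 bp mutual overlap into common
pairs (a peak overlapping two partners appears once, with both partners
listed) and specific remainders. Per class the support distribution is
summarised (median, mean, quartiles), the top-quartile loci are extracted
with a ties-included ≥-threshold at the 75th linear-interpolation
percentile, and common vs specific support is compared with a two-sided
Mann–Whitney U test (average-tie ranks, normal approximation). The
rank-sum test is an addition that makes the directional claim testable;
support counts are *not* corrected for per-cell sequencing depth, a known
confounder left uninterpreted here as in the source procedure.

## Differential promoters and copy number

Promoter windows are [TSS − 1000, TSS + 100) on '+' and mirrored on '−',
clipped to chromosome bounds; windows must be disjoint for counting. Per
gene, cut sites are counted per cluster and tested with a two-sided
Fisher's exact test on [count, total − count] per cluster, computed from
first principles by hypergeometric enumeration (the original GUI tool
publishes thresholds, not its statistic); log2FC uses pseudocount 1 on
counts with library-size denominators. Records passing |log2FC| > 0.6 and
raw p < 0.05 (BH q is reported alongside but not filtered on, matching the
source thresholds) are ranked by p, ties by |log2FC|, and truncated to the
top 50. Copy-number annotation joins a gene-level table on the
log2(relative to ploidy + 1) scale and reports the fraction of records
exceeding 1.5.

Known limitation: cut-site counts are clumped — both insertion sites of
one fragment often fall inside the same ~1.1 kb promoter — so counts are
roughly doubled Poisson and the Fisher test is anti-conservative for weak
effects (observed false-positive rate ≈ 3× nominal at p < 0.05 in
simulation). True differential promoters at the simulated effect size are
separated from this noise floor by dozens of orders of magnitude of p, so
ranking and recall are unaffected; analysts filtering near the threshold
should prefer fragment-level counts.

## Determinism

Every stochastic operation takes an explicit seed; there is no global
random state. The workflow report (`report.json`) contains no timestamps
or absolute paths and is byte-identical across reruns of the same
configuration and seed.
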