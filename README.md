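# sng4kit

Downstream analysis toolkit for **single-nuclei G4 CUT&Tag** fragment data.

G-quadruplexes (G4s) are four-stranded DNA secondary structures that form in
guanine-rich regions and participate in transcription, replication and genome
instability. Antibody-directed tagmentation (CUT&Tag with the BG4
structure-specific antibody) combined with droplet barcoding yields, per
nucleus, a set of deduplicated genomic fragments marking G4 loci. This
package implements the analysis that sits downstream of such an experiment,
for analysts who have 10X-style fragment files and want to know: *do G4
profiles alone resolve cell identity in a mixed population, and how variable
is G4 formation from cell to cell?*

## What it computes

Given barcoded fragments (`chrom  start  end  barcode  read_support`, 0-based
half-open) and reference peak sets, the pipeline:

1. **Cell clustering** — builds a cells × peaks count matrix, embeds it with
   latent semantic indexing (TF-IDF weighting of binarized counts, row-L2
   normalisation, truncated SVD with the depth-tracking first component
   dropped) and partitions cells with k-medoids (PAM, or its subsampling
   extension CLARA for large runs). PAM/CLARA are implemented from scratch:
   greedy BUILD, then best-improvement SWAP over all medoid/non-medoid
   exchanges.
2. **Identity imputation** — aggregates each cluster into a pseudobulk
   library, computes RPM profiles over a merged reference peak set, and
   assigns each cluster the label of the bulk reference library with the
   highest Spearman r_s (reporting the margin over the second-best label).
   The joint signal matrix is also z-scored per locus, capped at the global
   75th percentile, rescaled to [0, 1] and clustered by CLARA (K = 4 locus
   archetypes) for concordance.
3. **Supporting cells** — for every peak and cluster, counts the number of
   distinct barcodes with ≥ 1 overlapping fragment; partitions the two
   clusters' peak sets into common and cluster-specific; summarises support
   distributions, extracts the top-25%-supported loci, and tests
   common-vs-specific support with a Mann–Whitney rank-sum test.
4. **Differential promoters** — counts Tn5 cut sites in promoter windows
   (1,000 bp upstream to 100 bp downstream of each TSS, strand-aware),
   computes per-gene log2FC = log2(((a+1)/N_A) / ((b+1)/N_B)) with a
   two-sided Fisher's exact test, filters at |log2FC| > 0.6 and p < 0.05,
   ranks by p, and annotates the top genes with copy-number status
   (log2(relative to ploidy + 1) > 1.5).

Peaks can be called from any fragment collection with a Poisson
sliding-window scan (window 147 bp) with Benjamini–Hochberg control.

A deterministic **simulator** generates the whole world for testing: two
cell types with partly shared, partly type-specific peak repertoires,
negative-binomial per-cell depth, a configurable fraction of reads in peaks,
bulk replicate libraries, TSS and copy-number tables, and full ground truth.

## Worked example

```bash
sng4kit run-all --outdir run7 --seed 7
```

simulates 300 + 300 cells (median ≈ 800 fragments per cell, FRiP 0.45,
600 peaks of which half are shared) and runs every stage. It prints:

```json
{
 "report_sha256": "11a6bad4126a85523ce3e40d0ecc02db54f4822a0436c372c9a3a36bc3d2e96a",
 "ari_vs_truth": 1.0,
 "identity": [
  {"cluster": "cluster0", "label": "A", "r_s": 0.9873542735774589,
   "margin": 0.5483404525948693, "low_confidence": false},
  {"cluster": "cluster1", "label": "B", "r_s": 0.9860897938737292,
   "margin": 0.5442961312034673, "low_confidence": false}
 ]
}
```

Reading: the two k-medoids clusters coincide exactly with the simulated cell
types (adjusted Rand index 1.0); cluster 0's pseudobulk correlates at
r_s ≈ 0.987 with the type-A bulk references, 0.55 higher than with type-B —
a confident identity call (and symmetrically for cluster 1). The support
analysis (`run7/support_comparison.tsv`) shows the cell-to-cell variability
signature:

```text
cluster  n_common  n_specific  median_common  median_specific  mann_whitney_u  p_value      direction
0        293       131         152.0          108.0            24416.5         7.43e-06     common>specific
1        293       129         172.0          108.0            27778.0         1.44e-14     common>specific
```

i.e. peaks detected in both cell types are supported by more cells (median
152–172 of 300) than cluster-specific peaks (median 108), in both clusters.
`run7/differential_promoters.tsv` lists the enriched promoter peaks with
their counts, log2FC, Fisher p, BH q and copy-number annotation; on this
world all 20 simulated differential promoters pass the filter.

Every artifact (fragment files, BEDs, matrices, report) is plain text and
re-readable by the package's own readers; `report.json` is byte-identical
across reruns with the same seed.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full workflow from scratch at the stated world's defaults with
the given seed (intermediate artifacts under `scratch/`) and writes the
results JSON.

## Library layout

| module | contents |
|---|---|
| `sng4kit.core_io` | fragment/BED/TSS/copy-number readers and writers, domain types |
| `sng4kit.synthetic_data` | the simulator and its ground truth |
| `sng4kit.signal` | count/RPM matrices, FRiP, pseudobulk aggregation, bedGraph tracks |
| `sng4kit.clustering` | Spearman matrices, signal transform, PAM/CLARA, hierarchical clustering, LSI, identity imputation |
| `sng4kit.support` | supporting-cell counts, peak partitioning, rank-sum comparison |
| `sng4kit.peaks_diff` | interval algebra, Poisson window peak caller, promoters, differential test, copy-number annotation |
| `sng4kit.pipeline` / `sng4kit.cli` | orchestration and the `sng4kit` command |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
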