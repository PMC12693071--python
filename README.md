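# sccnv

Single-cell whole-genome copy-number analysis of tumor subclone evolution,
built for studying how cancers acquire resistance under therapeutic
selection (e.g. melanomas relapsing on immune-checkpoint inhibitors, or
tumor lines repeatedly challenged with killer T cells).

Shallow single-cell WGS (~1M reads per cell) resolves the copy-number
variant (CNV) architecture of a tumor at the level of individual cells.
`sccnv` turns a cells × bins read-count matrix into:

1. **Per-cell CNV profiles** — counts in count-equalized variable genomic
   bins are GC-corrected by lowess regression, converted to bin ratios
   r<sub>b</sub> = c<sub>b</sub> / mean(c), segmented per chromosome by
   permutation-thresholded binary segmentation, and scaled to integer copy
   numbers CN<sub>b</sub> = round(r̄<sub>b</sub> · ψ) with the sample ploidy
   ψ = 2·(DAPI A-peak median / D-peak median) from flow sorting.
2. **Quality control** — cells fail on mapping quality < 1, reads < 10% of
   the cohort mean, or > 10% empty bins; on mean Pearson correlation with
   their k nearest neighbors (k = 5 / 0.8 human, 4 / 0.7 mouse); diploid
   contaminants are identified by pooling observed segment-ratio
   coefficients of variation with 1,000 CVs simulated from N(0, 0.01) and
   fitting a two-component normal mixture by EM.
3. **Subclones** — UMAP on log2 segment ratios (seed 31, min_dist 0.1,
   n_neighbors 20, manhattan, spread 3), hierarchical density clustering
   (minimum subclone size 6, noise removed), consensus integer profiles as
   per-bin medians, and sample dominance (>50% of cells from one group).
4. **Phylogeny** — the minimum event distance (MED) between consensus
   profiles: the fewest ±1 events on contiguous bin runs converting one
   profile into the other, with copy number 0 unrecoverable; neighbor
   joining on the MED matrix rooted at an all-CN-2 diploid node.
5. **Resistance calls** — per gene and subclone, the median copy-number
   ratio; genes with CV < 0.18 across baseline-dominant subclones are
   called resistance-specific amplified/deleted when a resistant-dominant
   subclone exceeds the baseline maximum (falls below the minimum) by more
   than 0.09; genes with CV > 0.18 enter the preexistence branch, where
   baseline subclones with |z| > 1 are candidate carriers confirmed by the
   same margin rule.  Calls are functionalized against CRISPR-screen
   resister/sensitizer catalogs (≥ 2 concordant measurements per gene).
6. **Bulk integration and assays** — relapse-specific recurrent CNV gene
   extraction (≥ 3 patients), gene-set overlap, pairwise Fisher's exact
   co-occurrence with Benjamini–Hochberg control, BH3-profiling cytochrome
   c release, coculture growth normalization, and caliper tumor volume
   (l·w²/2).

Every stage is driven and validated by a synthetic-data generator
(`sccnv.synthetic`) that plants known subclonal CNV structure, GC bias,
depth variation and diploid contaminants — no sequencing data download is
required.

## Worked example

```python
from sccnv.synthetic import (default_study_spec, make_bin_grid,
                             simulate_cells, simulate_dapi)
from sccnv.pipeline import run_pipeline
from sccnv.evaluate import score_pipeline

spec = default_study_spec(seed=1)        # 2,000 bins, 5 subclones,
grid = make_bin_grid(spec)               # 15% diploid contaminants
counts, sheet, truth = simulate_cells(spec, grid)
dapi = simulate_dapi(spec, grid)

result = run_pipeline(counts, grid, sheet, dapi, seed=1)
print(result.subclones.names)
print(result.tree.newick)
print(score_pipeline(result, truth))
```

prints (abridged):

```
['c1', 'c2', 'c3', 'c4', 'c5']
(diploid:2.0,(c2:1.0,c5:1.0):1.0,(c1:1.0,(c3:1.0,c4:1.0):0.0):2.0);
{'n_subclones_found': 5, 'n_subclones_planted': 5, 'ari': 1.0,
 'consensus_accuracy': 1.0, 'consensus_accuracy_min': 1.0,
 'diploid_recall': 0.972972972972973,
 'diploid_false_positive_rate': 0.0, 'resistant_clade_recovered': 1.0}
```

All five planted subclones are recovered with perfect cell assignment
(adjusted Rand index 1.0), their consensus integer profiles match the
planted profiles on every bin, 36 of the 37 sequencable diploid
contaminants are flagged, and the three resistant-sample subclones form
one clade in the diploid-rooted tree, as planted.

A synthetic dataset can also be generated from the shell:

```sh
sccnv simulate --config spec.yaml --outdir out/ --seed 7
```

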