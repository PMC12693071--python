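# Methods

## Scope and data model

`sccnv` analyzes shallow single-cell whole-genome sequencing of tumors
sampled before and after a selective pressure (a "baseline" and a
"resistant" group of samples).  The unit of analysis is a cells × bins
matrix of read counts over an ordered grid of genomic bins (0-based,
half-open coordinates; bin indices are the unit of genomic length
throughout).  Bins are *variable-width* and count-equalized: in a diploid
genome every bin receives the same expected number of reads, so expected
counts scale with copy number and GC bias only, never with a bin's
physical width.  Desk-scale defaults (2,000 bins, ~1e5 reads per cell)
exercise every algorithm; nothing in the code depends on the genome-wide
scale (~220 kb bins, ~1M reads).

## Per-cell copy number

**GC correction.** Counts are divided by a lowess fit of count versus GC
(span 0.3, 3 robustness iterations; both exposed in `PipelineParams`).
The fitted trend is rescaled to mean 1 before division, so the corrected
counts preserve the cell's total signal; the fit is floored at 1e-3 of
the mean count to guard against non-positive values in sparse GC tails.
Constant GC degrades to an identity transform with a warning.

**Ratios.** Bin ratios divide corrected counts by the cell's mean bin
count; their mean is exactly 1 per cell, making profiles invariant to
sequencing depth.

**Segmentation.** Chromosomes are segmented independently by recursive
binary segmentation: the candidate split maximizes a pooled-variance
t-statistic over all splits leaving at least `min_width` = 3 bins on each
side, and is accepted when a permutation test (1,000 permutations of the
segment's bins, level alpha = 0.01) supports it.  The permutation loop
runs in batches and stops early once the exceedance count already rules
out significance — this changes nothing about which splits are accepted,
only the work spent rejecting them.  Any changepoint method honoring the
same contract (piecewise-constant output, segment mean = member-bin mean,
splits only under a level-alpha test, chromosome independence) is
interchangeable here; circular (two-boundary) candidate evaluation was
not used because its O(n²)-per-permutation cost buys nothing at these
segment lengths and noise levels, and the planted-breakpoint recovery
tests are already saturated (≥ 95% localization within ±1 bin at step
0.5, noise sd 0.05).

**Ploidy and integer copy number.** Sample ploidy is 2 × (median DAPI
intensity of the aneuploid peak / median of the diploid peak), valid when
most sequenced cells derive from the aneuploid peak.  Per-cell integer
copy number is round(segment ratio × ploidy), rounding ties half away
from zero and flooring at 0.  The half-away tie rule is applied
consistently here and in consensus profiles so that a 2.5 median yields 3.

## Quality control

Three per-cell filters:

1. **Basic:** mean mapping quality < 1; reads below 0.1 × the cohort mean
   (the published 100K floor at a nominal 1M, applied proportionally so
   desk-scale runs behave identically; an absolute floor is available via
   `min_reads_absolute`); > 10% empty bins.
2. **k-NN correlation:** a cell is dropped when the mean Pearson
   correlation of its segment-ratio profile with its k most-correlated
   peers is below a threshold — k = 5, 0.8 for human; k = 4, 0.7 for
   mouse (`PipelineParams.mouse()`).
3. **Diploid identification:** the coefficient of variation (CV) of each
   cell's segment ratios is pooled with 1,000 simulated diploid CVs drawn
   from N(0, 0.01) truncated at zero (a CV cannot be negative — the
   truncation is our reading of the simulation recipe), and a
   two-component Gaussian mixture is fitted by EM (k-means
   initialization, tolerance 1e-8, ≤ 500 iterations, seeded).  The
   component capturing the larger share of the simulated mass is the
   diploid component with mean m and sd s; a cell is diploid iff its
   CV ≤ m + 5s.  If EM fails to converge the classifier falls back to the
   fixed cutoff 5 × 0.01 with a warning.

Two deliberate design choices here.  First, the decision direction:
taken literally, "excluded if the CV *exceeds* 5 sd of the diploid
component" would flag high-CV (aneuploid) cells as diploid, contradicting
the construction — simulated diploid CVs are near zero.  The default
flags LOW-CV cells as diploid; the literal reading remains available via
`literal=True`.  Second, staging: diploid identification sees every
basic-passing cell rather than only k-NN survivors.  A diploid cell's
segment-ratio profile is flat, and flat profiles are mutually
decorrelated after normalization, so the correlation filter can remove
exactly the cells the diploid classifier is supposed to label; running
the classifier on the k-NN-filtered set would make diploid recall
meaningless.  The retained set is still
`passed_basic AND knn_pass AND NOT is_diploid`.

## Subclone discovery

Log2-transformed segment ratios (zero ratios floored at 1e-3) are
embedded by UMAP with the published settings (seed 31, min_dist 0.1,
n_neighbors 20, manhattan metric, spread 3) and clustered by hierarchical
density-based clustering with minimum cluster size 6; cells labeled noise
and clusters below 6 members are discarded.  Because UMAP equalizes
density, a homogeneous population embeds as a uniform cloud that plain
excess-of-mass cluster selection shatters into noise; clustering is
therefore run with a scale-aware cluster-selection epsilon (twice the
median distance to the 6th nearest embedding neighbor) and a single root
cluster allowed.  Plain DBSCAN is available behind
`cluster_method="dbscan"`.  Clusters are labeled c1…cK by decreasing
size.

Per subclone: the consensus integer profile is the per-bin median of
member integer CNs (ties half away from zero); the consensus ratio
profile is the per-bin median ratio; composition counts cells per sample;
and the subclone is baseline- or resistant-dominant when strictly more
than 50% of its cells come from that group's samples.

## Phylogeny

An *event* adds or subtracts one copy over a contiguous run of bins
within one chromosome; a bin at copy number 0 can never be re-gained or
decremented.  Event counting over a consensus profile reports maximal
constant runs differing from the base copy number (2), excluding
single-bin runs from the total.

The minimum event distance (MED) between two profiles is computed per
chromosome from the difference profile split into gain and loss parts;
because each bin moves monotonically toward its target, the minimum is
the sum of positive increments of each part, and a profile is unreachable
(infinite distance) iff the source has CN 0 where the target does not.
This closed form is verified in the test suite against exhaustive
shortest-path search (breadth-first on tiny instances; A* with the
admissible heuristic max(positive diff) + max(negative diff) — each event
moves a bin by at most one and cannot mix gains with losses — on random
pairs up to length 8, CN ≤ 4).

Trees are built by neighbor joining on the pairwise MED matrix over the
subclones plus an all-CN-2 diploid root, then rooted at the diploid node.
MED is directional under the zero rule, so the matrix entry is the
minimum of the two directions; building fails with a diagnostic when a
pair is unreachable both ways.  Consensus profiles of real tumor
subclones essentially never hit CN 0 over whole bins at these bin sizes,
so the symmetrization is inert in practice.

## Resistance calls

For each gene (a set of grid bins) and subclone, the *ratio* is the
median over member cells of the median bin ratio across the gene's bins
(bin ratios, not integer CNs, preserve sub-integer dosage shifts).  The
per-gene CV (population sd / mean) across baseline-dominant subclones
gates two mutually exclusive branches; a CV of exactly 0.18 falls in
neither (the published gates are strict "< 0.18" and "> 0.18", so the
boundary is undefined and documented as excluded).

* **CV < 0.18:** resistance-specific amplified (deleted) when some
  resistant-dominant subclone's ratio exceeds the baseline maximum
  (falls below the minimum) by strictly more than 0.09.  Calls by a
  strict subset of resistant-dominant subclones are *private*.
* **CV > 0.18:** baseline subclones with |z| > 1 (z-scores over
  baseline-dominant ratios, population sd) are preexistence candidates;
  a (gene, candidate) pair is confirmed when both (1) some
  resistant-dominant subclone and (2) the candidate itself clear the
  0.09 margin against the extreme ratio of the *non-candidate* baseline
  subclones.  The deletion mirror applies the margin below the
  non-candidate minimum; the published text states the amplified pattern
  explicitly and we assume the symmetric form for deletions.  Requires
  ≥ 3 baseline-dominant subclones so candidates leave a reference.

Calls are annotated with CRISPR-screen evidence weights — deleted genes
against resister catalogs, amplified genes against sensitizer catalogs
(≥ 2 concordant measurements per gene; genes supported in both directions
stay in both catalogs) — and a report label that separates subclones with
opposite-direction calls for the same gene by a semicolon.

## Bulk integration

A gene is relapse-specific in a patient when altered in ≥ 1
disease-progression tumor and no patient-matched baseline tumor (tumors
unioned per patient; patients without a baseline are excluded with a
warning), and recurrent at ≥ 3 patients (≥ 4 for enrichment input).
Pairwise co-occurrence across patients uses a two-sided Fisher's exact
test implemented from the hypergeometric definition (summing table
probabilities ≤ the observed with a 1 + 1e-7 relative tolerance, matching
R), with BH-adjusted q-values over all tested pairs and the display rule
p < 0.05 and odds ratio > 1.

## Assay formulas

Cytochrome c release = 100 − 100·(pep − ala)/(dmso − ala), with
alamethicin the full-release and DMSO the no-release control; raw values
are primary and a [0, 100] clamp is optional (whether published figures
clamp is unstated).  Growth series divide by the first time point per
well; wells with non-positive start signal are excluded.  Tumor volume is
length·width²/2 (inputs auto-ordered), and a relapse is two consecutive
volume increases.

## The synthetic-data generator

`sccnv.synthetic` emulates: per-cell depth drawn log-normally around a
nominal mean (default 1e5 at desk scale; scale of 0.25) with a dropout
tail (5% of cells at 2–8% of nominal) and a low-mapping-quality tail
(2%); a unimodal GC bias exp(−s·((gc − 0.5)/0.2)²) with s = 0.5, removable
by lowess; negative-binomial (Poisson-gamma) counts with relative
overdispersion 0.05; integer-CN subclone structure from explicit event
lists; diploid contaminants drawn binomially at an expected fraction and
cycled through sample labels; and DAPI peak medians consistent with the
planted sample ploidies.  The default study dataset plants five tumor
subclones of 51 cells (three resistant-sample subclones forming a derived
clade, two baseline-sample subclones) over 2,000 bins in 10 chromosomes
with 15% diploid contaminants — event widths of 60–120 bins give every
subclone pair at least one ~0.5 ratio step of separation.  Noise and
depth parameters are conventions chosen once to match shallow scWGS count
behavior; no published dispersion values exist to calibrate against.

Not modeled: read-level artifacts (the generator emits counts, not
FASTQs), mappability-driven bin-width derivation, doublets,
replication-timing or amplification-chemistry biases, and sub-bin event
boundaries.  Passing recovery tests therefore demonstrates algorithmic
correctness under a realistic count model, not robustness to every
artifact of real libraries.

A companion generator (`simulate_gene_ratio_matrix`) plants
resistance-call structure directly at the gene-ratio level — baseline
ratios at 1.0 with CV ≤ 0.05, specific shifts of 0.25 in random resistant
subsets, and preexisting shifts of 0.6 shared by one baseline candidate —
for high-replicate classifier recovery tests.

## Problem sizes and determinism

Default test and reproduction sizes: 2,000 bins × ~300 cells for the
pipeline; 100 replicates for classifier recovery and breakpoint
localization; 500 random pairs (plus an exhaustive small sweep) for the
MED oracle; all 2×2 tables with margins ≤ 12 for the exact-test oracle.
All randomness flows from explicit seeds (simulation specs, segmentation
permutations, EM, UMAP's seed 31), and identical seeds reproduce
datasets and results byte-for-byte.

## Known limitations

Integer CN assumes one ploidy per sample; subclones whose true ploidy
deviates strongly from the sample's DAPI estimate will round to shifted
integers.  MED here is the unit-step contiguous-event distance — no
whole-genome duplication events and no allele specificity.  The
preexistence branch cannot distinguish a candidate carrying the event
from one carrying an unrelated dosage shift in the same direction.  The
co-occurrence test treats patients as exchangeable and ignores within-
patient correlation of alterations on the same chromosome arm.
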