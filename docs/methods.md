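# Methods

This note documents the models, parameter choices and numerical conventions
behind `hkcre`, what the synthetic data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## Coordinates and interval arithmetic

All coordinates are 0-based half-open (BED). Readers accept 1-based
fully-closed input (`convention="one-based"`) and shift starts on read.
Multi-chromosome inputs are processed independently per chromosome; sorting
ties are broken by (end, cell_type) so every operation is deterministic.

`merge_within(regions, g)` merges two intervals when their gap is ≤ g bp
(overlap and adjacency count as gap ≤ 0), taking the transitive closure.
The default merge distance of 20 bp matches the bedtools/bedr-style
semantics of "merge with a distance of 20 bp". `gaps` is the exact
per-chromosome complement including terminal segments (filtered downstream).
All three primitives are verified against quadratic brute-force oracles
(pairwise gap-graph closure, all-pairs scans, per-base occupancy) in the
test suite.

## Iterative cross-cell merging

Given per-cell-type region sets (ABC rows with score ≥ 0.015; the boundary
is kept), each pass (1) pools the remaining raw regions of all cell types
and merges with gap ≤ 20 bp, (2) counts the **distinct** cell types
contributing ≥ 1 raw region to each merged region — a cell type contributing
two fragments is still one cell type — and selects the regions attaining the
current maximum (first pass: all regions whose fraction reaches
`hk_fraction`; if none does, the maximum), (3) removes raw regions
overlapping a selected region by ≥ 1 bp, and (4) repeats until the pool is
empty. Consequences, covered by tests: outputs are pairwise non-overlapping;
every raw region overlaps exactly one output; supporting-cell counts never
increase across passes. A region is housekeeping iff its activity fraction
is ≥ `hk_fraction`, inclusive (19 of 21 cells = 90.47% passes a 90% bar).

The stability sweep re-runs the merge over subsampled cell panels
(seeded `SeedSequence` substreams, one per replicate) for HK definitions of
70/80/90/100%, recording HK counts and median lengths.

## Negative samples

All CRE sets are pooled and merged with a minimum gap width of 100 bp; gaps
are computed per chromosome; terminal gaps (touching position 0 or the
chromosome end) and blacklisted intervals are dropped; gaps shorter than
3 kb are dropped; `ns_count` gaps are drawn uniformly without replacement
and the central 500 bp window of each is emitted (odd gaps center at
floor(midpoint) − 250). The literal 3 kb rule guarantees ≥ 1,250 bp
clearance between a window edge and the nearest pooled CRE — comfortably
more than the 250 bp histone extension. The whole-genome default is 10,000
windows; the synthetic bundle uses 400 because its 20 Mb genome only holds a
few hundred eligible gaps.

## Annotation

* **Histone marks.** Per ChIP sample: log(signal+1), then centering and
  scaling to unit variance within the sample (population SD; a constant
  sample divides by 1 and yields zeros). The choice of z-scaling over
  min–max is isolated in `preprocess_histone` for substitution. Per region:
  extend ±250 bp, pool peaks of the mark across samples, keep peaks with
  ≥ 250 bp overlap, average their normalized signals; no qualifying peak
  gives 0. Marks are never mixed.
* **dnTSS.** Absolute distance from the region **center** to the nearest
  TSS; ties prefer the smaller TSS position, then the lexicographically
  smaller gene id. The nearest gene is the gene of the winning TSS.
* **Conservation.** Fixed window center ± 500 bp; the mean is unweighted
  over overlapping track intervals (bp-weighting is available as
  `conservation_bp_weighted`). No overlapping interval gives a missing
  value, never zero.
* **CpG methylation.** A 1 kb window concentric with the region, half-open
  (a site at the window start counts, at the end does not); the mean is
  taken over sites × atlas cell types; zero sites give count 0 and an
  undefined mean.

## NS-guided filtering

Regions and NS are jointly standardized on (H3K27ac, H3K4me3, H3K4me1,
log(1+dnTSS)), embedded with PCA (default 3 of 4 components; the explained
variance is reported in place of interactive PC selection) and clustered
with Louvain (igraph multilevel, resolution 1.0) on a union-symmetrized
kNN graph (k = 15, unit edge weights) under a seeded RNG. Coincident
embedding rows are collapsed to one graph node — identical points must
co-cluster; a kNN graph over exact duplicates is arbitrary. Clusters with
NS fraction > 20% are re-analyzed on their own; inside the recursion,
regions in sub-clusters with NS fraction > 50% are removed; recursion
continues until no suspicious cluster remains, bounded at depth 10 (the
ambiguous cluster is then retained with a warning). A suspicious cluster too
small to subdivide is dropped when its NS fraction exceeds the removal
fraction. PCA may alternatively be fitted on NS only and regions projected
(`pca_fit_on="ns"`); both readings of an ambiguous procedure are exposed.

## Classification

Per-cluster mean z-scores are discretized: `++` at z ≥ 1.0, `+` at
[0.25, 1.0), `+/−` at (−0.25, 0.25), `−` at ≤ −0.25, and `zero` when the
cluster carries no raw signal at all; the median dnTSS falls into
very_short (< 300 bp), short (< 2 kb), intermediate (< 8 kb), long (< 15 kb)
or very_long. A cluster is assigned the reference class minimizing
(Hamming distance on the three marks) + 3 × |ordinal difference of the
distance category|, ties resolved toward the class with the larger reference
count. The distance term is weighted because it is what separates
otherwise-similar promoter-like signatures: a dominant promoter cluster
whose z-scores saturate to (++, ++, −) at a very short dnTSS must map to
core promoters, not promoters, and plain Hamming would invert that. The
z-thresholds and weight are config-exposed and validated by synthetic-class
recovery.

## Gene association, expression and enrichment

A gene is associated with an HK core promoter when any of its TSSs lies
within 300 bp (inclusive) of the region center. Expression matrices are
filtered of all-zero genes and natural-log-normalized (log(TPM+1)); group
contrasts are unpaired two-sided rank-sum tests with the conventional
significance symbols (ns > 0.05 … **** ≤ 1e−4). Term over-representation is
the one-sided hypergeometric tail with Benjamini–Hochberg FDR (floored at
the raw p-value); this replaces an external web tool with a self-contained
test on a consistent FDR scale. Differential enrichment compares
r = −log10(FDR) (floored at 1e−6) between two gene groups; terms with a
ratio ≥ 20 in either direction are reported, sorted, truncated to the top
10. Base 10 is the package's choice of log base.

## Cancer activity and survival

A merged region is *active* in a held-out cell type when it overlaps any of
that cell's significant raw regions by ≥ 1 bp — the weakest consistent
reading of activity, applied uniformly to validation-healthy and cancer
cohorts. Percentages are reported at full precision; published tables
truncate to two decimals (20/21 → 95.23), so comparisons against them
truncate. The accounting identity pass + fail = total holds exactly; the
helper `accounting_from_reported` inverts a reported (count, percentage)
pair to the cohort total. Promoters active in < 35% of cancer cells
(strict) are ranked by ascending cancer activity, then by the distance of
their gene's TSS to its chromosome end (chrom_length − TSS, 1-based TSS).
The stricter 20% bound for suppressor candidates is a separate config knob
(`suppressor_frac`); the two thresholds are kept distinct.

Survival: per project, per gene z-transform (sample SD, ddof = 1; < 2
samples or zero variance are errors); the per-sample mean z over the gene
set is thresholded at its empirical 3rd quartile (inclusive, so ties only
inflate the HIGH group; numpy's default linear interpolation). Overall
survival is days_to_last_follow_up for living patients (censored) and
days_to_death otherwise. The Kaplan–Meier estimator and the two-sample
log-rank test (hypergeometric variance, native tie handling, χ²₁) are
implemented in the package and cross-checked against lifelines in the test
suite only.

## Synthetic data: what it emulates, and what it does not

Default scale (chosen for seconds-scale tests with enough structure for
clustering): 2 chromosomes × 10 Mb, 20 training + 7 validation healthy cell
types, 6 cancer cell types, 200 genes, 100 HK loci (60 at gene TSSs = the
promoter class, 40 elsewhere), 400 CTS loci, 100 decoys, 10 cancer-silenced
promoters, 3 ChIP samples per mark, 4 patient projects × 80 samples.

* Loci occupy jittered slots ≥ ~2.7 kb apart — positions are continuous, not
  lattice-quantized (a lattice leaks into dnTSS and lets decoys be separated
  from NS on an artifact).
* HK presence per healthy cell is Binomial(n, 0.97) floored at the HK
  definition: HK elements are active in essentially every healthy cell, and
  HK counts then plateau under cell-type subsampling. CTS loci are active in
  1–3 cells; decoys in 1–2 training cells with background-level histone
  signal only.
* Histone signals are log-normal with class-specific means (promoter-like:
  high H3K27ac + H3K4me3; enhancer-like: high H3K27ac + H3K4me1), the
  signatures being qualitative in the reference; background peaks come from
  a low-mean log-normal.
* Expression uses gene-intrinsic log-normal baselines shared across cohorts
  (HKG high without dropout; other genes lower with dropout); silenced genes
  are divided by ≥ 4 in cancer on top of their baseline.
* Patient expression of the suppressor genes follows a per-project offset
  plus a latent per-sample factor; survival times are exponential with a
  LOW/HIGH hazard ratio of 3 (config) and administrative censoring at 3,000
  days.

Not emulated: read-level data (no FASTQ/peak calling), Hi-C contacts,
genome sequence or GC/mappability structure, batch effects, assembly
liftover, covariate-driven censoring. Passing tests therefore demonstrate
the correctness and calibration of the pipeline's logic under its stated
assumptions, not robustness to the technical artifacts of real ChIP/RNA-seq
corpora.

## Numerical conventions and degenerate inputs

Seeds: every stochastic step takes an explicit seed; sweeps spawn
per-replicate `SeedSequence` substreams; Louvain runs under a temporarily
seeded Python RNG and restores the previous state. Degenerate inputs are
either defined (empty merge input → empty output; a gene missing from an
expression matrix → recorded missing; constant cohort → missing correlation)
or loud errors (zero-variance feature naming the feature; empty stratum;
fewer eligible gaps than requested windows, reporting the shortfall).

## Known limitations

Percentage agreement with published tables is limited to arithmetic
reproduction — the full-corpus counts (≈136k regions, ≈11k HK-CREs) are not
reachable from a 20 Mb synthetic genome, and no claim is made about them.
The Louvain resolution and PC count remain free parameters as in the
original interactive procedure; defaults are validated only by
synthetic-class recovery. The recursive NS filter can retain regions in
mixed noise clusters when the NS-to-lookalike ratio is low (~4:1); raising
`ns_count` sharpens it.
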