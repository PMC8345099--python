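# Methods

This note documents the models, parameter choices and numerical conventions
behind `enhancerkit`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Coordinate conventions

BED intervals are 0-based half-open `[start, end)`; VCF positions are
1-based. The two meet in exactly one predicate
(`io.variant_in_region`): a variant at POS `p` lies inside `[s, e)` iff
`s < p <= e`. Strand is ignored on regions (acetylation marks are
unstranded); TSS strand is kept so TSS distances can be signed (positive =
downstream of the gene's start). Peak centers are floor midpoints, so
even-width ties resolve leftward.

## Signal matrices and quantile normalization

`extract_signal_matrix` bins per-bp coverage in a fixed window (default
10 kb, 100 bp bins) centered on each peak; bins outside the covered
chromosome are zero. The invariant "sum of bin means x bin size = track
integral over the window" is asserted in tests.

Quantile normalization operates on the flattened region x bin vector per
sample — i.e. on each sample's whole signal distribution over the peak
windows, not per-bin. Each value is replaced by the across-sample mean of
the sorted values at its rank; ties receive the mean of the reference
values over their tied rank positions (the common average-ties convention).
Two consequences worth knowing:

- For tie-free data the sorted per-sample vectors are identical afterwards
  to machine precision.
- With ties the equality is only approximate, because differently sized tie
  runs across samples average different reference stretches. In practice
  ties arise in binned coverage when close-spaced peaks have overlapping
  extraction windows (the same track bin then appears twice within one
  sample). The discrepancy is a fraction of a percent and is documented in
  the test suite.

## Per-region statistics: footprint vs window

"Peak intensity" and fold change are computed over the bins covering the
peak footprint (the region itself), not the full extraction window. The
window exists to give clustering a spatial profile; averaging intensity over
it would dilute a 2 kb peak in a 10 kb window five-fold and make the
intensity threshold width-dependent, which is not what a peak-level
intensity filter means. Fold changes use a pseudocount of 1 normalized unit
on both condition means (configurable).

## Differential regions

Two routes are provided, mirroring common practice:

- **Threshold filter** (used for region calling): width > 2000 bp,
  peak intensity > 1000 (max of the two condition means by default, so a
  region fully silenced in one condition remains callable; mean-of-means is
  selectable), and pseudocounted fold change > 1.3 (up) or < 0.75 (down).
- **K-means clustering** (used for the global heatmap view): features are
  per-bin `log2((s2 + 1)/(s1 + 1))` profiles; K defaults to 3 (one common
  and two differential clusters), k-means++ with `n_init=10` and a fixed
  seed for determinism. Clusters are labeled by their mean
  footprint-restricted log-ratio against the same 1.3 / 0.75 thresholds.

Nearest-TSS annotation is by absolute midpoint-to-TSS distance with ties
broken lexicographically by gene name; the signed distance flips sign for
minus-strand genes. The TSS position is compared directly against the
region midpoint without a 1-bp frame shift — at histogram resolution the
off-by-one is immaterial, and the simpler rule is the one the tests pin.

Inverse-region matching defaults to "any overlap" semantics because both
comparisons are normally run on the same peak universe; a reciprocal
overlap-fraction threshold is available when they are not.

## Super-enhancers

Peaks whose gap is at most the stitch distance (default 12,500 bp, the
canonical ROSE value) merge transitively; an optional TSS-exclusion window
drops promoter-proximal peaks before stitching (off by default). The
ranking signal per constituent is mean track signal x width. After sorting
by total signal and scaling rank and signal to the unit square, the cutoff
is the signal at the first discrete slope exceeding 1 — a deterministic
approximation of ROSE's tangent rule that avoids spline fitting. All-equal
signals yield zero super-enhancers with a warning.

## SNP density

Counts are per region (a variant may count in several overlapping regions)
and normalized to variants per kb, because region widths differ
systematically between classes. The class comparison is a two-sided
Mann–Whitney U: exact null distribution when both groups have at most 8
tie-free observations, otherwise the normal approximation with tie
correction. Under a simulated null (equal Poisson rates, 50 regions per
class) the test rejects at ~5% as asserted in the suite.

## Gene-level scores

- **Cumulative signal**: sum of region signals over a gene's assigned
  regions (nearest-TSS assignment).
- **Resistance index**: expression is z-scored per gene across the panel;
  the index is mean z over up-signature genes minus mean z over
  down-signature genes; groups are defined by the GI50 threshold (20 µM)
  and compared by Mann–Whitney. The exact published formula behind such
  signature scores is not fixed in the literature; this mean-z difference
  is a documented reconstruction with the intended invariances (swapping
  signatures negates it; constant expression nullifies it).
- **Combined score**: `log2FC x (-log10 FDR) x log10(1 + cumulative
  signal)`. The three ingredients are standard; the product form is a
  reconstruction chosen so that any null component annihilates the score
  and each factor contributes monotonically. It is a plain function and can
  be swapped out.
- **Enrichment**: upper-tail hypergeometric per gene set against a universe
  of assayable genes, BH-adjusted. This deliberately simplifies
  locus-length-aware enrichment models (ChIP-Enrich-style regression):
  genes with longer regulatory domains collect more peaks, so the
  hypergeometric p-values carry a length bias on real data. The tests
  validate the combinatorics, not the bias correction.

## Screen analysis

Counts get a pseudocount of 1 and are normalized to reads per million
within each (condition, replicate) library; depletion is the day14/pool RPM
ratio per guide (a single sequenced pool is broadcast across replicates;
per-replicate pools are supported). Gene-level depletion is the geometric
mean over the pooled guide x replicate ratios — order-invariant and exactly
the log-domain mean. Differential depletion `D = depletion_drug /
depletion_vehicle` ranks genes ascending. An optional permutation test
(shuffling the guide-to-gene assignment, matched on guide count, default
1000 permutations) supplies empirical p-values; hit calling combines a D
threshold with a minimum of 2 supporting guides, since the original
significance criterion for "depleted" screen hits is typically not stated.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis assumes,
with defaults matching the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_common / n_up / n_down | 200 / 50 / 50 | planted region classes |
| fc_up / fc_down | 2.0 / 0.5 | planted acetylation fold changes |
| base_intensity | 2000 a.u. | mean bin signal, sensitive condition |
| noise_cv | 0.15 | lognormal bin-noise coefficient of variation |
| peak widths | 1–6 kb uniform | straddles the 2 kb filter on purpose |
| region spacing | 25 kb (10% at 3 kb) | exercises stitching both ways |
| n_genes / n_shrnas | 1139 / 6485 | screen library size |
| n_depleted / effect | 4 / 0.2 | planted drug-specific dropouts |
| NB dispersion | 0.1 | count overdispersion (var = mu + 0.1 mu^2) |
| snp_rate_bg / snp_rate_up | 0.5 / 1.5 per kb | Poisson variant rates |
| panel | 18 lines, 11 resistant | GI50 threshold 20 µM |
| expression_shift | 1.0 log2 units | planted signature effect |

Noise shapes are the standard choices where the data-generating process is
not otherwise specified: multiplicative lognormal (mean exactly 1) for
coverage, negative binomial for sequencing counts, Poisson for variant
occurrence. Noiseless limits reproduce planted effects exactly and are
asserted. All generators draw from named substreams of one root seed, so
every emitted file is byte-deterministic per seed.

What the simulations do **not** model: read-level artifacts (mappability,
GC bias, duplicate reads), realistic genome sequence or copy-number
structure, correlated replicate structure, input/IgG background, guide
off-target effects, and biological correlation between the acetylation,
variant and expression layers beyond the planted links. Passing the
planted-truth tests therefore demonstrates that the algorithms recover the
effects they target at realistic effect sizes and noise levels — not that
those effect sizes are what any particular real dataset shows.

One deliberate property: planted peak widths extend below the 2 kb filter,
so a fraction of planted differential regions is *not callable by design*.
Recovery metrics (sensitivity, precision, cluster agreement) are therefore
evaluated on the size-eligible subset; sub-2 kb peaks are below the
method's stated resolution.

## Problem sizes used in the checks

The automated checks run the full study-scale configuration where it is
cheap (300 regions, 6485 guides, 18-line panel) and use repeated
simulation where a rate is being estimated: 100 seeds for detection/recovery
rates, 500 simulations for type-I-error calibration, 15–40 seeds in the
faster unit-level variants of the same checks.

## Known limitations

- The quantile-normalization tie rule makes marginal equality approximate
  in the presence of ties (see above).
- The super-enhancer cutoff is the discrete-slope tangent rule; on curves
  with a very shallow elbow it can differ from spline-based
  implementations by a few ranks.
- Hypergeometric enrichment carries locus-length bias on real data.
- The resistance index and the combined gene score are reconstructions of
  informally specified scores; their defaults are documented and pluggable.
- The Mann–Whitney exact path is limited to small tie-free groups;
  elsewhere the tie-corrected normal approximation is used.
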