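# enhancerkit

Analysis toolkit for studying **non-genetic (epigenetic) platinum resistance**
in cancer cell lines through the lens of enhancer remodeling. When an
ovarian-cancer line acquires cisplatin resistance, the genome-wide landscape
of the active-enhancer mark **H3K27ac** shifts: some regulatory regions gain
acetylation, others lose it, and those changes propagate to gene expression
and drug response. `enhancerkit` implements the computational side of such a
study as a tested, reusable pipeline:

- **Signal matrices** — per-peak binned ChIP-seq coverage in a 10 kb window
  around each peak center, with quantile normalization across samples.
- **Differential enhancer calling** — K-means clustering of per-bin
  log2-ratio profiles, and an explicit filter keeping peaks wider than 2 kb
  with peak intensity > 1000 and fold change > 1.3 (up) or < 0.75 (down).
- **Super-enhancers** — ROSE-style stitching of peaks within 12.5 kb and a
  tangent-line cutoff on the scaled signal-rank curve.
- **SNP density** — variants per kb inside region classes, compared between
  conditions with a Mann–Whitney U test.
- **Gene-level scores** — cumulative H3K27ac per gene, a signature-based
  resistance index over an 18-line expression panel split at GI50 = 20 µM
  (11 resistant / 7 sensitive), a combined ranking score
  `log2FC x (-log10 FDR) x log10(1 + cumulative signal)`, and hypergeometric
  gene-set enrichment.
- **Pooled shRNA dropout screen** — reads-per-million normalization,
  day14/pool depletion ratios, geometric-mean gene aggregation over
  guides x replicates (1139 genes, 6485 shRNAs, n = 3), and drug/vehicle
  differential-depletion ranking.
- **Inverse regions** — loci whose acetylation change under knockdown of a
  chromatin remodeler opposes their change in the resistant line.
- **Synthetic data** — generators for every input with planted ground truth
  (region classes, depleted genes, expression signatures, SNP enrichment),
  fully deterministic per seed.
- **qPCR helpers** — spike-in-normalized ChIP-qPCR and reference-gene
  relative expression (including a 2^-ddCt wrapper).

## Worked example

Everything below runs on synthetic data with planted truth; with a fixed
seed the output is bit-reproducible.

```python
import enhancerkit as ek
from enhancerkit import differential as dm, screen as sm, snp_density as sd

cfg = ek.SimulationConfig(seed=1)          # 50 up @FC 2.0, 50 down @FC 0.5, 200 common
chip = ek.simulate_chip(cfg)
matrix = ek.quantile_normalize(ek.extract_signal_matrix(chip.tracks, chip.peaks))
stats = dm.compute_region_stats(matrix, chip.condition_samples["sensitive"],
                                chip.condition_samples["resistant"])
up, down = dm.filter_differential_peaks(stats)
print(f"differential regions: {len(up)} up, {len(down)} down (of {len(chip.peaks)} peaks)")

screen = ek.simulate_screen(cfg)           # 1139 genes / 6485 shRNAs, 4 planted dropouts
rpm = sm.normalize_counts(screen.table)
dep = sm.differential_depletion(sm.gene_depletion(sm.shrna_depletion(rpm)))
print("top-4 depleted genes:", ", ".join(dep.top(4)))
```

prints

```
differential regions: 39 up, 36 down (of 300 peaks)
top-4 depleted genes: G0730, G0509, G1067, G0490
```

The 39 + 36 called regions are the planted up/down peaks that clear the 2 kb
size gate (sub-2 kb peaks are excluded by the filter, by design), and the
four top-ranked screen genes are exactly the four planted dropouts
(differential depletion ≈ 0.15–0.21, close to the planted effect of 0.2).
The same dataset yields a SNP-density enrichment in up-regions (median 1.52
vs 0.53 variants/kb, p = 4.4e-11) and a resistance index separating the
GI50-defined groups (1.12 vs −1.76, p = 6.3e-05).

The whole pipeline can also be driven from a YAML config:

```bash
enhancerkit run --config config.yaml      # stages: simulate, signal, differential,
                                          # superenhancer, snp, gene_scores, screen, inverse
```

Each run writes a `manifest.json` with a SHA-256 checksum per output;
identical config + seed reproduce identical checksums. Individual stages are
exposed as `enhancerkit simulate | signal | diff | se | snp | genes | screen`.

## Layout

```
src/enhancerkit/
  io.py             BED / bedGraph / VCF / GMT / TSV readers and writers
  simulate.py       synthetic-data generators with planted ground truth
  signal.py         signal matrices, quantile normalization, qPCR helpers
  differential.py   clustering, differential filter, TSS annotation, inverse regions
  superenhancer.py  stitching and rank-curve cutoff
  snp_density.py    per-region variant counts and density comparison
  gene_scores.py    resistance index, combined score, enrichment
  screen.py         shRNA dropout-screen depletion analysis
  pipeline.py       orchestration, manifest, determinism
  cli.py            command-line interface
docs/methods.md     model assumptions, parameter choices, limitations
```
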