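"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline has a generator here that emits its
inputs with a known planted structure: two-condition binned ChIP signal with
up/down/common region classes, variant positions enriched inside up-regions
of the resistant condition, shRNA screen counts with condition-specific
dropouts, and an expression panel whose resistance signature tracks GI50
groups. All generators are deterministic per seed (named substreams off one
root seed) and their outputs re-parse through :mod:`enhancerkit.io`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CoverageTrack,
    GenomicRegion,
    RegionSet,
    ScreenCountTable,
    TSSAnnotation,
    VariantSet,
    write_bed,
    write_bedgraph,
    write_tss_table,
    write_vcf,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ChipSimulation",
    "ScreenSimulation",
    "ExpressionSimulation",
    "simulate_chip",
    "simulate_chip_knockdown",
    "simulate_screen",
    "simulate_variants",
    "simulate_expression",
    "write_variant_sets",
]

CHROM = "chrS"

# substream tags so each generator draws from an independent stream
_STREAM_CHIP, _STREAM_SCREEN, _STREAM_VARIANTS, _STREAM_EXPR = 1, 2, 3, 4


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults mirror the study conditions."""

    seed: int = 0
    # ChIP signal
    n_common: int = 200
    n_up: int = 50
    n_down: int = 50
    fc_up: float = 2.0
    fc_down: float = 0.5
    base_intensity: float = 2000.0
    noise_cv: float = 0.15
    window_bp: int = 10_000
    bin_bp: int = 100
    n_chip_replicates: int = 1
    min_peak_bp: int = 1000
    max_peak_bp: int = 6000
    region_spacing_bp: int = 25_000  # 2x the default stitch distance
    close_fraction: float = 0.1  # fraction of regions placed within stitch range
    close_gap_bp: int = 3000
    # screen
    n_genes: int = 1139
    n_shrnas: int = 6485
    n_depleted: int = 4
    depletion_effect: float = 0.2
    n_replicates: int = 3
    screen_mean_count: float = 500.0
    nb_dispersion: float = 0.1
    drift_cv: float = 0.1
    pool_per_replicate: bool = False
    # variants
    snp_rate_bg: float = 0.5  # per kb
    snp_rate_up: float = 1.5  # per kb, inside up regions of the resistant condition
    # expression panel
    n_cell_lines: int = 18
    n_resistant: int = 11
    gi50_threshold_uM: float = 20.0
    n_signature: int = 50
    n_background_genes: int = 400
    expression_shift: float = 1.0  # log2 units added to signature genes in resistant lines
    expression_noise_sd: float = 0.5
    # TSS placement relative to planted regions (bp offsets, cycled)
    tss_offsets: tuple[int, ...] = (-10_000, -2000, 0, 2000, 10_000)

    def __post_init__(self) -> None:
        counts = (
            self.n_common, self.n_up, self.n_down, self.n_genes, self.n_shrnas,
            self.n_depleted, self.n_replicates, self.n_cell_lines, self.n_resistant,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if not (self.fc_up > 1 > self.fc_down > 0):
            raise ValueError("need fc_up > 1 > fc_down > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.window_bp < self.bin_bp or self.window_bp % self.bin_bp:
            raise ValueError("window_bp must be a positive multiple of bin_bp")
        if self.n_depleted > self.n_genes:
            raise ValueError("n_depleted cannot exceed n_genes")
        if self.n_resistant > self.n_cell_lines:
            raise ValueError("n_resistant cannot exceed n_cell_lines")


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    region_labels: list[str] = field(default_factory=list)  # per region: up/down/common
    depleted_genes: list[str] = field(default_factory=list)
    signature_up: list[str] = field(default_factory=list)
    signature_down: list[str] = field(default_factory=list)
    cell_line_status: dict[str, str] = field(default_factory=dict)  # resistant/sensitive

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 (cv=0 -> ones)."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# ChIP signal
# ---------------------------------------------------------------------------

@dataclass
class ChipSimulation:
    peaks: RegionSet
    tracks: dict[str, CoverageTrack]
    track_records: dict[str, list[tuple[str, int, int, float]]]
    tss: TSSAnnotation
    truth: GroundTruth
    condition_samples: dict[str, list[str]]  # condition -> sample names

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        peaks_path = outdir / "peaks.bed"
        write_bed(self.peaks, peaks_path)
        paths["peaks"] = peaks_path
        for sample, records in self.track_records.items():
            p = outdir / f"{sample}.bedGraph"
            write_bedgraph(records, p)
            paths[f"track:{sample}"] = p
        tss_path = outdir / "tss.tsv"
        write_tss_table(self.tss, tss_path)
        paths["tss"] = tss_path
        truth_path = outdir / "truth.json"
        self.truth.to_json(truth_path)
        paths["truth"] = truth_path
        return paths


def simulate_chip(config: SimulationConfig) -> ChipSimulation:
    """Two-condition binned ChIP signal with planted up/down/common regions.

    Peaks sit on one synthetic chromosome, widths drawn between
    ``min_peak_bp`` and ``max_peak_bp`` (so a fraction falls below the 2 kb
    differential filter), mostly spaced beyond twice the super-enhancer
    stitch distance with a configurable close-spaced fraction. The sensitive
    condition has mean bin signal ``base_intensity``; the resistant
    condition multiplies that by 1, ``fc_up`` or ``fc_down`` according to
    the planted class, with independent lognormal bin noise in each sample.
    """
    rng = np.random.default_rng([config.seed, _STREAM_CHIP])
    n_total = config.n_common + config.n_up + config.n_down
    labels = (
        ["common"] * config.n_common
        + ["up"] * config.n_up
        + ["down"] * config.n_down
    )
    rng.shuffle(labels)

    # widths on the bin grid, inclusive of both bounds
    n_width_steps = (config.max_peak_bp - config.min_peak_bp) // config.bin_bp + 1
    widths = (
        config.min_peak_bp
        + rng.integers(0, n_width_steps, size=n_total) * config.bin_bp
    )
    close = rng.random(n_total) < config.close_fraction
    regions = []
    cursor = config.window_bp  # leave room for the extraction window
    for i in range(n_total):
        start = cursor
        end = start + int(widths[i])
        regions.append(
            GenomicRegion(CHROM, start, end, name=f"peak{i:05d}")
        )
        gap = config.close_gap_bp if close[i] else config.region_spacing_bp
        cursor = end + gap
    peaks = RegionSet(regions, label="peaks")

    fc_of = {"common": 1.0, "up": config.fc_up, "down": config.fc_down}
    condition_samples = {"sensitive": [], "resistant": []}
    track_records: dict[str, list[tuple[str, int, int, float]]] = {}
    tracks: dict[str, CoverageTrack] = {}
    for condition in ("sensitive", "resistant"):
        for rep in range(1, config.n_chip_replicates + 1):
            sample = f"{condition}_rep{rep}"
            condition_samples[condition].append(sample)
            records = []
            for region, label in zip(regions, labels):
                n_bins = region.width // config.bin_bp
                mean = config.base_intensity
                if condition == "resistant":
                    mean = mean * fc_of[label]
                values = mean * _lognormal_noise(rng, config.noise_cv, n_bins)
                for b in range(n_bins):
                    s = region.start + b * config.bin_bp
                    records.append((CHROM, s, s + config.bin_bp, float(values[b])))
            track_records[sample] = records
            tracks[sample] = CoverageTrack.from_records(records)

    offsets = config.tss_offsets
    entries = []
    counters = {"up": 0, "down": 0, "common": 0}
    for i, (region, label) in enumerate(zip(regions, labels)):
        offset = offsets[i % len(offsets)]
        pos = max(1, region.midpoint + offset)
        strand = "+" if i % 2 == 0 else "-"
        # gene names align with the expression panel's signature genes so the
        # acetylation and expression ground truths describe the same genes
        k = counters[label]
        counters[label] += 1
        if label == "up":
            gene = f"SIGUP{k:03d}" if k < config.n_signature else f"XUP{k:03d}"
        elif label == "down":
            gene = f"SIGDN{k:03d}" if k < config.n_signature else f"XDN{k:03d}"
        else:
            gene = f"BG{k:04d}"
        entries.append((gene, CHROM, pos, strand))
    tss = TSSAnnotation(entries)

    truth = GroundTruth(region_labels=list(labels))
    return ChipSimulation(peaks, tracks, track_records, tss, truth, condition_samples)


_STREAM_KNOCKDOWN = 5


def simulate_chip_knockdown(
    config: SimulationConfig,
    chip: ChipSimulation,
    invert_fraction: float = 0.5,
) -> ChipSimulation:
    """A second two-condition contrast on the same peaks (knockdown vs control).

    Emulates the chromatin response to suppressing a remodeling factor: a
    planted fraction of the resistance-differential regions responds in the
    opposite direction (up-in-resistant regions lose acetylation on
    knockdown and vice versa), the rest stay flat. Truth labels record the
    knockdown-contrast direction per region.
    """
    rng = np.random.default_rng([config.seed, _STREAM_KNOCKDOWN])
    kd_labels = []
    for label in chip.truth.region_labels:
        if label != "common" and rng.random() < invert_fraction:
            # inverse response: direction opposite to the resistance contrast
            kd_labels.append("down" if label == "up" else "up")
        else:
            kd_labels.append("common")
    condition_samples = {"control": [], "knockdown": []}
    track_records: dict[str, list[tuple[str, int, int, float]]] = {}
    tracks: dict[str, CoverageTrack] = {}
    for condition in ("control", "knockdown"):
        for rep in range(1, config.n_chip_replicates + 1):
            sample = f"{condition}_rep{rep}"
            condition_samples[condition].append(sample)
            records = []
            for region, label in zip(chip.peaks, kd_labels):
                n_bins = region.width // config.bin_bp
                mean = config.base_intensity
                if condition == "knockdown" and label != "common":
                    mean = mean * (config.fc_up if label == "up" else config.fc_down)
                values = mean * _lognormal_noise(rng, config.noise_cv, n_bins)
                for b in range(n_bins):
                    s = region.start + b * config.bin_bp
                    records.append((CHROM, s, s + config.bin_bp, float(values[b])))
            track_records[sample] = records
            tracks[sample] = CoverageTrack.from_records(records)
    truth = GroundTruth(region_labels=kd_labels)
    return ChipSimulation(
        chip.peaks, tracks, track_records, chip.tss, truth, condition_samples
    )


# ---------------------------------------------------------------------------
# shRNA screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimulation:
    table: ScreenCountTable
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts_path = outdir / "screen_counts.tsv"
        self.table.df.to_csv(counts_path, sep="\t", index=False)
        truth_path = outdir / "screen_truth.json"
        self.truth.to_json(truth_path)
        return {"counts": counts_path, "truth": truth_path}


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson if 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_screen(config: SimulationConfig) -> ScreenSimulation:
    """Pooled dropout screen with condition-specific planted depletions.

    The library distributes ``n_shrnas`` guides as evenly as possible over
    ``n_genes`` genes (the default 6485 over 1139 gives 5-6 per gene). Pool
    counts are negative binomial around a common mean; day-14 counts apply a
    per-guide lognormal passage drift shared between arms, and the drug arm
    additionally multiplies every guide of a planted depleted gene by
    ``depletion_effect``.
    """
    rng = np.random.default_rng([config.seed, _STREAM_SCREEN])
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    base, extra = divmod(config.n_shrnas, config.n_genes)
    guides_per_gene = np.full(config.n_genes, base, dtype=int)
    guides_per_gene[:extra] += 1
    shrna_gene = np.repeat(np.arange(config.n_genes), guides_per_gene)
    shrna_names = [
        f"sh_{genes[g]}_{k}" for g, k in zip(
            shrna_gene, np.concatenate([np.arange(c) for c in guides_per_gene])
        )
    ]
    n = len(shrna_names)

    depleted_idx = rng.choice(config.n_genes, size=config.n_depleted, replace=False)
    depleted = sorted(genes[i] for i in depleted_idx)
    effect = np.where(
        np.isin(shrna_gene, depleted_idx), config.depletion_effect, 1.0
    )
    drift = _lognormal_noise(rng, config.drift_cv, n)
    mu = config.screen_mean_count

    rows = []
    pool_reps = range(1, config.n_replicates + 1) if config.pool_per_replicate else (1,)
    for rep in pool_reps:
        counts = _nb_counts(rng, np.full(n, mu), config.nb_dispersion)
        rows.append(pd.DataFrame({
            "shRNA": shrna_names,
            "gene": [genes[g] for g in shrna_gene],
            "condition": "pool",
            "replicate": rep,
            "count": counts,
        }))
    for condition, mult in (("vehicle_d14", np.ones(n)), ("cpt_d14", effect)):
        for rep in range(1, config.n_replicates + 1):
            counts = _nb_counts(rng, mu * drift * mult, config.nb_dispersion)
            rows.append(pd.DataFrame({
                "shRNA": shrna_names,
                "gene": [genes[g] for g in shrna_gene],
                "condition": condition,
                "replicate": rep,
                "count": counts,
            }))
    table = ScreenCountTable(pd.concat(rows, ignore_index=True))
    return ScreenSimulation(table, GroundTruth(depleted_genes=depleted))


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def simulate_variants(
    config: SimulationConfig, peaks: RegionSet, truth: GroundTruth
) -> dict[str, VariantSet]:
    """Poisson variants inside the planted peak regions, per condition.

    Both conditions draw at ``snp_rate_bg`` per kb in every region; the
    resistant condition instead uses ``snp_rate_up`` inside up-class regions,
    planting the density enrichment the comparison is meant to detect.
    """
    if len(peaks) != len(truth.region_labels):
        raise ValueError("peaks and truth labels are not parallel")
    rng = np.random.default_rng([config.seed, _STREAM_VARIANTS])
    out: dict[str, VariantSet] = {}
    for condition in ("sensitive", "resistant"):
        positions: list[tuple[str, int]] = []
        for region, label in zip(peaks, truth.region_labels):
            rate = config.snp_rate_bg
            if condition == "resistant" and label == "up":
                rate = config.snp_rate_up
            lam = rate * region.width / 1000.0
            k = int(rng.poisson(lam))
            if k:
                # 1-based positions inside [start, end): start+1 .. end
                pos = rng.integers(region.start + 1, region.end + 1, size=k)
                positions.extend((region.chrom, int(p)) for p in pos)
        out[condition] = VariantSet(sorted(positions), sample=condition)
    return out


def write_variant_sets(
    variant_sets: dict[str, VariantSet], outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for condition, vs in variant_sets.items():
        p = outdir / f"variants_{condition}.vcf"
        write_vcf(vs, p)
        paths[condition] = p
    return paths


# ---------------------------------------------------------------------------
# Expression panel
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimulation:
    expression: pd.DataFrame  # genes x cell lines, log2 units
    gi50: dict[str, float]
    truth: GroundTruth

    def de_table(self) -> pd.DataFrame:
        """Per-gene log2FC/FDR summary of the panel (resistant vs sensitive).

        Plumbing for stages that take a differential-expression table as
        input: group-mean log2 fold change, Welch t-test p, BH FDR.
        """
        from scipy import stats as _st

        from .gene_scores import benjamini_hochberg

        res = [s for s, v in self.truth.cell_line_status.items() if v == "resistant"]
        sen = [s for s, v in self.truth.cell_line_status.items() if v == "sensitive"]
        a = self.expression[res].to_numpy()
        b = self.expression[sen].to_numpy()
        log2fc = a.mean(axis=1) - b.mean(axis=1)
        p = _st.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        fdr = np.clip(benjamini_hochberg(p), np.finfo(float).tiny, 1.0)
        return pd.DataFrame(
            {"gene": self.expression.index, "log2fc": log2fc, "fdr": fdr}
        ).reset_index(drop=True)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        expr_path = outdir / "expression.tsv"
        self.expression.to_csv(expr_path, sep="\t", index_label="gene")
        gi50_path = outdir / "gi50.tsv"
        pd.DataFrame(
            {"cell_line": list(self.gi50), "gi50_uM": list(self.gi50.values())}
        ).to_csv(gi50_path, sep="\t", index=False)
        truth_path = outdir / "expression_truth.json"
        self.truth.to_json(truth_path)
        return {"expression": expr_path, "gi50": gi50_path, "truth": truth_path}


def simulate_expression(config: SimulationConfig) -> ExpressionSimulation:
    """Expression panel with a planted resistance signature tied to GI50.

    Resistant lines shift up-signature genes by ``+expression_shift`` log2
    units and down-signature genes by the negative; GI50 values are drawn on
    either side of the threshold so thresholding reproduces the planted
    status exactly (resistant above 20 uM by default, 11 of 18 lines).
    """
    rng = np.random.default_rng([config.seed, _STREAM_EXPR])
    lines = [f"CL{i:02d}" for i in range(config.n_cell_lines)]
    status = ["resistant"] * config.n_resistant + ["sensitive"] * (
        config.n_cell_lines - config.n_resistant
    )
    rng.shuffle(status)
    up = [f"SIGUP{i:03d}" for i in range(config.n_signature)]
    down = [f"SIGDN{i:03d}" for i in range(config.n_signature)]
    background = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    genes = up + down + background
    baseline = rng.normal(8.0, 1.0, size=len(genes))
    x = baseline[:, None] + rng.normal(
        0.0, config.expression_noise_sd, size=(len(genes), len(lines))
    )
    resistant_mask = np.array([s == "resistant" for s in status])
    x[: len(up), resistant_mask] += config.expression_shift
    x[len(up) : len(up) + len(down), resistant_mask] -= config.expression_shift
    expression = pd.DataFrame(x, index=genes, columns=lines)

    t = config.gi50_threshold_uM
    gi50 = {}
    for line, s in zip(lines, status):
        if s == "resistant":
            gi50[line] = float(rng.uniform(t * 1.25, t * 4.0))
        else:
            gi50[line] = float(rng.uniform(t * 0.05, t * 0.75))
    truth = GroundTruth(
        signature_up=up,
        signature_down=down,
        cell_line_status=dict(zip(lines, status)),
    )
    return ExpressionSimulation(expression, gi50, truth)
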