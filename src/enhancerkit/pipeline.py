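"""Pipeline orchestration: run all stages from one declarative config.

Stages execute in dependency order (simulate -> signal -> differential ->
super-enhancer / SNP density / gene scores / inverse regions; the screen is
independent). Every run writes a manifest recording parameters, the seed
and a checksum per output file, so identical config + seed reproduce
byte-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diff_mod
from . import gene_scores as gs_mod
from . import screen as screen_mod
from . import signal as signal_mod
from . import snp_density as snp_mod
from . import superenhancer as se_mod
from .io import GeneSetCollection, write_bed
from .simulate import (
    SimulationConfig,
    simulate_chip,
    simulate_chip_knockdown,
    simulate_expression,
    simulate_screen,
    simulate_variants,
    write_variant_sets,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

STAGES = (
    "simulate",
    "signal",
    "differential",
    "superenhancer",
    "snp",
    "gene_scores",
    "screen",
    "inverse",
)

# stage -> stages it needs
DEPENDENCIES = {
    "signal": ("simulate",),
    "differential": ("signal",),
    "superenhancer": ("differential",),
    "snp": ("differential",),
    "gene_scores": ("differential",),
    "inverse": ("differential",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Declarative run description: stage toggles, thresholds, seed, outdir."""

    outdir: str = "pipeline_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # differential-filter thresholds
    min_width_bp: int = 2000
    min_intensity: float = 1000.0
    fc_up: float = 1.3
    fc_down: float = 0.75
    # signal extraction
    window_bp: int = 10_000
    bin_bp: int = 100
    k_clusters: int = 3
    # super-enhancers
    stitch_bp: int = 12_500
    # resistance index
    gi50_threshold_uM: float = 20.0
    # screen
    screen_permutations: int = 0
    # simulation knobs are forwarded to SimulationConfig
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise PipelineError("need fc_down < 1 < fc_up")
        for name in ("min_width_bp", "min_intensity", "window_bp", "bin_bp",
                     "stitch_bp", "gi50_threshold_uM"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")
        enabled = set(self.stages)
        for stage in sorted(enabled):
            for dep in DEPENDENCIES.get(stage, ()):
                if dep not in enabled:
                    raise PipelineError(
                        f"stage {stage!r} requires stage {dep!r} to be enabled"
                    )

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            seed=self.seed,
            window_bp=self.window_bp,
            bin_bp=self.bin_bp,
            gi50_threshold_uM=self.gi50_threshold_uM,
            **self.simulation,
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute the enabled stages and return the run manifest.

    ``dry_run`` validates the configuration (including stage dependencies,
    already checked at construction) without touching any inputs or outputs.
    """
    if dry_run:
        return {"dry_run": True, "stages": list(config.stages), "seed": config.seed}

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"
        },
        "stages": {},
    }

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(Path(p).relative_to(outdir)), "sha256": _sha256(Path(p))}
            for name, p in paths.items()
        }

    sim_config = config.simulation_config()
    chip = expr = screen_sim = None
    try:
        if "simulate" in enabled:
            chip = simulate_chip(sim_config)
            paths = chip.write(outdir / "simulate")
            expr = simulate_expression(sim_config)
            paths.update(expr.write(outdir / "simulate"))
            record("simulate", paths)

        if "signal" in enabled:
            matrix = signal_mod.extract_signal_matrix(
                chip.tracks, chip.peaks, config.window_bp, config.bin_bp
            )
            qnormed = signal_mod.quantile_normalize(matrix)
            sig_dir = outdir / "signal"
            sig_dir.mkdir(exist_ok=True)
            qnormed.write_tsv(sig_dir / "signal_matrix.tsv")
            record("signal", {"matrix": sig_dir / "signal_matrix.tsv"})

        if "differential" in enabled:
            cond1 = chip.condition_samples["sensitive"]
            cond2 = chip.condition_samples["resistant"]
            stats_list = diff_mod.compute_region_stats(qnormed, cond1, cond2)
            up, down = diff_mod.filter_differential_peaks(
                stats_list,
                min_width_bp=config.min_width_bp,
                min_intensity=config.min_intensity,
                fc_up=config.fc_up,
                fc_down=config.fc_down,
            )
            clusters = diff_mod.cluster_regions(
                qnormed, cond1, cond2, k=config.k_clusters, seed=config.seed,
                fc_up=config.fc_up, fc_down=config.fc_down,
            )
            hits = diff_mod.annotate_nearest_tss(chip.peaks, chip.tss)
            diff_dir = outdir / "differential"
            diff_dir.mkdir(exist_ok=True)
            write_bed(up, diff_dir / "up.bed")
            write_bed(down, diff_dir / "down.bed")
            pd.DataFrame(
                {
                    "region": [r.name for r in chip.peaks],
                    "mean_sensitive": [s.mean1 for s in stats_list],
                    "mean_resistant": [s.mean2 for s in stats_list],
                    "fold_change": [s.fold_change for s in stats_list],
                    "width": [s.width for s in stats_list],
                    "cluster_label": clusters.region_labels,
                    "nearest_gene": [h.gene for h in hits],
                    "tss_distance": [h.distance for h in hits],
                }
            ).to_csv(diff_dir / "region_stats.tsv", sep="\t", index=False)
            record(
                "differential",
                {
                    "up": diff_dir / "up.bed",
                    "down": diff_dir / "down.bed",
                    "stats": diff_dir / "region_stats.tsv",
                },
            )

        if "superenhancer" in enabled:
            track = chip.tracks[chip.condition_samples["resistant"][0]]
            signals = se_mod.region_signals(track, chip.peaks)
            stitched = se_mod.stitch_peaks(
                chip.peaks, signals=signals, stitch_bp=config.stitch_bp
            )
            call = se_mod.call_superenhancers(stitched)
            se_dir = outdir / "superenhancer"
            se_dir.mkdir(exist_ok=True)
            write_bed([e.region for e in call.superenhancers()], se_dir / "super.bed")
            write_bed([e.region for e in call.typical()], se_dir / "typical.bed")
            pd.DataFrame(
                {
                    "chrom": [e.region.chrom for e in call.enhancers],
                    "start": [e.region.start for e in call.enhancers],
                    "end": [e.region.end for e in call.enhancers],
                    "n_constituents": [e.n_constituents for e in call.enhancers],
                    "total_signal": [e.total_signal for e in call.enhancers],
                    "rank": [e.rank for e in call.enhancers],
                    "scaled_rank": call.scaled_rank,
                    "scaled_signal": call.scaled_signal,
                    "is_super": call.is_super,
                }
            ).to_csv(se_dir / "ranking.tsv", sep="\t", index=False)
            record(
                "superenhancer",
                {
                    "super": se_dir / "super.bed",
                    "typical": se_dir / "typical.bed",
                    "ranking": se_dir / "ranking.tsv",
                },
            )

        if "snp" in enabled:
            variant_sets = simulate_variants(sim_config, chip.peaks, chip.truth)
            snp_dir = outdir / "snp"
            paths = write_variant_sets(variant_sets, snp_dir)
            rows = []
            per_class: dict[tuple[str, str], list] = {}
            for condition, vs in variant_sets.items():
                counts = snp_mod.count_variants_per_region(vs, chip.peaks, condition)
                for rvc, label in zip(counts, chip.truth.region_labels):
                    rows.append(
                        {
                            "region": rvc.region.name,
                            "condition": condition,
                            "class": label,
                            "count": rvc.count,
                            "density_per_kb": rvc.density,
                        }
                    )
                    per_class.setdefault((condition, label), []).append(rvc)
            cmp_res = snp_mod.compare_density(
                per_class.get(("resistant", "up"), []),
                per_class.get(("sensitive", "up"), []),
            )
            pd.DataFrame(rows).to_csv(snp_dir / "region_counts.tsv", sep="\t", index=False)
            cmp_res.to_frame().to_csv(snp_dir / "comparison.tsv", sep="\t", index=False)
            paths.update(
                {
                    "counts": snp_dir / "region_counts.tsv",
                    "comparison": snp_dir / "comparison.tsv",
                }
            )
            record("snp", paths)

        if "gene_scores" in enabled:
            gs_dir = outdir / "gene_scores"
            gs_dir.mkdir(exist_ok=True)
            # cumulative normalized signal of up regions per nearest gene
            up_names = {r.name for r in up}
            mean2 = {s.region.name: s.mean2 for s in stats_list}
            assignments = [
                (h.gene, mean2[h.region.name] * h.region.width)
                for h in hits
                if h.assigned and h.region.name in up_names
            ]
            cumulative = gs_mod.cumulative_signal_per_gene(assignments)
            de = expr.de_table()
            de["cumulative_signal"] = de["gene"].map(cumulative).fillna(0.0)
            scored = gs_mod.combined_rank_score(
                de[de["gene"].isin({g for g, _ in assignments})]
                if assignments
                else de
            )
            scored.to_csv(gs_dir / "gene_scores.tsv", sep="\t", index=False)
            ri = gs_mod.resistance_index(
                expr.expression,
                expr.truth.signature_up,
                expr.truth.signature_down,
                expr.gi50,
                threshold_uM=config.gi50_threshold_uM,
            )
            ri_df = pd.DataFrame(
                {
                    "cell_line": ri.index.index,
                    "resistance_index": ri.index.to_numpy(),
                    "group": [
                        "resistant" if s in ri.resistant else "sensitive"
                        for s in ri.index.index
                    ],
                }
            )
            ri_df.attrs["p_value"] = ri.p_value
            ri_df.to_csv(gs_dir / "resistance_index.tsv", sep="\t", index=False)
            collection = _planted_gene_sets(expr.truth, de["gene"].tolist(), config.seed)
            universe = de["gene"].tolist()
            selected = sorted({g for g, _ in assignments} & set(universe))
            enrich_rows = []
            if selected:
                for r in gs_mod.enrich_gene_sets(selected, universe, collection):
                    enrich_rows.append(dataclasses.asdict(r))
            pd.DataFrame(enrich_rows).to_csv(
                gs_dir / "enrichment.tsv", sep="\t", index=False
            )
            record(
                "gene_scores",
                {
                    "scores": gs_dir / "gene_scores.tsv",
                    "resistance_index": gs_dir / "resistance_index.tsv",
                    "enrichment": gs_dir / "enrichment.tsv",
                },
            )

        if "screen" in enabled:
            screen_sim = simulate_screen(sim_config)
            screen_dir = outdir / "screen"
            paths = screen_sim.write(screen_dir)
            rpm = screen_mod.normalize_counts(screen_sim.table)
            ratios = screen_mod.shrna_depletion(rpm)
            gene_dep = screen_mod.gene_depletion(ratios)
            result = screen_mod.differential_depletion(
                gene_dep,
                shrna_ratios=ratios,
                n_permutations=config.screen_permutations,
                seed=config.seed,
            )
            ratios.to_csv(screen_dir / "shrna_ratios.tsv", sep="\t", index=False)
            result.table.to_csv(screen_dir / "gene_depletion.tsv", sep="\t", index=False)
            paths.update(
                {
                    "ratios": screen_dir / "shrna_ratios.tsv",
                    "gene_depletion": screen_dir / "gene_depletion.tsv",
                }
            )
            record("screen", paths)

        if "inverse" in enabled:
            kd = simulate_chip_knockdown(sim_config, chip)
            kd_matrix = signal_mod.extract_signal_matrix(
                kd.tracks, kd.peaks, config.window_bp, config.bin_bp
            )
            kd_qnormed = signal_mod.quantile_normalize(kd_matrix)
            kd_stats = diff_mod.compute_region_stats(
                kd_qnormed,
                kd.condition_samples["control"],
                kd.condition_samples["knockdown"],
            )
            kd_up, kd_down = diff_mod.filter_differential_peaks(
                kd_stats,
                min_width_bp=config.min_width_bp,
                min_intensity=config.min_intensity,
                fc_up=config.fc_up,
                fc_down=config.fc_down,
            )
            inv = diff_mod.find_inverse_regions((up, down), (kd_up, kd_down))
            inv_dir = outdir / "inverse"
            inv_dir.mkdir(exist_ok=True)
            rows = []
            for direction, pairs in (
                ("up_in_resistant_down_on_kd", inv.up_down),
                ("down_in_resistant_up_on_kd", inv.down_up),
            ):
                for a, b in pairs:
                    rows.append(
                        {
                            "direction": direction,
                            "chrom": a.chrom,
                            "start": a.start,
                            "end": a.end,
                            "fc_resistant": a.score,
                            "fc_knockdown": b.score,
                        }
                    )
            pd.DataFrame(rows).to_csv(
                inv_dir / "inverse_regions.tsv", sep="\t", index=False
            )
            record("inverse", {"regions": inv_dir / "inverse_regions.tsv"})
    except PipelineError:
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _planted_gene_sets(truth, universe: list[str], seed: int) -> GeneSetCollection:
    """Gene sets for the demo enrichment: the planted signatures + random sets."""
    rng = np.random.default_rng([seed, 17])
    sets = {
        "PLANTED_UP_SIGNATURE": list(truth.signature_up),
        "PLANTED_DOWN_SIGNATURE": list(truth.signature_down),
    }
    pool = list(universe)
    for i in range(3):
        sets[f"RANDOM_SET_{i}"] = sorted(
            rng.choice(pool, size=min(40, len(pool)), replace=False).tolist()
        )
    descriptions = {k: "synthetic gene set" for k in sets}
    return GeneSetCollection(sets, descriptions)
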