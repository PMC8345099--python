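"""Pooled shRNA dropout-screen analysis.

The screen compares guide abundance after 14 days of culture against the
initial library pool, under drug versus vehicle. Counts are normalized to
reads per million, per-guide depletion is the day14/pool RPM ratio, genes
are aggregated by geometric mean over their guide x replicate ratios, and
differential depletion is the drug/vehicle ratio of those gene-level
depletions; the most depleted genes rank first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ScreenCountTable

__all__ = [
    "DepletionResult",
    "normalize_counts",
    "shrna_depletion",
    "gene_depletion",
    "differential_depletion",
]

POOL = "pool"
VEHICLE = "vehicle_d14"
CPT = "cpt_d14"


def normalize_counts(table: ScreenCountTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Reads-per-million per (condition, replicate) library, pseudocounted.

    rpm = 1e6 * (count + pseudocount) / sum over shRNAs of (count + pseudocount).
    """
    df = table.df.copy()
    df["adj"] = df["count"] + pseudocount
    totals = df.groupby(["condition", "replicate"])["adj"].transform("sum")
    if (totals <= 0).any():
        raise ValueError("empty library for some (condition, replicate)")
    df["rpm"] = 1e6 * df["adj"] / totals
    return df.drop(columns="adj")


def shrna_depletion(
    rpm: pd.DataFrame, pool_condition: str = POOL
) -> pd.DataFrame:
    """Per-guide depletion ratio rpm_condition / rpm_pool.

    If the pool was sequenced once (a single replicate) it is broadcast
    against every day-14 replicate; with per-replicate pools the ratio is
    taken within replicate. Guides absent from the pool are dropped with a
    warning column in the report.
    """
    pool = rpm.loc[rpm["condition"] == pool_condition, ["shRNA", "replicate", "rpm"]]
    if pool.empty:
        raise ValueError(f"pool condition {pool_condition!r} absent from table")
    day14 = rpm.loc[rpm["condition"] != pool_condition].copy()
    if pool["replicate"].nunique() == 1:
        merged = day14.merge(
            pool.drop(columns="replicate"), on="shRNA", how="left",
            suffixes=("", "_pool"),
        )
    else:
        merged = day14.merge(
            pool, on=["shRNA", "replicate"], how="left", suffixes=("", "_pool")
        )
    missing = merged["rpm_pool"].isna()
    if missing.any():
        import warnings

        warnings.warn(
            f"{merged.loc[missing, 'shRNA'].nunique()} shRNAs missing from pool; excluded"
        )
        merged = merged.loc[~missing]
    merged["ratio"] = merged["rpm"] / merged["rpm_pool"]
    return merged[["shRNA", "gene", "condition", "replicate", "ratio"]]


def gene_depletion(ratios: pd.DataFrame) -> pd.DataFrame:
    """Geometric mean of depletion ratios per (gene, condition).

    The mean pools all shRNA x replicate ratios of a gene within a
    condition, so it is invariant to aggregation order.
    """
    if (ratios["ratio"] <= 0).any():
        raise ValueError("depletion ratios must be positive")
    df = ratios.copy()
    df["log_ratio"] = np.log(df["ratio"])
    agg = (
        df.groupby(["gene", "condition"], sort=True)
        .agg(log_mean=("log_ratio", "mean"), n_shrnas=("shRNA", "nunique"))
        .reset_index()
    )
    agg["depletion"] = np.exp(agg["log_mean"])
    return agg[["gene", "condition", "depletion", "n_shrnas"]]


@dataclass
class DepletionResult:
    """Ranked differential depletion (drug vs vehicle) per gene."""

    table: pd.DataFrame  # gene, depletion_cpt, depletion_vehicle, differential, rank, ...
    hits: list[str]
    n_permutations: int

    def top(self, n: int = 4) -> list[str]:
        return self.table.nsmallest(n, "differential")["gene"].tolist()


def differential_depletion(
    gene_dep: pd.DataFrame,
    shrna_ratios: pd.DataFrame | None = None,
    cpt_condition: str = CPT,
    vehicle_condition: str = VEHICLE,
    n_permutations: int = 0,
    seed: int = 0,
    hit_threshold: float = 0.5,
    min_shrnas: int = 2,
) -> DepletionResult:
    """Rank genes by drug/vehicle differential depletion.

    ``D(g) = depletion_cpt(g) / depletion_vehicle(g)``; genes sort ascending
    in D (most depleted first, rank 1). With ``n_permutations > 0`` an
    empirical p-value per gene is computed by permuting the shRNA -> gene
    assignment (requires ``shrna_ratios``); the null statistic is matched on
    the gene's shRNA count. Hits are genes with ``D < hit_threshold``
    supported by at least ``min_shrnas`` guides (and, when permutations were
    run, permutation p <= 0.05).
    """
    wide = gene_dep.pivot_table(
        index="gene", columns="condition", values="depletion"
    )
    for cond in (cpt_condition, vehicle_condition):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond!r} absent from gene depletion table")
    n_guides = gene_dep.groupby("gene")["n_shrnas"].max()
    both = wide.dropna(subset=[cpt_condition, vehicle_condition])
    excluded = sorted(set(wide.index) - set(both.index))
    out = pd.DataFrame(
        {
            "gene": both.index,
            "depletion_cpt": both[cpt_condition].to_numpy(),
            "depletion_vehicle": both[vehicle_condition].to_numpy(),
        }
    )
    out["differential"] = out["depletion_cpt"] / out["depletion_vehicle"]
    out["n_shrnas"] = n_guides.reindex(out["gene"]).to_numpy()

    if n_permutations > 0:
        if shrna_ratios is None:
            raise ValueError("permutation test needs the per-shRNA ratio table")
        out = out.merge(
            _permutation_p(
                shrna_ratios, cpt_condition, vehicle_condition, n_permutations, seed
            ),
            on="gene",
            how="left",
        )
    out = out.sort_values(["differential", "gene"], kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    hit_mask = (out["differential"] < hit_threshold) & (out["n_shrnas"] >= min_shrnas)
    if "perm_p" in out.columns:
        hit_mask &= out["perm_p"] <= 0.05
    result = DepletionResult(out, out.loc[hit_mask, "gene"].tolist(), n_permutations)
    if excluded:
        result.table.attrs["excluded_genes"] = excluded
    return result


def _permutation_p(
    shrna_ratios: pd.DataFrame,
    cpt_condition: str,
    vehicle_condition: str,
    n_permutations: int,
    seed: int,
) -> pd.DataFrame:
    """Empirical p for depletion by permuting shRNA -> gene labels.

    The per-guide statistic is the replicate-mean log ratio difference
    (drug minus vehicle); the gene statistic is its mean over the gene's
    guides. For each permutation guides are reshuffled across the same gene
    size structure; p is the fraction of permuted statistics at most the
    observed one, with the +1 correction.
    """
    per_guide = (
        shrna_ratios.assign(log_ratio=np.log(shrna_ratios["ratio"]))
        .pivot_table(
            index=["shRNA", "gene"], columns="condition", values="log_ratio",
            aggfunc="mean",
        )
        .reset_index()
    )
    v = (per_guide[cpt_condition] - per_guide[vehicle_condition]).to_numpy()
    genes = per_guide["gene"].to_numpy()
    order = np.argsort(genes, kind="stable")
    v = v[order]
    genes = genes[order]
    uniq, starts = np.unique(genes, return_index=True)
    sizes = np.diff(np.append(starts, len(genes)))
    observed = np.add.reduceat(v, starts) / sizes
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(uniq))
    for _ in range(n_permutations):
        perm = rng.permutation(v)
        null = np.add.reduceat(perm, starts) / sizes
        exceed += null <= observed
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return pd.DataFrame({"gene": uniq, "perm_p": p})
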