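"""Gene-level integration of acetylation and expression evidence.

Covers four read-outs: cumulative H3K27ac signal per gene, a signature-based
resistance index over an expression panel split by cisplatin GI50, a
combined ranking score multiplying expression fold change, reproducibility
and cumulative acetylation, and hypergeometric gene-set enrichment over
nearest-TSS gene assignments.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

__all__ = [
    "ResistanceIndexResult",
    "EnrichmentResult",
    "cumulative_signal_per_gene",
    "resistance_index",
    "combined_rank_score",
    "enrich_gene_sets",
    "benjamini_hochberg",
]


def cumulative_signal_per_gene(
    assignments: Iterable[tuple[str, float]],
    genes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Sum region signals per assigned gene.

    ``assignments`` yields (gene, region signal) pairs, e.g. from zipping
    nearest-TSS hits with region means. Genes listed in ``genes`` but never
    assigned get 0.
    """
    out: dict[str, float] = {g: 0.0 for g in genes} if genes else {}
    for gene, signal in assignments:
        out[gene] = out.get(gene, 0.0) + float(signal)
    return out


@dataclass
class ResistanceIndexResult:
    """Per-cell-line signature score with a GI50-group comparison."""

    index: pd.Series  # per cell line
    resistant: list[str]
    sensitive: list[str]
    u_statistic: float
    p_value: float
    threshold_uM: float

    @property
    def group_means(self) -> tuple[float, float]:
        """(resistant mean, sensitive mean)."""
        return (
            float(self.index[self.resistant].mean()),
            float(self.index[self.sensitive].mean()),
        )


def resistance_index(
    expression: pd.DataFrame,
    signature_up: Sequence[str],
    signature_down: Sequence[str],
    gi50: Mapping[str, float],
    threshold_uM: float = 20.0,
) -> ResistanceIndexResult:
    """Signature score per cell line, compared between GI50-defined groups.

    Expression (genes x cell lines, log scale) is z-scored per gene across
    the panel; the index is mean z over up-signature genes minus mean z over
    down-signature genes. Lines with GI50 above the threshold are the
    resistant group; group separation is tested with a two-sided
    Mann-Whitney U.
    """
    samples = [s for s in expression.columns if s in gi50]
    if len(samples) < 4:
        raise ValueError("need GI50 for at least 4 panel cell lines")
    up = [g for g in signature_up if g in expression.index]
    down = [g for g in signature_down if g in expression.index]
    dropped = (len(signature_up) - len(up)) + (len(signature_down) - len(down))
    if dropped:
        warnings.warn(f"{dropped} signature genes absent from expression matrix")
    if not up and not down:
        raise ValueError("signature is empty after intersecting with the matrix")
    x = expression[samples].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0  # constant genes contribute z = 0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    zf = pd.DataFrame(z, index=expression.index, columns=samples)
    idx = pd.Series(0.0, index=samples)
    if up:
        idx = idx + zf.loc[up].mean(axis=0)
    if down:
        idx = idx - zf.loc[down].mean(axis=0)
    resistant = [s for s in samples if gi50[s] > threshold_uM]
    sensitive = [s for s in samples if gi50[s] <= threshold_uM]
    if len(resistant) < 2 or len(sensitive) < 2:
        raise ValueError("need at least 2 cell lines per GI50 group")
    r_vals, s_vals = idx[resistant].to_numpy(), idx[sensitive].to_numpy()
    pooled = np.concatenate([r_vals, s_vals])
    if np.all(pooled == pooled[0]):
        u, p = len(r_vals) * len(s_vals) / 2, 1.0
    else:
        res = stats.mannwhitneyu(r_vals, s_vals, alternative="two-sided")
        u, p = float(res.statistic), float(res.pvalue)
    return ResistanceIndexResult(idx, resistant, sensitive, u, p, threshold_uM)


def combined_rank_score(table: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by expression change, reproducibility and acetylation.

    ``table`` needs columns ``gene, log2fc, fdr, cumulative_signal``. The
    score is ``log2fc * (-log10 fdr) * log10(1 + cumulative_signal)``; any
    zero component annihilates it. Genes are ranked descending by score,
    ties broken by FDR (ascending) then gene name.
    """
    for col in ("gene", "log2fc", "fdr", "cumulative_signal"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    df = table.copy()
    if (df["fdr"] > 1).any() or (df["fdr"] < 0).any():
        raise ValueError("FDR must lie in (0, 1]")
    if (df["fdr"] == 0).any():
        warnings.warn("FDR of 0 clamped to the smallest positive float")
        df.loc[df["fdr"] == 0, "fdr"] = sys.float_info.min
    if (df["cumulative_signal"] < 0).any():
        raise ValueError("cumulative signal must be >= 0")
    df["score"] = (
        df["log2fc"]
        * (-np.log10(df["fdr"]))
        * np.log10(1.0 + df["cumulative_signal"])
    )
    df = df.sort_values(
        ["score", "fdr", "gene"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values, clipped to [p, 1]."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one gene set."""

    set_name: str
    overlap: int  # k
    set_size: int  # m (within universe)
    selected: int  # n
    universe: int  # N
    p_value: float
    q_value: float


def enrich_gene_sets(
    selected: Sequence[str],
    universe: Sequence[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each gene set, BH-adjusted.

    ``selected`` must be a subset of ``universe``; gene sets are intersected
    with the universe first and sets disjoint from it are skipped. Results
    are returned for every tested set (filter on ``p_value <= alpha`` for
    reporting); gene symbols are compared upper-case.
    """
    uni = {g.upper() for g in universe}
    sel = {g.upper() for g in selected}
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    big_n, n = len(uni), len(sel)
    results = []
    raw_p = []
    tested = []
    for name, genes in collection.sets.items():
        members = {g.upper() for g in genes} & uni
        if not members:
            warnings.warn(f"gene set {name!r} disjoint from universe; skipped")
            continue
        m = len(members)
        k = len(members & sel)
        # P(X >= k) for X ~ Hypergeom(N, m, n)
        p = float(stats.hypergeom.sf(k - 1, big_n, m, n))
        tested.append((name, k, m))
        raw_p.append(min(p, 1.0))
    q = benjamini_hochberg(raw_p) if raw_p else np.array([])
    for (name, k, m), p, qv in zip(tested, raw_p, q):
        results.append(EnrichmentResult(name, k, m, n, big_n, p, float(qv)))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
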