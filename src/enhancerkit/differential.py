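"""Identification of common vs differential acetylation regions.

Two complementary routes mirror how differential enhancer landscapes are
usually summarized: K-means clustering of per-bin log-ratio profiles (for
the global heatmap view) and an explicit threshold filter on width, peak
intensity and fold change (for region calling). TSS annotation, mark-mark
correlation and inverse-response region matching live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .io import GenomicRegion, RegionSet, TSSAnnotation
from .signal import SignalMatrix

__all__ = [
    "RegionStats",
    "ClusterResult",
    "InverseRegionResult",
    "TSSHit",
    "compute_region_stats",
    "cluster_regions",
    "filter_differential_peaks",
    "annotate_nearest_tss",
    "correlate_marks",
    "find_inverse_regions",
]

#: pseudocount added to both condition means before taking a fold change
FC_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class RegionStats:
    """Per-region summary: condition means and their fold change."""

    region: GenomicRegion
    mean1: float
    mean2: float
    fold_change: float
    width: int

    @staticmethod
    def from_means(
        region: GenomicRegion,
        mean1: float,
        mean2: float,
        pseudocount: float = FC_PSEUDOCOUNT,
    ) -> "RegionStats":
        fc = (mean2 + pseudocount) / (mean1 + pseudocount)
        return RegionStats(region, mean1, mean2, fc, region.width)


def _footprint_bin_mask(matrix: SignalMatrix) -> np.ndarray:
    """Boolean (regions x bins) mask of bins overlapping each peak footprint.

    The extraction window is centered on the peak midpoint and usually wider
    than the peak itself; averaging over the whole window would dilute the
    peak intensity by the footprint/window ratio, so per-region summaries
    are taken over the footprint bins only.
    """
    n_bins = matrix.n_bins
    half = matrix.window_bp // 2
    mask = np.zeros((len(matrix.regions), n_bins), dtype=bool)
    for i, r in enumerate(matrix.regions):
        window_start = r.midpoint - half
        b0 = max(0, (r.start - window_start) // matrix.bin_bp)
        b1 = min(n_bins, -((r.end - window_start) // -matrix.bin_bp))  # ceil div
        mask[i, b0:b1] = True
    return mask


def compute_region_stats(
    matrix: SignalMatrix,
    condition1_samples: Sequence[str],
    condition2_samples: Sequence[str],
    pseudocount: float = FC_PSEUDOCOUNT,
) -> list[RegionStats]:
    """Per-region mean signal per condition (replicates averaged) and FC.

    Means are taken over the bins covering the peak footprint (the region
    itself), not the full extraction window.
    """
    i1 = [matrix.sample_index(s) for s in condition1_samples]
    i2 = [matrix.sample_index(s) for s in condition2_samples]
    mask = _footprint_bin_mask(matrix)
    out = []
    for i, r in enumerate(matrix.regions):
        m1 = float(matrix.values[i][mask[i]][:, i1].mean())
        m2 = float(matrix.values[i][mask[i]][:, i2].mean())
        out.append(RegionStats.from_means(r, m1, m2, pseudocount))
    return out


@dataclass
class ClusterResult:
    """K-means assignment with direction labels derived from mean log-ratio."""

    cluster_id: np.ndarray  # per-region integer cluster
    labels: list[str]  # per-cluster label in {up, down, common}
    k: int
    seed: int
    inertia: float

    @property
    def region_labels(self) -> np.ndarray:
        return np.array([self.labels[c] for c in self.cluster_id])


def _log_ratio_features(
    matrix: SignalMatrix,
    condition1_samples: Sequence[str],
    condition2_samples: Sequence[str],
    pseudocount: float = FC_PSEUDOCOUNT,
) -> np.ndarray:
    i1 = [matrix.sample_index(s) for s in condition1_samples]
    i2 = [matrix.sample_index(s) for s in condition2_samples]
    s1 = matrix.values[:, :, i1].mean(axis=2)
    s2 = matrix.values[:, :, i2].mean(axis=2)
    return np.log2((s2 + pseudocount) / (s1 + pseudocount))


def cluster_regions(
    matrix: SignalMatrix,
    condition1_samples: Sequence[str],
    condition2_samples: Sequence[str],
    k: int = 3,
    seed: int = 0,
    fc_up: float = 1.3,
    fc_down: float = 0.75,
) -> ClusterResult:
    """K-means on per-bin log2 condition-ratio profiles.

    Clusters are labeled by their mean log-ratio: above ``log2(fc_up)`` ->
    ``up``, below ``log2(fc_down)`` -> ``down``, otherwise ``common``.
    Deterministic for a fixed seed (k-means++ with fixed ``n_init``).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(matrix.regions):
        raise ValueError(f"k={k} exceeds number of regions ({len(matrix.regions)})")
    features = _log_ratio_features(matrix, condition1_samples, condition2_samples)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assignment = km.fit_predict(features)
    # label by the footprint-restricted log-ratio so window padding does not
    # dilute the cluster's effective fold change
    fp = _footprint_bin_mask(matrix)
    region_lr = np.array(
        [features[i][fp[i]].mean() for i in range(len(features))]
    )
    labels = []
    for c in range(k):
        mask = assignment == c
        mean_lr = float(region_lr[mask].mean()) if mask.any() else 0.0
        if mean_lr > np.log2(fc_up):
            labels.append("up")
        elif mean_lr < np.log2(fc_down):
            labels.append("down")
        else:
            labels.append("common")
    return ClusterResult(assignment, labels, k, seed, float(km.inertia_))


def filter_differential_peaks(
    stats_list: Sequence[RegionStats],
    min_width_bp: int = 2000,
    min_intensity: float = 1000.0,
    fc_up: float = 1.3,
    fc_down: float = 0.75,
    intensity_mode: str = "max",
) -> tuple[RegionSet, RegionSet]:
    """Threshold filter for differential peaks on quantile-normalized signal.

    A region is called iff ``width > min_width_bp`` and its peak intensity
    exceeds ``min_intensity`` and the fold change (condition2/condition1,
    pseudocounted) is ``> fc_up`` (up) or ``< fc_down`` (down). Intensity is
    the max of the two condition means by default (``intensity_mode="max"``),
    so a peak silenced in one condition still qualifies; ``"mean"`` uses
    their average instead.
    """
    if intensity_mode not in ("max", "mean"):
        raise ValueError("intensity_mode must be 'max' or 'mean'")
    up, down = [], []
    for st in stats_list:
        if st.width <= min_width_bp:
            continue
        intensity = (
            max(st.mean1, st.mean2)
            if intensity_mode == "max"
            else (st.mean1 + st.mean2) / 2
        )
        if intensity <= min_intensity:
            continue
        r = st.region
        scored = GenomicRegion(r.chrom, r.start, r.end, name=r.name, score=st.fold_change)
        if st.fold_change > fc_up:
            up.append(scored)
        elif st.fold_change < fc_down:
            down.append(scored)
    return RegionSet(up, label="up"), RegionSet(down, label="down")


@dataclass(frozen=True)
class TSSHit:
    """Nearest-TSS assignment for a region (signed distance, bp)."""

    region: GenomicRegion
    gene: str | None
    distance: int | None  # positive = downstream of the TSS; None if no TSS on chrom

    @property
    def assigned(self) -> bool:
        return self.gene is not None


def annotate_nearest_tss(regions: RegionSet, tss: TSSAnnotation) -> list[TSSHit]:
    """Assign each region to its nearest TSS by absolute midpoint distance.

    Distance is ``midpoint - tss`` with the sign flipped for minus-strand
    genes, so positive always means downstream of the TSS. Ties (equal
    absolute distance) are broken by lexicographic gene name. Regions on a
    chromosome absent from the annotation get ``gene=None``.
    """
    if len(tss.entries) == 0:
        raise ValueError("TSS annotation is empty")
    by_chrom: dict[str, list[tuple[str, int, str]]] = {}
    for gene, chrom, pos, strand in tss.entries:
        by_chrom.setdefault(chrom, []).append((gene, pos, strand))
    hits = []
    for region in regions:
        entries = by_chrom.get(region.chrom)
        if not entries:
            hits.append(TSSHit(region, None, None))
            continue
        mid = region.midpoint
        best = min(entries, key=lambda e: (abs(mid - e[1]), e[0]))
        gene, pos, strand = best
        signed = mid - pos
        if strand == "-":
            signed = -signed
        hits.append(TSSHit(region, gene, int(signed)))
    return hits


def distance_histogram(
    hits: Sequence[TSSHit], breaks: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed TSS distances over the given breaks."""
    d = np.array([h.distance for h in hits if h.assigned], dtype=float)
    counts, edges = np.histogram(d, bins=np.asarray(breaks, dtype=float))
    return counts, edges


@dataclass
class MarkCorrelation:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    means_a: np.ndarray = field(repr=False, default=None)
    means_b: np.ndarray = field(repr=False, default=None)


def correlate_marks(
    matrix_a: SignalMatrix, matrix_b: SignalMatrix
) -> MarkCorrelation:
    """Correlate per-region mean signal of two marks over the same regions."""
    if len(matrix_a.regions) != len(matrix_b.regions):
        raise ValueError("matrices must cover the same regions")
    if len(matrix_a.regions) < 3:
        raise ValueError("need at least 3 regions to correlate")
    a = matrix_a.values.mean(axis=(1, 2))
    b = matrix_b.values.mean(axis=(1, 2))
    pr = stats.pearsonr(a, b)
    sr = stats.spearmanr(a, b)
    return MarkCorrelation(
        float(pr.statistic),
        float(pr.pvalue),
        float(sr.statistic),
        float(sr.pvalue),
        len(a),
        means_a=a,
        means_b=b,
    )


@dataclass
class InverseRegionResult:
    """Regions whose acetylation change opposes between two comparisons.

    ``up_down``: up in comparison A, overlapping a down region of comparison
    B; ``down_up`` is the symmetric set. Each match carries both regions'
    fold changes (taken from the BED score column of the input sets).
    """

    up_down: list[tuple[GenomicRegion, GenomicRegion]]
    down_up: list[tuple[GenomicRegion, GenomicRegion]]

    @property
    def n_up_down(self) -> int:
        return len(self.up_down)

    @property
    def n_down_up(self) -> int:
        return len(self.down_up)


def _overlap_pairs(
    set_a: RegionSet, set_b: RegionSet, min_overlap_frac: float
) -> list[tuple[GenomicRegion, GenomicRegion]]:
    """All (a, b) pairs that overlap; optional reciprocal-fraction threshold."""
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for b in set_b:
        by_chrom.setdefault(b.chrom, []).append(b)
    for regions in by_chrom.values():
        regions.sort(key=lambda r: r.start)
    pairs = []
    for a in set_a:
        candidates = by_chrom.get(a.chrom, ())
        for b in candidates:
            if b.start >= a.end:
                break
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov <= 0:
                continue
            if min_overlap_frac > 0 and (
                ov / a.width < min_overlap_frac or ov / b.width < min_overlap_frac
            ):
                continue
            pairs.append((a, b))
    return pairs


def find_inverse_regions(
    diff_a: tuple[RegionSet, RegionSet],
    diff_b: tuple[RegionSet, RegionSet],
    min_overlap_frac: float = 0.0,
) -> InverseRegionResult:
    """Match regions changing in opposite directions between two comparisons.

    ``diff_a`` and ``diff_b`` are (up, down) region-set pairs from
    :func:`filter_differential_peaks`. With the default threshold any
    overlap counts; a reciprocal overlap fraction can be required when the
    two comparisons use different peak universes.
    """
    up_a, down_a = diff_a
    up_b, down_b = diff_b
    return InverseRegionResult(
        up_down=_overlap_pairs(up_a, down_b, min_overlap_frac),
        down_up=_overlap_pairs(down_a, up_b, min_overlap_frac),
    )
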