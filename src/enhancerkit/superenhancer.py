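"""ROSE-style super-enhancer calling.

Peaks within a stitch distance of one another are merged into stitched
enhancers; stitched enhancers are ranked by total signal and the rank curve,
scaled to the unit square, is cut where its discrete slope first exceeds 1
(the tangent-line rule). Everything above that cutoff is a super-enhancer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CoverageTrack, GenomicRegion, RegionSet, TSSAnnotation

__all__ = [
    "StitchedEnhancer",
    "SECall",
    "stitch_peaks",
    "call_superenhancers",
    "region_signals",
]


@dataclass
class StitchedEnhancer:
    """Hull of transitively stitched peaks with their summed signal."""

    region: GenomicRegion
    constituents: list[GenomicRegion]
    total_signal: float
    rank: int | None = None  # ascending by total signal, set when called

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


@dataclass
class SECall:
    """Super-enhancer call: flags, signal cutoff and the scaled rank curve."""

    enhancers: list[StitchedEnhancer]  # sorted ascending by total signal
    is_super: np.ndarray
    cutoff_signal: float
    scaled_rank: np.ndarray
    scaled_signal: np.ndarray

    @property
    def n_super(self) -> int:
        return int(self.is_super.sum())

    def superenhancers(self) -> list[StitchedEnhancer]:
        return [e for e, s in zip(self.enhancers, self.is_super) if s]

    def typical(self) -> list[StitchedEnhancer]:
        return [e for e, s in zip(self.enhancers, self.is_super) if not s]


def region_signals(track: CoverageTrack, regions: RegionSet) -> np.ndarray:
    """Ranking signal per constituent: mean track value x width (area)."""
    return np.array(
        [track.mean(r.chrom, r.start, r.end) * r.width for r in regions], dtype=float
    )


def stitch_peaks(
    peaks: RegionSet,
    signals: Sequence[float] | None = None,
    stitch_bp: int = 12_500,
    tss: TSSAnnotation | None = None,
    tss_exclusion_bp: int = 0,
) -> list[StitchedEnhancer]:
    """Merge peaks on a chromosome whose gap is at most ``stitch_bp``.

    ``signals`` supplies the per-peak ranking signal (parallel to ``peaks``);
    if omitted, each peak's ``score`` is used (0 where unset). With a TSS
    exclusion window, peaks fully contained in ``tss +- tss_exclusion_bp``
    are dropped before stitching (promoter-proximal filtering).
    """
    if stitch_bp < 0:
        raise ValueError("stitch distance must be >= 0")
    if signals is None:
        signals = [r.score if r.score is not None else 0.0 for r in peaks]
    if len(signals) != len(peaks):
        raise ValueError("signals must be parallel to peaks")

    items = sorted(
        zip(peaks, signals), key=lambda t: (t[0].chrom, t[0].start, t[0].end)
    )
    if tss is not None and tss_exclusion_bp > 0:
        windows: dict[str, list[tuple[int, int]]] = {}
        for _, chrom, pos, _ in tss.entries:
            windows.setdefault(chrom, []).append(
                (pos - tss_exclusion_bp, pos + tss_exclusion_bp)
            )
        items = [
            (r, s)
            for r, s in items
            if not any(
                w0 <= r.start and r.end <= w1 for w0, w1 in windows.get(r.chrom, ())
            )
        ]

    stitched: list[StitchedEnhancer] = []
    group: list[tuple[GenomicRegion, float]] = []

    def flush() -> None:
        if not group:
            return
        regions = [g[0] for g in group]
        hull = GenomicRegion(
            regions[0].chrom,
            min(r.start for r in regions),
            max(r.end for r in regions),
        )
        stitched.append(
            StitchedEnhancer(hull, regions, float(sum(g[1] for g in group)))
        )

    for region, sig in items:
        if group and (
            region.chrom != group[-1][0].chrom
            or region.start - max(g[0].end for g in group) > stitch_bp
        ):
            flush()
            group = []
        group.append((region, sig))
    flush()
    return stitched


def call_superenhancers(stitched: Sequence[StitchedEnhancer]) -> SECall:
    """Rank stitched enhancers and cut the scaled curve at slope 1.

    Enhancers are sorted ascending by total signal; rank and signal are both
    scaled to [0, 1]; the cutoff is the signal at the first rank where the
    discrete slope of the scaled curve exceeds 1, and every enhancer with
    total signal strictly above the cutoff is flagged super.
    """
    if len(stitched) < 3:
        raise ValueError("need at least 3 stitched enhancers to call a cutoff")
    order = np.argsort([e.total_signal for e in stitched], kind="stable")
    enhancers = [stitched[i] for i in order]
    for rank, e in enumerate(enhancers):
        e.rank = rank
    signal = np.array([e.total_signal for e in enhancers], dtype=float)
    n = len(signal)
    span = signal[-1] - signal[0]
    scaled_rank = np.arange(n, dtype=float) / (n - 1)
    if span == 0:
        warnings.warn("all stitched enhancers have equal signal; no supers called")
        return SECall(
            enhancers,
            np.zeros(n, dtype=bool),
            float(signal[-1]),
            scaled_rank,
            np.zeros(n, dtype=float),
        )
    scaled_signal = (signal - signal[0]) / span
    # discrete slope between consecutive scaled points
    slopes = np.diff(scaled_signal) / np.diff(scaled_rank)
    above = np.nonzero(slopes > 1)[0]
    if len(above) == 0:
        cutoff = float(signal[-1])
    else:
        cutoff = float(signal[above[0]])
    is_super = signal > cutoff
    return SECall(enhancers, is_super, cutoff, scaled_rank, scaled_signal)
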