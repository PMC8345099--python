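"""Peak-centered signal matrices and the normalizations applied to ChIP data.

A :class:`SignalMatrix` holds normalized coverage binned in a fixed window
around each peak center (regions x bins x samples). Quantile normalization
equalizes the marginal signal distribution across samples; spike-in and
reference-gene normalizations handle the qPCR read-outs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CoverageTrack, RegionSet

__all__ = [
    "SignalMatrix",
    "QpcrRecord",
    "extract_signal_matrix",
    "quantile_normalize",
    "quantile_normalize_columns",
    "normalize_chip_qpcr",
    "relative_expression",
    "fold_change_ddct",
]


@dataclass
class SignalMatrix:
    """Binned coverage: ``values[region, bin, sample]`` in arbitrary units."""

    values: np.ndarray  # (n_regions, n_bins, n_samples)
    regions: RegionSet
    samples: list[str]
    window_bp: int
    bin_bp: int

    def __post_init__(self) -> None:
        n_regions, n_bins, n_samples = self.values.shape
        if n_regions != len(self.regions):
            raise ValueError("values/regions length mismatch")
        if n_samples != len(self.samples):
            raise ValueError("values/samples length mismatch")
        if self.window_bp % self.bin_bp != 0:
            raise ValueError("window_bp must be an even multiple of bin_bp")
        if n_bins != self.window_bp // self.bin_bp:
            raise ValueError("bin dimension inconsistent with window/bin size")
        if np.isnan(self.values).any():
            raise ValueError("SignalMatrix must not contain NaN")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def region_means(self, sample: str | Sequence[str]) -> np.ndarray:
        """Per-region mean signal for one sample or averaged over several."""
        names = [sample] if isinstance(sample, str) else list(sample)
        idx = [self.sample_index(s) for s in names]
        return self.values[:, :, idx].mean(axis=(1, 2))

    def to_frame(self) -> pd.DataFrame:
        """Long-format TSV-ready table (region, bin, sample, value)."""
        n_r, n_b, n_s = self.values.shape
        region_names = [
            r.name if r.name else f"{r.chrom}:{r.start}-{r.end}" for r in self.regions
        ]
        rows = {
            "region": np.repeat(region_names, n_b * n_s),
            "bin": np.tile(np.repeat(np.arange(n_b), n_s), n_r),
            "sample": np.tile(self.samples, n_r * n_b),
            "value": self.values.ravel(),
        }
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def extract_signal_matrix(
    tracks: Mapping[str, CoverageTrack],
    peaks: RegionSet,
    window_bp: int = 10_000,
    bin_bp: int = 100,
) -> SignalMatrix:
    """Bin per-bp coverage in a fixed window around each peak center.

    The window is ``[center - window/2, center + window/2)`` with
    ``center = floor((start + end) / 2)``; each bin holds the mean per-bp
    value, zero outside the covered chromosome.
    """
    if window_bp % bin_bp != 0:
        raise ValueError("window_bp must be an even multiple of bin_bp")
    n_bins = window_bp // bin_bp
    samples = list(tracks)
    values = np.zeros((len(peaks), n_bins, len(samples)), dtype=float)
    half = window_bp // 2
    for i, region in enumerate(peaks):
        center = region.midpoint
        w_start, w_end = center - half, center + half
        for j, name in enumerate(samples):
            per_bp = tracks[name].values(region.chrom, w_start, w_end)
            values[i, :, j] = per_bp.reshape(n_bins, bin_bp).mean(axis=1)
    return SignalMatrix(values, peaks, samples, window_bp, bin_bp)


def quantile_normalize_columns(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a 2-D (features x samples) array.

    Each column's values are replaced by the across-column mean of the sorted
    values at the same rank; tied values receive the mean of the reference
    values over their tied rank positions. Afterwards every column has an
    identical sorted vector.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D features x samples array")
    n_features, n_samples = x.shape
    if n_samples < 2:
        warnings.warn("quantile normalization with a single sample is the identity")
        return x.copy()
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        order = np.argsort(x[:, j], kind="stable")
        col_sorted = x[order, j]
        assigned = reference.copy()
        # tie handling: average the reference over each run of equal values
        start = 0
        for k in range(1, n_features + 1):
            if k == n_features or col_sorted[k] != col_sorted[start]:
                if k - start > 1:
                    assigned[start:k] = reference[start:k].mean()
                start = k
        out[order, j] = assigned
    return out


def quantile_normalize(matrix: SignalMatrix) -> SignalMatrix:
    """Quantile-normalize a :class:`SignalMatrix` across its samples.

    Normalization operates on the flattened region x bin vector per sample,
    i.e. on each sample's whole signal distribution over the peak windows.
    """
    n_r, n_b, n_s = matrix.values.shape
    flat = matrix.values.reshape(n_r * n_b, n_s)
    normed = quantile_normalize_columns(flat)
    return SignalMatrix(
        normed.reshape(n_r, n_b, n_s),
        matrix.regions,
        list(matrix.samples),
        matrix.window_bp,
        matrix.bin_bp,
    )


@dataclass(frozen=True)
class QpcrRecord:
    """One ChIP-qPCR measurement with its input and spike-in counterparts."""

    target: float
    input_signal: float
    spike_target: float
    spike_input: float

    def __post_init__(self) -> None:
        if self.input_signal <= 0 or self.spike_input <= 0 or self.spike_target <= 0:
            raise ValueError("qPCR denominators must be positive")

    @property
    def spike_normalized(self) -> float:
        """(target/input) corrected by the spike-in recovery (spike/spike-input)."""
        return (self.target / self.input_signal) / (
            self.spike_target / self.spike_input
        )


def normalize_chip_qpcr(record: QpcrRecord, reference: QpcrRecord) -> float:
    """Spike-in-corrected enrichment as fold over the reference condition.

    The spike-in chromatin is added at a fixed fraction before IP, so the
    ratio of its recovery between samples calibrates ChIP efficiency; the
    reference record maps to exactly 1.0.
    """
    ref = reference.spike_normalized
    if ref == 0:
        raise ZeroDivisionError("reference spike-normalized value is zero")
    return record.spike_normalized / ref


def relative_expression(
    target: float,
    reference_gene: float,
    control_target: float,
    control_reference: float,
) -> float:
    """Ratio-of-ratios expression: (target/ref) over the control sample's.

    The control sample maps to 1.0 by construction.
    """
    if reference_gene <= 0 or control_reference <= 0 or control_target <= 0:
        raise ValueError("reference and control quantities must be positive")
    return (target / reference_gene) / (control_target / control_reference)


def fold_change_ddct(
    ct_target: float,
    ct_reference: float,
    ct_control_target: float,
    ct_control_reference: float,
    efficiency: float = 2.0,
) -> float:
    """2^-ddCt convenience wrapper mapping Ct values to relative expression."""
    quantity = lambda ct: efficiency ** (-ct)  # noqa: E731
    return relative_expression(
        quantity(ct_target),
        quantity(ct_reference),
        quantity(ct_control_target),
        quantity(ct_control_reference),
    )
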