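"""Readers and writers for the plain-text genomics formats the pipeline consumes.

Coordinate conventions: BED intervals are 0-based half-open ``[start, end)``;
VCF positions are 1-based. The single place where the two meet is
:func:`variant_in_region`, which all counting code goes through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "RegionSet",
    "VariantSet",
    "TSSAnnotation",
    "GeneSetCollection",
    "CoverageTrack",
    "ScreenCountTable",
    "read_bed",
    "write_bed",
    "read_track",
    "write_bedgraph",
    "read_vcf_positions",
    "write_vcf",
    "read_count_table",
    "read_gmt",
    "read_tss_table",
    "write_tss_table",
    "variant_in_region",
]


class ParseError(ValueError):
    """Raised when a file does not conform to its declared format."""


@dataclass(frozen=True)
class GenomicRegion:
    """Half-open genomic interval ``[start, end)`` on ``chrom`` (0-based)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: end <= start"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint; even-width ties resolve leftward."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class RegionSet:
    """Ordered collection of :class:`GenomicRegion` with a class label."""

    def __init__(self, regions: Iterable[GenomicRegion] = (), label: str = ""):
        self.regions: list[GenomicRegion] = list(regions)
        self.label = label

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def sorted(self) -> "RegionSet":
        return RegionSet(
            sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)),
            label=self.label,
        )

    def __repr__(self) -> str:
        return f"RegionSet(n={len(self)}, label={self.label!r})"


@dataclass
class VariantSet:
    """Point variants as 1-based ``(chrom, pos)`` pairs for one sample."""

    positions: list[tuple[str, int]]
    sample: str = ""

    def __post_init__(self) -> None:
        for chrom, pos in self.positions:
            if pos < 1:
                raise ValueError(f"VCF POS must be >= 1, got {chrom}:{pos}")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class TSSAnnotation:
    """Transcription start sites: ``(gene, chrom, tss, strand)``, tss 1-based."""

    entries: list[tuple[str, str, int, str]]

    def __post_init__(self) -> None:
        for gene, chrom, tss, strand in self.entries:
            if strand not in ("+", "-"):
                raise ValueError(f"strand must be + or -, got {strand!r} for {gene}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GeneSetCollection:
    """Named gene sets with one-line descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def variant_in_region(pos: int, start: int, end: int) -> bool:
    """True iff the 1-based variant position falls in the 0-based ``[start, end)``.

    A variant at POS ``p`` occupies 0-based coordinate ``p - 1``, hence it is
    inside iff ``start < p <= end``.
    """
    return start < pos <= end


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> RegionSet:
    """Read a 3-6 column BED file into a :class:`RegionSet` (order preserved)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            try:
                regions.append(GenomicRegion(chrom, start, end, name=name, score=score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return RegionSet(regions, label=Path(path).stem)


def write_bed(regions: RegionSet | Sequence[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED; emits 3, 4 or 5 columns depending on what is set."""
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None or r.score is not None:
                cols.append(r.name if r.name is not None else ".")
            if r.score is not None:
                cols.append(f"{r.score:g}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# bedGraph coverage tracks
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Per-bp coverage backed by non-overlapping bedGraph intervals.

    Queries over any interval return a per-bp vector, zero where uncovered.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values), each sorted by start, non-overlapping
        self._by_chrom = intervals

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if end <= start:
                raise ValueError(f"invalid bedGraph interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        any_negative = False
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
            ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
            values = np.array([iv[2] for iv in ivs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping bedGraph intervals on {chrom} near position {ends[i]}"
                )
            if np.any(values < 0):
                any_negative = True
            out[chrom] = (starts, ends, values)
        if any_negative:
            warnings.warn("track contains negative values (background-subtracted?)")
        return cls(out)

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp values over ``[start, end)``; zeros where uncovered.

        ``start`` may be negative (upstream of the chromosome): those
        positions are reported as zero coverage.
        """
        if end <= start:
            raise ValueError("query end must exceed start")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._by_chrom:
            return out
        starts, ends, values = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start)
            b = min(ends[i], end)
            if b > a:
                out[a - start : b - start] = values[i]
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        return float(self.values(chrom, start, end).mean())


def read_track(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return CoverageTrack.from_records(records)


def write_bedgraph(
    records: Iterable[tuple[str, int, int, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_positions(
    path: str | Path, keep_filters: tuple[str, ...] = ("PASS", ".")
) -> VariantSet:
    """Extract one ``(chrom, POS)`` per VCF record whose FILTER passes.

    Multi-allelic records contribute a single position. ``keep_filters``
    controls which FILTER values are retained (default: PASS and unfiltered).
    """
    positions: list[tuple[str, int]] = []
    sample = ""
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                cols = line.split("\t")
                if len(cols) > 9:
                    sample = cols[9]
                continue
            if line.startswith("#"):
                continue
            if not saw_header:
                raise ParseError(f"{path}: record before #CHROM header line")
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: expected >=7 VCF columns")
            filt = fields[6]
            if filt not in keep_filters:
                continue
            positions.append((fields[0], int(fields[1])))
    if not saw_header:
        raise ParseError(f"{path}: missing #CHROM header")
    return VariantSet(positions, sample=sample)


def write_vcf(variants: VariantSet, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with PASS records (REF/ALT are placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos in sorted(variants.positions):
            fh.write(f"{chrom}\t{pos}\t.\tN\tA\t60\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Screen count tables
# ---------------------------------------------------------------------------

class ScreenCountTable:
    """shRNA-level counts indexed by (shRNA, gene, condition, replicate).

    Wraps a DataFrame with columns ``shRNA, gene, condition, replicate,
    count``. Each shRNA maps to exactly one gene; the (shRNA x condition x
    replicate) index must be complete unless missing cells were filled.
    """

    REQUIRED = ("shRNA", "gene", "condition", "replicate", "count")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if (df["count"] < 0).any():
            bad = df.loc[df["count"] < 0].iloc[0]
            raise ValueError(
                f"negative count for ({bad['shRNA']}, {bad['condition']}, "
                f"{bad['replicate']})"
            )
        dup = df.duplicated(subset=["shRNA", "condition", "replicate"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise ValueError(
                f"duplicate key ({bad['shRNA']}, {bad['condition']}, "
                f"{bad['replicate']})"
            )
        genes_per_shrna = df.groupby("shRNA")["gene"].nunique()
        if (genes_per_shrna > 1).any():
            bad = genes_per_shrna[genes_per_shrna > 1].index[0]
            raise ValueError(f"shRNA {bad!r} maps to multiple genes")
        self.df = df.reset_index(drop=True)

    @property
    def shrnas(self) -> list[str]:
        return sorted(self.df["shRNA"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    def __len__(self) -> int:
        return len(self.df)


def read_count_table(path: str | Path, fill_missing: bool = False) -> ScreenCountTable:
    """Read a TSV of screen counts; the index must be complete.

    With ``fill_missing=True`` absent (shRNA, condition, replicate) cells are
    filled with count 0 instead of raising.
    """
    df = pd.read_csv(path, sep="\t", dtype={"shRNA": str, "gene": str, "condition": str})
    missing_cols = [c for c in ScreenCountTable.REQUIRED if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    if not np.issubdtype(df["count"].dtype, np.integer):
        as_float = df["count"].astype(float)
        if not np.allclose(as_float, np.round(as_float)):
            raise ValueError(f"{path}: non-integer counts")
        df["count"] = as_float.round().astype(int)
    table = ScreenCountTable(df)
    # completeness over the full cross product
    expected = (
        table.df["shRNA"].nunique()
        * table.df.groupby("condition")["replicate"].nunique().sum()
    )
    if len(table.df) != expected:
        if not fill_missing:
            raise ValueError(
                f"{path}: incomplete index ({len(table.df)} rows, expected {expected}); "
                "pass fill_missing=True to fill with zeros"
            )
        gene_of = table.df.drop_duplicates("shRNA").set_index("shRNA")["gene"]
        cells = [
            (s, gene_of[s], c, r)
            for s in table.df["shRNA"].unique()
            for c, reps in table.df.groupby("condition")["replicate"].unique().items()
            for r in reps
        ]
        full = pd.DataFrame(cells, columns=["shRNA", "gene", "condition", "replicate"])
        merged = full.merge(table.df, how="left").fillna({"count": 0})
        merged["count"] = merged["count"].astype(int)
        table = ScreenCountTable(merged)
    return table


# ---------------------------------------------------------------------------
# GMT gene sets and TSS tables
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read GMT (set name, description, genes...); gene symbols upper-cased."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT needs name, description and >=1 gene"
                )
            name = fields[0]
            genes = [g.upper() for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
            descriptions[name] = fields[1]
    return GeneSetCollection(sets, descriptions)


def read_tss_table(path: str | Path) -> TSSAnnotation:
    """Read a TSV with columns gene, chrom, tss (1-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    for col in ("gene", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    entries = [
        (row.gene, row.chrom, int(row.tss), row.strand)
        for row in df.itertuples(index=False)
    ]
    return TSSAnnotation(entries)


def write_tss_table(tss: TSSAnnotation, path: str | Path) -> None:
    pd.DataFrame(tss.entries, columns=["gene", "chrom", "tss", "strand"]).to_csv(
        path, sep="\t", index=False
    )
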