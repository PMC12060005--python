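"""Shared genomic data model: genomes, intervals, genes, binned tracks.

All coordinates are 0-based half-open throughout the package; 1-based
inputs (GFF3) are converted at the I/O boundary.  Adjacent intervals
([a, b) and [b, c)) never count as overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

#: Region labels recognised on a :class:`GenomeModel`.
REGION_LABELS = ("autosome", "PAR", "S0", "W")


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "Interval") -> int:
        """Overlap in bp with ``other``; 0 if different chromosome or disjoint."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "Interval") -> bool:
        return self.overlap_length(other) > 0


@dataclass(frozen=True)
class SampleKey:
    """Identifies one profiled sample: sex, tissue, replicate number."""

    sex: str
    tissue: str
    replicate: int = 1

    def label(self) -> str:
        return f"{self.sex}_{self.tissue}_rep{self.replicate}"


@dataclass
class GenomeModel:
    """Chromosome sizes plus a map of special regions (PAR, S0, W).

    Any position not covered by an explicit region interval is treated as
    autosomal.  Region intervals must lie within their chromosome and must
    not overlap one another.
    """

    chromosomes: list[tuple[str, int]]
    regions: list[tuple[Interval, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if name in seen:
                raise ValueError(f"duplicate chromosome {name}")
            seen.add(name)
        sizes = dict(self.chromosomes)
        by_chrom: dict[str, list[Interval]] = {}
        for iv, label in self.regions:
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r}")
            if iv.chrom not in sizes:
                raise ValueError(f"region on unknown chromosome {iv.chrom}")
            if iv.end > sizes[iv.chrom]:
                raise ValueError(f"region {iv} exceeds chromosome length")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping regions on {chrom}: {a} / {b}")

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def chrom_length(self, name: str) -> int:
        for n, length in self.chromosomes:
            if n == name:
                return length
        raise KeyError(f"unknown chromosome {name}")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.chrom_length(chrom) // bin_size)

    def region_of(self, chrom: str, pos: int) -> str:
        """Region label at a single position (default ``autosome``)."""
        if chrom not in dict(self.chromosomes):
            raise KeyError(f"unknown chromosome {chrom}")
        for iv, label in self.regions:
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return label
        return "autosome"

    def region_of_interval(self, iv: Interval) -> str:
        """Region label at the interval midpoint."""
        return self.region_of(iv.chrom, (iv.start + iv.end) // 2)

    def region_intervals(self, label: str) -> list[Interval]:
        """Maximal intervals carrying ``label`` (autosome = complement)."""
        if label != "autosome":
            return [iv for iv, lab in self.regions if lab == label]
        out = []
        for chrom, length in self.chromosomes:
            covered = sorted(
                (iv for iv, _ in self.regions if iv.chrom == chrom),
                key=lambda i: i.start,
            )
            pos = 0
            for iv in covered:
                if iv.start > pos:
                    out.append(Interval(chrom, pos, iv.start))
                pos = iv.end
            if pos < length:
                out.append(Interval(chrom, pos, length))
        return out

    def region_length(self, label: str) -> int:
        return sum(iv.length for iv in self.region_intervals(label))


@dataclass
class GeneAnnotation:
    """A gene: transcript span plus transposable-element content flags."""

    gene_id: str
    body: Interval
    te_in_intron: bool = False
    te_in_exon: bool = False

    @property
    def tss(self) -> int:
        return self.body.start if self.body.strand != "-" else self.body.end - 1


def check_unique_gene_ids(genes: Sequence[GeneAnnotation]) -> None:
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("gene_id values are not unique")


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width binned signal for one mark in one sample.

    The final bin of each chromosome may be truncated by the chromosome
    end; it still counts as one bin but its true width is used for any
    per-bp arithmetic.
    """

    mark: str
    sample: SampleKey
    bin_size: int
    values: dict[str, np.ndarray]
    genome: GenomeModel | None = None

    def __post_init__(self) -> None:
        for chrom, vals in self.values.items():
            vals = np.asarray(vals, dtype=float)
            if np.any(vals < 0):
                raise ValueError(f"negative values on {chrom}")
            self.values[chrom] = vals
            if self.genome is not None:
                expect = self.genome.n_bins(chrom, self.bin_size)
                if len(vals) != expect:
                    raise ValueError(
                        f"{chrom}: {len(vals)} bins, expected {expect} "
                        f"for bin size {self.bin_size}"
                    )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def n_bins(self) -> int:
        return sum(len(v) for v in self.values.values())

    def interval_count(self, iv: Interval) -> float:
        """Signal attributed to an interval, fractional at partial bins."""
        vals = self.values.get(iv.chrom)
        if vals is None:
            raise KeyError(f"track has no chromosome {iv.chrom}")
        bs = self.bin_size
        first, last = iv.start // bs, (iv.end - 1) // bs
        total = 0.0
        for b in range(first, min(last, len(vals) - 1) + 1):
            b_start, b_end = b * bs, (b + 1) * bs
            ov = min(b_end, iv.end) - max(b_start, iv.start)
            total += vals[b] * ov / bs
        return total

    def per_bp(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base step values over [start, end); out-of-range is NaN."""
        vals = self.values[chrom]
        bs = self.bin_size
        pos = np.arange(start, end)
        out = np.full(end - start, np.nan)
        ok = (pos >= 0) & (pos // bs < len(vals))
        out[ok] = vals[pos[ok] // bs]
        return out

    def scaled(self, factor: float) -> "BinnedTrack":
        return replace(
            self, values={c: v * factor for c, v in self.values.items()}
        )


def intersect(
    a: Sequence[Interval],
    b: Sequence[Interval],
    genome: GenomeModel | None = None,
) -> list[tuple[int, int, int]]:
    """All overlapping pairs between two interval sets.

    Returns ``(index_in_a, index_in_b, overlap_bp)`` triples; every reported
    overlap is at least 1 bp (half-open adjacency is not overlap).
    """
    if genome is not None:
        known = set(genome.chrom_names)
        for iv in list(a) + list(b):
            if iv.chrom not in known:
                raise KeyError(f"unknown chromosome {iv.chrom}")
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    out = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if ov > 0:
                out.append((i, hit.data, ov))
    out.sort()
    return out


def replicate_correlation(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    features: Sequence[Interval],
) -> float:
    """Pearson r of per-feature normalized coverage between two tracks.

    Coverage per feature is signal per bp scaled to the track's total
    (per-million), so library size differences cancel.  Raises
    ``ValueError`` when either vector has zero variance (r undefined).
    """
    from scipy.stats import pearsonr

    if not features:
        raise ValueError("no features given")

    def vec(track: BinnedTrack) -> np.ndarray:
        total = track.total()
        scale = 1e6 / total if total > 0 else 1.0
        return np.array(
            [track.interval_count(iv) / iv.length * scale for iv in features]
        )

    va, vb = vec(track_a), vec(track_b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("zero variance in per-feature coverage: r undefined")
    return float(pearsonr(va, vb)[0])
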