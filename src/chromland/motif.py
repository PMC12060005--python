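"""Motif scanning, per-region densities, and the random-loci resampling
enrichment test.

The scanner matches an IUPAC consensus (optionally with mismatches) on
both strands, reporting every overlapping occurrence.  Enrichment of
motif hits in a peak set is assessed against B resampled locus sets drawn
uniformly over the genome with the observed peak-length multiset; the
empirical p uses the add-one form, so its floor is 1 / (B + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomeModel, Interval

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class MotifModel:
    """IUPAC consensus with an allowed mismatch budget."""

    consensus: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if len(self.consensus) < 4:
            raise ValueError("consensus must be at least 4 bases")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes: {sorted(bad)}")

    def reverse_complement(self) -> str:
        return self.consensus.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_positions(
    enc: np.ndarray, pattern: str, max_mismatches: int, masked: np.ndarray | None
) -> np.ndarray:
    L = len(pattern)
    n = len(enc) - L + 1
    if n <= 0:
        return np.array([], dtype=int)
    mismatches = np.zeros(n, dtype=np.int16)
    for j, code in enumerate(pattern):
        allowed = _encode(IUPAC[code])
        window = enc[j : j + n]
        mismatches += ~np.isin(window, allowed)
    hits = np.flatnonzero(mismatches <= max_mismatches)
    if masked is not None and len(hits):
        bad = np.convolve(masked.astype(int), np.ones(L, dtype=int), mode="valid") > 0
        hits = hits[~bad[hits]]
    return hits


def scan_motif(
    sequences: Mapping[str, str],
    motif: MotifModel | str,
    skip_masked: bool = True,
) -> pd.DataFrame:
    """All motif occurrences on both strands of every sequence.

    Sequences are uppercase-normalised; when ``skip_masked`` is set,
    windows touching lowercase or N bases are not reported.  Overlapping
    occurrences are all returned.  Columns: chrom, start, end, strand.
    """
    if isinstance(motif, str):
        motif = MotifModel(motif)
    L = len(motif.consensus)
    rows = []
    for chrom, seq in sequences.items():
        raw = _encode(seq)
        masked = None
        if skip_masked:
            is_lower = (raw >= 97) & (raw <= 122)
            upper = np.where(is_lower, raw - 32, raw)
            masked = is_lower | (upper == ord("N"))
            enc = upper
        else:
            enc = np.where((raw >= 97) & (raw <= 122), raw - 32, raw)
        for strand, pattern in (
            ("+", motif.consensus),
            ("-", motif.reverse_complement()),
        ):
            for pos in _match_positions(enc, pattern, motif.max_mismatches, masked):
                rows.append((chrom, int(pos), int(pos) + L, strand))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return out.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


def motif_density(
    occurrences: pd.DataFrame,
    regions: Sequence[tuple[str, Interval]],
) -> pd.DataFrame:
    """Hits per Mb for each named region (hit midpoint must fall inside)."""
    rows = []
    for name, iv in regions:
        if iv.length == 0:
            raise ValueError(f"zero-length region {name}")
        if len(occurrences):
            mid = (occurrences["start"] + occurrences["end"]) // 2
            n = int(
                (
                    (occurrences["chrom"] == iv.chrom)
                    & (mid >= iv.start)
                    & (mid < iv.end)
                ).sum()
            )
        else:
            n = 0
        rows.append(
            {
                "region": name,
                "chrom": iv.chrom,
                "length": iv.length,
                "count": n,
                "per_mb": n / (iv.length / 1e6),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ResamplingResult:
    observed: int
    b: int
    n_ge_observed: int
    p: float
    seed: int


def _count_hits(
    starts_by_chrom: dict[str, np.ndarray],
    motif_len: int,
    loci_chrom: np.ndarray,
    loci_start: np.ndarray,
    loci_end: np.ndarray,
) -> int:
    """Number of (locus, occurrence) overlaps; an occurrence overlaps a
    locus iff its start lies in (locus.start - L, locus.end)."""
    total = 0
    for chrom in np.unique(loci_chrom):
        starts = starts_by_chrom.get(chrom)
        if starts is None:
            continue
        sel = loci_chrom == chrom
        lo = np.searchsorted(starts, loci_start[sel] - motif_len + 1, side="left")
        hi = np.searchsorted(starts, loci_end[sel], side="left")
        total += int((hi - lo).sum())
    return total


def resampling_enrichment(
    peaks: Sequence[Interval] | pd.DataFrame,
    occurrences: pd.DataFrame,
    genome: GenomeModel,
    b: int = 10_000,
    seed: int = 0,
) -> ResamplingResult:
    """Empirical enrichment of motif hits in a peak set.

    The statistic is the number of motif occurrences overlapping the
    loci.  Each of the ``b`` resamples places one random locus per
    observed peak, uniformly over the genome, with the same length
    multiset (clipped to chromosome ends).  p = (1 + #{resample >=
    observed}) / (b + 1); deterministic given ``seed``.
    """
    if isinstance(peaks, pd.DataFrame):
        peaks = [Interval(r.chrom, r.start, r.end) for r in peaks.itertuples()]
    if not peaks:
        raise ValueError("peak set is empty")
    if b < 100:
        warnings.warn("fewer than 100 resamples gives a coarse p-value")
    if len(occurrences) == 0:
        motif_len = 1
        starts_by_chrom: dict[str, np.ndarray] = {}
    else:
        motif_len = int((occurrences["end"] - occurrences["start"]).iloc[0])
        starts_by_chrom = {
            chrom: np.sort(sub["start"].to_numpy())
            for chrom, sub in occurrences.groupby("chrom")
        }

    lengths = np.array([p.length for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    starts = np.array([p.start for p in peaks])
    observed = _count_hits(
        starts_by_chrom, motif_len, chroms, starts, starts + lengths
    )

    chrom_names = np.array(genome.chrom_names)
    chrom_sizes = np.array([genome.chrom_length(c) for c in chrom_names])
    cum = np.concatenate([[0], np.cumsum(chrom_sizes)])
    total = cum[-1]

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(b):
        gpos = rng.integers(0, total, size=len(peaks))
        ci = np.searchsorted(cum, gpos, side="right") - 1
        pos = gpos - cum[ci]
        # clip so each locus keeps its full length inside the chromosome
        pos = np.minimum(pos, np.maximum(chrom_sizes[ci] - lengths, 0))
        stat = _count_hits(
            starts_by_chrom, motif_len, chrom_names[ci], pos, pos + lengths
        )
        if stat >= observed:
            n_ge += 1
    p = (1 + n_ge) / (b + 1)
    return ResamplingResult(
        observed=int(observed), b=b, n_ge_observed=n_ge, p=float(p), seed=seed
    )
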