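"""Per-gene histone-mark enrichment (CPKM), Z-specific vs autosome
comparisons, TSS metaprofiles, AUC-threshold peak calling, and
peak/expression relationships.

CPKM is counts per kilobase of gene body per million assigned reads.  The
peak caller keeps maximal runs of non-zero signal whose area (value x
width) exceeds the (1 - f) empirical quantile of all block areas - the
threshold-free top-fraction rule used for sparse tagmentation data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core import BinnedTrack, GeneAnnotation, GenomeModel, Interval, SampleKey

LOG2_PSEUDOCOUNT = 0.5


def cpkm(counts: float, gene_length_bp: float, library_size: float) -> float:
    """counts / ((length in kb) x (library reads / 1e6))."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return counts / ((gene_length_bp / 1e3) * (library_size / 1e6))


def cpkm_table(
    tracks: Mapping[tuple, BinnedTrack],
    genes: Sequence[GeneAnnotation],
) -> pd.DataFrame:
    """Per-gene CPKM for every track; columns are the track keys
    (mark, sex, tissue, replicate), rows are genes."""
    data = {}
    for key, track in tracks.items():
        lib = track.total()
        data[key] = [
            cpkm(track.interval_count(g.body), g.body.length, lib) for g in genes
        ]
    out = pd.DataFrame(data, index=[g.gene_id for g in genes])
    out.columns = pd.MultiIndex.from_tuples(
        out.columns, names=["mark", "sex", "tissue", "replicate"]
    )
    return out.sort_index(axis=1)


def replicate_mean_cpkm(
    table: pd.DataFrame, mark: str, sex: str, tissue: str
) -> pd.Series:
    return table.loc[:, (mark, sex, tissue)].mean(axis=1)


def region_enrichment(
    table: pd.DataFrame,
    genome: GenomeModel,
    genes: Sequence[GeneAnnotation],
    expression: pd.Series,
    mark: str,
    region: str = "S0",
    tpm_floor: float = 0.5,
) -> pd.DataFrame:
    """Rank-sum comparison of per-gene CPKM between a sex-chromosome
    region and the autosomes, per sex/tissue and per replicate.

    Genes pass the expressed filter when their mean TPM exceeds
    ``tpm_floor``.  Reports the ratio of group medians and the two-sided
    rank-sum p on replicate-mean CPKM, plus each replicate separately
    (the replicate-consistency check).
    """
    import warnings

    by_region = {
        g.gene_id: genome.region_of_interval(g.body) for g in genes
    }
    expressed = set(expression.index[expression > tpm_floor])
    reg_ids = [g for g, r in by_region.items() if r == region and g in expressed]
    auto_ids = [g for g, r in by_region.items() if r == "autosome" and g in expressed]
    if not reg_ids or not auto_ids:
        raise ValueError("empty gene group after expressed filter")
    if min(len(reg_ids), len(auto_ids)) < 5:
        warnings.warn("fewer than 5 genes in a group; test still computed")

    rows = []
    sub = table[mark]
    for sex, tissue in sorted({(s, t) for s, t, _ in sub.columns}):
        reps = sub.loc[:, (sex, tissue)]
        entries = [("mean", reps.mean(axis=1))] + [
            (f"rep{r}", reps[r]) for r in reps.columns
        ]
        for label, vals in entries:
            a, b = vals.loc[reg_ids], vals.loc[auto_ids]
            med_a, med_b = float(a.median()), float(b.median())
            stat, p = mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {
                    "mark": mark,
                    "sex": sex,
                    "tissue": tissue,
                    "replicate": label,
                    "n_region": len(a),
                    "n_autosome": len(b),
                    "median_region": med_a,
                    "median_autosome": med_b,
                    "median_ratio": med_a / med_b if med_b > 0 else np.inf,
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TssProfile:
    """Mean normalized coverage around TSSs for one gene group."""

    group: str
    positions: np.ndarray  # bin-start offsets relative to the TSS
    values: np.ndarray
    n_genes: int


def tss_profiles(
    tracks: Sequence[BinnedTrack],
    genes: Sequence[GeneAnnotation],
    genome: GenomeModel,
    group: str = "all",
    upstream: int = 1000,
    downstream: int = 2000,
    bin_width: int = 5,
) -> TssProfile:
    """Strand-aware TSS metaprofile, replicates combined by mean.

    Each replicate track is scaled per-million before averaging; minus
    strand genes are flipped so the axis runs 5'->3'.  Positions outside
    the chromosome are excluded from the mean rather than padded with
    zeros.
    """
    n_bins = (upstream + downstream) // bin_width
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    scaled = []
    for t in tracks:
        total = t.total()
        scaled.append(t.scaled(1e6 / total) if total > 0 else t)
    used = 0
    for g in genes:
        tss = g.tss
        length = genome.chrom_length(g.body.chrom)
        if not 0 <= tss < length:
            continue
        if g.body.strand == "-":
            start, end = tss - downstream + 1, tss + upstream + 1
        else:
            start, end = tss - upstream, tss + downstream
        per_bp = np.nanmean(
            [t.per_bp(g.body.chrom, start, end) for t in scaled], axis=0
        )
        if g.body.strand == "-":
            per_bp = per_bp[::-1]
        binned = per_bp.reshape(n_bins, bin_width)
        with np.errstate(invalid="ignore"):
            vals = np.nanmean(binned, axis=1)
        ok = ~np.isnan(vals)
        acc[ok] += vals[ok]
        cnt[ok] += 1
        used += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    positions = np.arange(-upstream, downstream, bin_width)
    return TssProfile(group=group, positions=positions, values=mean, n_genes=used)


def call_peaks(track: BinnedTrack, top_fraction: float = 0.01) -> pd.DataFrame:
    """Top-fraction AUC peak caller on a non-negative signal track.

    Candidate blocks are maximal runs of non-zero bins; block AUC is the
    sum of value x bp width.  Blocks whose AUC exceeds the (1 - f)
    empirical quantile of all block AUCs are returned.  Scale-invariant:
    rescaling the track by any positive constant keeps the same peaks.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    blocks = []
    bs = track.bin_size
    for chrom, vals in track.values.items():
        length = (
            track.genome.chrom_length(chrom) if track.genome else len(vals) * bs
        )
        nz = vals > 0
        if not nz.any():
            continue
        edges = np.flatnonzero(np.diff(np.r_[0, nz.astype(int), 0]))
        for i0, i1 in zip(edges[::2], edges[1::2]):
            start, end = i0 * bs, min(i1 * bs, length)
            widths = np.full(i1 - i0, bs, dtype=float)
            widths[-1] = end - (i1 - 1) * bs
            auc = float(np.dot(vals[i0:i1], widths))
            blocks.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "auc": auc,
                    "max": float(vals[i0:i1].max()),
                }
            )
    if not blocks:
        return pd.DataFrame(columns=["chrom", "start", "end", "auc", "max"])
    df = pd.DataFrame(blocks)
    threshold = float(np.quantile(df["auc"], 1 - top_fraction))
    out = df[df["auc"] > threshold].reset_index(drop=True)
    out.attrs["threshold"] = threshold
    out.attrs["n_blocks"] = len(df)
    return out


def peaks_to_intervals(peaks: pd.DataFrame) -> list[Interval]:
    return [Interval(r.chrom, r.start, r.end) for r in peaks.itertuples()]


def log2_fm_ratio(tpm: pd.DataFrame, tissue: str) -> pd.Series:
    """Per-gene log2 female:male expression (replicate means, pseudocount)."""
    from .sexbias import _sex_columns

    f = _sex_columns(tpm, "female", tissue).mean(axis=1)
    m = _sex_columns(tpm, "male", tissue).mean(axis=1)
    return np.log2((f + LOG2_PSEUDOCOUNT) / (m + LOG2_PSEUDOCOUNT))


def peak_gene_analysis(
    peaks: pd.DataFrame,
    genes: Sequence[GeneAnnotation],
    tpm: pd.DataFrame,
    genome: GenomeModel,
    tissue: str,
    sex: str = "female",
    region: str = "S0",
    tpm_floor: float = 0.5,
) -> dict:
    """Overlap of region genes with peaks, and rank-sum comparisons of
    (a) expression and (b) log2 female:male ratio between peak-overlapping
    and non-overlapping genes.

    The expressed filter (mean TPM > floor in the given sex/tissue) is
    applied first.  A comparison with an empty side is skipped with a
    note.
    """
    from .core import intersect
    from .sexbias import _sex_columns

    expr = _sex_columns(tpm, sex, tissue).mean(axis=1)
    region_genes = [
        g
        for g in genes
        if genome.region_of_interval(g.body) == region
        and expr.get(g.gene_id, 0) > tpm_floor
    ]
    peak_ivs = peaks_to_intervals(peaks)
    hits = intersect([g.body for g in region_genes], peak_ivs)
    with_peak = {region_genes[i].gene_id for i, _, _ in hits}
    ids = [g.gene_id for g in region_genes]
    without_peak = [g for g in ids if g not in with_peak]
    result = {
        "n_expressed": len(ids),
        "n_with_peak": len(with_peak),
        "n_without_peak": len(without_peak),
        "fraction_with_peak": len(with_peak) / len(ids) if ids else np.nan,
    }
    fm = log2_fm_ratio(tpm, tissue)
    for name, series in (("expression", expr), ("log2_fm", fm)):
        if not with_peak or not without_peak:
            result[name] = {"skipped": "one group empty"}
            continue
        a = series.loc[sorted(with_peak)]
        b = series.loc[without_peak]
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        result[name] = {
            "median_with_peak": float(a.median()),
            "median_without_peak": float(b.median()),
            "p": float(p),
        }
    return result
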