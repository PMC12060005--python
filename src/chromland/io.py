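"""Readers and writers for BED, bedGraph, GFF3 genes, FASTA and genome JSON.

Every writer's output reads back to the identical in-memory object for the
fields retained.  BED and bedGraph stay 0-based half-open; GFF3 gene rows
are converted from 1-based closed coordinates on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import BinnedTrack, GeneAnnotation, GenomeModel, Interval, SampleKey


class ParseError(ValueError):
    """Malformed input line; message carries the 1-based line number."""


def read_bed(path) -> list[Interval]:
    """Read BED3/BED6 intervals; name/score columns are ignored."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(Interval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(
    intervals: Sequence[Interval],
    path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3 (or BED6 when names/scores/strands are present)."""
    six = names is not None or scores is not None or any(
        iv.strand != "." for iv in intervals
    )
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if six:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(path) -> list[tuple[Interval, float]]:
    """Read a bedGraph; intervals must be sorted and non-overlapping per chrom."""
    out: list[tuple[Interval, float]] = []
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinate or value") from exc
            chrom = fields[0]
            try:
                iv = Interval(chrom, start, end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if chrom in last and start < last[chrom]:
                raise ParseError(
                    f"{path}:{lineno}: unsorted or overlapping interval on {chrom}"
                )
            last[chrom] = end
            out.append((iv, value))
    return out


def write_bedgraph(records: Sequence[tuple[Interval, float]], path) -> None:
    with open(path, "w") as fh:
        for iv, value in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


def track_to_bedgraph(track: BinnedTrack) -> list[tuple[Interval, float]]:
    """Flatten a binned track to bedGraph runs; zero bins are omitted
    (gaps read back as 0) and adjacent equal-valued bins are merged."""
    genome = track.genome
    out = []
    for chrom, vals in track.values.items():
        length = genome.chrom_length(chrom) if genome else len(vals) * track.bin_size
        i = 0
        while i < len(vals):
            j = i
            while j + 1 < len(vals) and vals[j + 1] == vals[i]:
                j += 1
            if vals[i] != 0:
                start = i * track.bin_size
                end = min((j + 1) * track.bin_size, length)
                out.append((Interval(chrom, start, end), float(vals[i])))
            i = j + 1
    return out


def bedgraph_to_track(
    records: Sequence[tuple[Interval, float]],
    genome: GenomeModel,
    bin_size: int,
    mark: str = "signal",
    sample: SampleKey | None = None,
) -> BinnedTrack:
    """Bin bedGraph records over a declared genome; gaps become 0.

    A record's value is distributed to bins by bp overlap, expressed per
    full bin width (the inverse of :func:`track_to_bedgraph`).
    """
    values = {
        chrom: np.zeros(genome.n_bins(chrom, bin_size))
        for chrom in genome.chrom_names
    }
    for iv, value in records:
        vals = values[iv.chrom]
        first, last = iv.start // bin_size, (iv.end - 1) // bin_size
        for b in range(first, last + 1):
            ov = min((b + 1) * bin_size, iv.end) - max(b * bin_size, iv.start)
            vals[b] += value * ov / bin_size
    # end-truncated bins store the full-bin-equivalent value
    for chrom in genome.chrom_names:
        length = genome.chrom_length(chrom)
        if length % bin_size:
            frac = (length % bin_size) / bin_size
            values[chrom][-1] /= frac if frac > 0 else 1.0
            values[chrom][-1] *= 1.0
    return BinnedTrack(
        mark=mark,
        sample=sample or SampleKey("na", "na", 1),
        bin_size=bin_size,
        values=values,
        genome=genome,
    )


def read_gff3_genes(path) -> list[GeneAnnotation]:
    """Minimal GFF3 reader: ``gene`` features only, 1-based converted."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != "gene":
                continue
            try:
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"gene_{lineno}")
            strand = fields[6] if fields[6] in "+-" else "."
            try:
                body = Interval(fields[0], start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(GeneAnnotation(gene_id=gene_id, body=body))
    return out


def write_gff3_genes(genes: Sequence[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.body
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(
                f"{iv.chrom}\tchromland\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\tID={g.gene_id}\n"
            )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_genome(genome: GenomeModel, path) -> None:
    obj = {
        "chromosomes": [[n, L] for n, L in genome.chromosomes],
        "regions": [
            [iv.chrom, iv.start, iv.end, label] for iv, label in genome.regions
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_genome(path) -> GenomeModel:
    obj = json.loads(Path(path).read_text())
    return GenomeModel(
        chromosomes=[(n, int(L)) for n, L in obj["chromosomes"]],
        regions=[
            (Interval(c, int(s), int(e)), label)
            for c, s, e, label in obj.get("regions", [])
        ],
    )


def write_genes_tsv(genes: Sequence[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tte_in_intron\tte_in_exon\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.body.chrom}\t{g.body.start}\t{g.body.end}\t"
                f"{g.body.strand}\t{int(g.te_in_intron)}\t{int(g.te_in_exon)}\n"
            )


def read_genes_tsv(path) -> list[GeneAnnotation]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ParseError(f"{path}:1: missing gene table header")
        for line in fh:
            gid, chrom, start, end, strand, tei, tee = line.rstrip("\n").split("\t")
            out.append(
                GeneAnnotation(
                    gene_id=gid,
                    body=Interval(chrom, int(start), int(end), strand),
                    te_in_intron=bool(int(tei)),
                    te_in_exon=bool(int(tee)),
                )
            )
    return out
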