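"""Readers and writers for BED, BedGraph, GTF (GENCODE dialect), FASTA and
plain TSV tables.

Every reader converts to the package's internal 0-based half-open
coordinates; GTF is 1-based inclusive on disk and converted at this
boundary.  Malformed lines raise ``FileFormatError`` naming file and line.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import SignalTrack
from .genes import GeneModel, TranscriptModel
from .intervals import GenomicInterval, GenomeSequence


class FileFormatError(ValueError):
    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


# ---------------------------------------------------------------- BED


def read_bed(path) -> list[GenomicInterval]:
    """BED3/BED6; name and strand are kept when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FileFormatError(path, lineno, "fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FileFormatError(path, lineno, f"bad coordinates: {exc}") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise FileFormatError(path, lineno, str(exc)) from exc
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path,
    scores: Sequence[float] | None = None,
) -> None:
    """BED6 when any record carries a name/strand/score, else BED3."""
    intervals = list(intervals)
    bed6 = scores is not None or any(
        iv.name is not None or iv.strand != "." for iv in intervals
    )
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if bed6:
                score = 0 if scores is None else scores[i]
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t{score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------- BedGraph


def read_bedgraph(path, sample_id: str | None = None) -> SignalTrack:
    runs: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FileFormatError(path, lineno, "fewer than 4 BedGraph fields")
            try:
                runs.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise FileFormatError(path, lineno, f"bad BedGraph record: {exc}") from exc
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    try:
        return SignalTrack.from_runs(runs, sample_id=sample_id)
    except ValueError as exc:
        raise FileFormatError(path, 0, str(exc)) from exc


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------- GTF


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in raw.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_genes(path) -> list[GeneModel]:
    """Assemble gene models from GTF exon records (GENCODE dialect:
    attributes carry ``gene_id`` and ``transcript_id``)."""
    exons: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FileFormatError(path, lineno, f"expected 9 GTF fields, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attr_raw = fields
            if feature != "exon":
                continue
            try:
                start0 = int(start) - 1  # 1-based inclusive -> 0-based half-open
                end0 = int(end)
            except ValueError as exc:
                raise FileFormatError(path, lineno, f"bad coordinates: {exc}") from exc
            attrs = _parse_gtf_attributes(attr_raw)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise FileFormatError(path, lineno, "missing gene_id/transcript_id attribute")
            key = (attrs["gene_id"], attrs["transcript_id"])
            rec = exons.setdefault(key, {"chrom": chrom, "strand": strand, "exons": []})
            rec["exons"].append(GenomicInterval(chrom, start0, end0, strand))
    genes: dict[str, GeneModel] = {}
    for (gene_id, transcript_id), rec in exons.items():
        tx = TranscriptModel(transcript_id, rec["chrom"], rec["strand"], rec["exons"])
        if gene_id not in genes:
            genes[gene_id] = GeneModel(gene_id, rec["chrom"], rec["strand"], [tx])
        else:
            genes[gene_id].transcripts.append(tx)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.span.start, g.gene_id))


def write_gtf(genes: Iterable[GeneModel], path, source: str = "tcnescan") -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for exon in tx.exons:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}"
                        f"\t.\t{gene.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> GenomeSequence:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(genome.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- TSV


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
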