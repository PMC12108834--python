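"""Gene and transcript models built from GTF-style annotation."""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval


@dataclass
class TranscriptModel:
    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand,
            name=self.transcript_id,
        )

    @property
    def length(self) -> int:
        return self.span.length

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, indexed 1..k in transcription
        order (5'->3' along the strand): the list is returned in that order,
        so ``introns()[0]`` is the first intron on either strand."""
        gaps = [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]
        if self.strand == "-":
            gaps.reverse()
        return gaps


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.strand != self.strand:
                raise ValueError(f"strand mismatch in gene {self.gene_id}")

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand, name=self.gene_id)

    @property
    def tss(self) -> int:
        """Transcription start site in genome coordinates (strand-aware)."""
        span = self.span
        return span.start if self.strand == "+" else span.end

    @property
    def tes(self) -> int:
        span = self.span
        return span.end if self.strand == "+" else span.start

    def representative_transcript(self) -> TranscriptModel:
        """Longest transcript (genomic span), the default isoform used for
        intron indexing and context classification."""
        return max(self.transcripts, key=lambda t: (t.length, t.transcript_id))

    def exons(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]
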