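"""Genic context of each element: intronic vs intergenic, intron index,
TSS distance and normalized position within the host gene."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genes import GeneModel, TranscriptModel
from .intervals import GenomicInterval, overlap_length
from .stats import spearman


@dataclass
class ContextAnnotation:
    element_id: str
    category: str                      # "intronic" | "intergenic"
    host_gene_id: str | None = None    # intronic only
    intron_index: int | None = None    # 1-based, 5'->3'
    tss_distance_bp: int | None = None
    normalized_position: float | None = None  # intronic only
    nearest_gene_id: str | None = None        # intergenic only
    ambiguous: bool = False
    boundary_flagged: bool = False


def introns_of(transcript: TranscriptModel) -> list[GenomicInterval]:
    """Ordered introns of a transcript (1..k in transcription order)."""
    return transcript.introns()


def tss_distance(element: GenomicInterval, gene: GeneModel) -> int:
    """Signed distance from the gene TSS to the element midpoint; positive
    values lie downstream of the TSS on the gene's strand."""
    if gene.strand not in "+-":
        raise ValueError(f"gene {gene.gene_id} has no strand")
    mid = element.midpoint
    return mid - gene.tss if gene.strand == "+" else gene.tss - mid


def normalized_position(element: GenomicInterval, gene: GeneModel) -> float:
    """TSS distance over gene span length, clamped to [0, 1]."""
    length = gene.span.length
    if length == 0:
        raise ValueError(f"zero-length gene {gene.gene_id}")
    return min(1.0, max(0.0, tss_distance(element, gene) / length))


def _intron_hit(element: GenomicInterval, gene: GeneModel) -> int | None:
    """1-based index of the representative-transcript intron wholly
    containing the element, else None."""
    for idx, intron in enumerate(gene.representative_transcript().introns(), 1):
        if (
            intron.chrom == element.chrom
            and element.start >= intron.start
            and element.end <= intron.end
        ):
            return idx
    return None


def classify_context(
    element: GenomicInterval, genes: Sequence[GeneModel], element_id: str | None = None
) -> ContextAnnotation:
    """Intronic when the element lies wholly within an intron of a host
    gene's representative (longest) transcript; otherwise intergenic with
    the nearest gene by absolute TSS distance.

    When introns of several overlapping genes contain the element the gene
    with the closer TSS wins and the annotation is flagged ambiguous.  An
    element straddling an exon boundary of the representative transcript of
    an overlapping gene is classified by majority base overlap with the
    merged intronic space and flagged.
    """
    eid = element_id or element.name or str(element)
    hits: list[tuple[GeneModel, int]] = []
    overlapping: list[GeneModel] = []
    for gene in genes:
        if gene.chrom != element.chrom:
            continue
        if overlap_length(element, gene.span) > 0:
            overlapping.append(gene)
            idx = _intron_hit(element, gene)
            if idx is not None:
                hits.append((gene, idx))
    if hits:
        hits.sort(key=lambda h: (abs(tss_distance(element, h[0])), -h[0].span.length))
        gene, idx = hits[0]
        return ContextAnnotation(
            element_id=eid,
            category="intronic",
            host_gene_id=gene.gene_id,
            intron_index=idx,
            tss_distance_bp=tss_distance(element, gene),
            normalized_position=normalized_position(element, gene),
            ambiguous=len(hits) > 1,
        )
    # straddling an exon boundary: majority-overlap rule, flagged
    for gene in overlapping:
        introns = gene.representative_transcript().introns()
        inside = sum(overlap_length(element, i) for i in introns)
        if inside * 2 > element.length:
            return ContextAnnotation(
                element_id=eid,
                category="intronic",
                host_gene_id=gene.gene_id,
                intron_index=None,
                tss_distance_bp=tss_distance(element, gene),
                normalized_position=normalized_position(element, gene),
                boundary_flagged=True,
            )
    nearest = None
    best = None
    for gene in genes:
        if gene.chrom != element.chrom:
            continue
        d = abs(element.midpoint - gene.tss)
        if best is None or d < best:
            best, nearest = d, gene
    return ContextAnnotation(
        element_id=eid,
        category="intergenic",
        nearest_gene_id=nearest.gene_id if nearest else None,
        tss_distance_bp=tss_distance(element, nearest) if nearest else None,
        boundary_flagged=bool(overlapping),
    )


def annotate_elements(
    elements: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[ContextAnnotation]:
    return [classify_context(e, genes) for e in elements]


def context_table(annotations: Sequence[ContextAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": [a.element_id for a in annotations],
            "category": [a.category for a in annotations],
            "host_gene_id": [a.host_gene_id for a in annotations],
            "nearest_gene_id": [a.nearest_gene_id for a in annotations],
            "intron_index": [a.intron_index for a in annotations],
            "tss_distance_bp": [a.tss_distance_bp for a in annotations],
            "normalized_position": [a.normalized_position for a in annotations],
            "ambiguous": [a.ambiguous for a in annotations],
        }
    )


def distance_expression_correlation(
    annotations: Sequence[ContextAnnotation], host_expression: dict[str, float]
) -> tuple[float, float]:
    """Spearman correlation between intronic-element TSS distances and the
    expression of their host genes."""
    dist, expr = [], []
    for a in annotations:
        if a.category == "intronic" and a.host_gene_id in host_expression:
            dist.append(float(a.tss_distance_bp))
            expr.append(float(host_expression[a.host_gene_id]))
    return spearman(dist, expr)
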