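"""TCNE-to-gene linking by expression correlation with copy-number
filtering.

Candidate pairs are element/gene combinations whose element midpoint lies
within 500 kb of the gene TSS on the same chromosome.  Samples whose copy
number is aberrant (|log2 segment mean| above the cutoff) at either locus
are dropped from the correlation; the link passes when Spearman rho > 0.8
and the Benjamini-Hochberg adjusted p < 0.01 over the whole candidate
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel
from .intervals import GenomicInterval
from .stats import bh_adjust, spearman


@dataclass
class LinkConfig:
    window: int = 500_000
    cna_cutoff: float = 1.5
    cna_two_sided: bool = True     # False: literal one-sided "above 1.5"
    cna_drop_link: bool = False    # True: discard the whole link instead of samples
    rho_min: float = 0.8
    alpha: float = 0.01
    min_samples: int = 8
    adjust_method: str = "fdr_bh"  # "holm" available


@dataclass
class CNASegments:
    """Per-sample copy-number segments: sample -> (intervals, log2 means)."""

    segments: dict[str, list[tuple[GenomicInterval, float]]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CNASegments":
        """Columns: sample, chrom, start, end, log2_segment_mean."""
        out: dict[str, list[tuple[GenomicInterval, float]]] = {}
        for row in df.itertuples(index=False):
            out.setdefault(str(row.sample), []).append(
                (
                    GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                    float(row.log2_segment_mean),
                )
            )
        return cls(out)

    def value_at(self, sample: str, chrom: str, pos: int) -> float | None:
        for iv, value in self.segments.get(sample, ()):
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return value
        return None


@dataclass
class LinkRecord:
    tcne_id: str
    gene_id: str
    distance_to_tss: int
    n_samples_used: int = 0
    rho: float = float("nan")
    p_raw: float = float("nan")
    p_adjusted: float = float("nan")
    passed: bool = False
    genes_skipped: int = 0
    skip_reason: str | None = None
    retained_samples: list[str] = field(default_factory=list)
    uncovered_flag: bool = False


def candidate_pairs(
    elements: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = 500_000,
) -> list[tuple[GenomicInterval, GeneModel]]:
    """All same-chromosome pairs with |element midpoint - gene TSS| <= window."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs = []
    for el in elements:
        for g in by_chrom.get(el.chrom, []):
            if abs(el.midpoint - g.tss) <= window:
                pairs.append((el, g))
    return pairs


def cna_sample_filter(
    element: GenomicInterval,
    gene: GeneModel,
    samples: Sequence[str],
    cna: CNASegments | None,
    cutoff: float = 1.5,
    two_sided: bool = True,
) -> tuple[list[str], bool]:
    """Samples retained for the correlation.

    A sample is dropped when its log2 segment mean at the element midpoint
    or at the gene TSS exceeds the cutoff (strictly; |.| when two_sided).
    Samples with no covering segment at a locus are retained and flagged.
    """
    if cna is None:
        return list(samples), False
    retained = []
    uncovered = False
    gene_pos = gene.tss if gene.strand == "+" else gene.tss - 1
    for s in samples:
        drop = False
        for chrom, pos in ((element.chrom, element.midpoint), (gene.chrom, gene_pos)):
            v = cna.value_at(s, chrom, pos)
            if v is None:
                uncovered = True
                continue
            metric = abs(v) if two_sided else v
            if metric > cutoff:
                drop = True
                break
        if not drop:
            retained.append(s)
    return retained, uncovered


def test_link(tcne_expr: Sequence[float], gene_expr: Sequence[float]) -> tuple[float, float]:
    """Spearman rho and raw p for one candidate pair."""
    return spearman(tcne_expr, gene_expr)


def link_candidates(
    elements: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    tcne_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    cna: CNASegments | None = None,
    config: LinkConfig | None = None,
) -> list[LinkRecord]:
    """Full linking pipeline over expression matrices (features x samples).

    ``tcne_expr`` rows are element ids, ``gene_expr`` rows are gene ids;
    the two matrices are aligned on their shared sample columns.
    """
    config = config or LinkConfig()
    samples = [s for s in tcne_expr.columns if s in set(gene_expr.columns)]
    if len(samples) != len(tcne_expr.columns) or len(samples) != len(gene_expr.columns):
        raise ValueError("sample ids differ between element and gene expression matrices")
    gene_by_id = {g.gene_id: g for g in genes}
    records: list[LinkRecord] = []
    for el, gene in candidate_pairs(elements, genes, config.window):
        eid = el.name or str(el)
        rec = LinkRecord(
            tcne_id=eid,
            gene_id=gene.gene_id,
            distance_to_tss=el.midpoint - gene.tss,
        )
        records.append(rec)
        if eid not in tcne_expr.index or gene.gene_id not in gene_expr.index:
            rec.skip_reason = "missing expression"
            continue
        retained, uncovered = cna_sample_filter(
            el, gene, samples, cna, config.cna_cutoff, config.cna_two_sided
        )
        rec.uncovered_flag = uncovered
        if config.cna_drop_link and len(retained) < len(samples):
            rec.skip_reason = "cna_aberrant_link"
            continue
        rec.retained_samples = retained
        rec.n_samples_used = len(retained)
        if len(retained) < config.min_samples:
            rec.skip_reason = "too few retained samples"
            continue
        x = tcne_expr.loc[eid, retained].to_numpy(dtype=float)
        y = gene_expr.loc[gene.gene_id, retained].to_numpy(dtype=float)
        try:
            rec.rho, rec.p_raw = test_link(x, y)
        except ValueError:
            rec.skip_reason = "constant expression"
    tested = [r for r in records if not np.isnan(r.p_raw)]
    if tested:
        adjusted = bh_adjust([r.p_raw for r in tested], method=config.adjust_method)
        for r, padj in zip(tested, adjusted):
            r.p_adjusted = float(padj)
            r.passed = (r.rho > config.rho_min) and (r.p_adjusted < config.alpha)
    _annotate_skipped_genes(records, elements, genes)
    return records


def _annotate_skipped_genes(
    records: Sequence[LinkRecord],
    elements: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
) -> None:
    el_by_id = {(e.name or str(e)): e for e in elements}
    gene_by_id = {g.gene_id: g for g in genes}
    for rec in records:
        el = el_by_id[rec.tcne_id]
        target = gene_by_id[rec.gene_id]
        lo, hi = sorted((el.midpoint, target.tss))
        rec.genes_skipped = sum(
            1
            for g in genes
            if g.chrom == el.chrom and g.gene_id != target.gene_id and lo < g.tss < hi
        )


def links_table(records: Sequence[LinkRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tcne_id": [r.tcne_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "distance_to_tss": [r.distance_to_tss for r in records],
            "n_samples_used": [r.n_samples_used for r in records],
            "rho": [r.rho for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adjusted": [r.p_adjusted for r in records],
            "passed": [r.passed for r in records],
            "genes_skipped": [r.genes_skipped for r in records],
            "skip_reason": [r.skip_reason for r in records],
        }
    )


def link_topology(records: Sequence[LinkRecord]) -> dict[str, pd.Series]:
    """Summaries over passed links: elements per gene, genes per element,
    and the skipped-gene count distribution."""
    passed = [r for r in records if r.passed]
    per_gene = pd.Series([r.gene_id for r in passed]).value_counts().sort_index()
    per_tcne = pd.Series([r.tcne_id for r in passed]).value_counts().sort_index()
    skipped = pd.Series([r.genes_skipped for r in passed]).value_counts().sort_index()
    return {
        "tcnes_per_gene": per_gene,
        "genes_per_tcne": per_tcne,
        "genes_skipped": skipped,
    }
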