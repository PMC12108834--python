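"""Putative RNA G-quadruplex (PQS) detection on element transcript
sequences.

The motif grammar is explicit: four G-tracts of at least ``min_tract``
guanines separated by three loops of 1-30 nt.  Tracts are maximal G-runs
(loops never begin or end with G, though a loop may contain interior
G-runs when a run is skipped), which makes every candidate decomposition
unambiguous and exhaustively enumerable.  The score is

    score = 20 * (tetrads - 1) - sum_i max(0, loop_i - 3)

with ``tetrads`` the shortest tract length; canonical three-tetrad
quadruplexes with short loops score 40 and two-tetrad runs at most 20, so
the default reporting threshold of 25 separates them.  Reported hits are
selected greedily by descending score (leftmost on ties) and never overlap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .intervals import GenomicInterval, GenomeSequence
from .stats import PermutationResult, permutation_enrichment

_G_RUN = re.compile(r"G+")

DEFAULT_MIN_SCORE = 25.0
DEFAULT_MIN_TRACT = 2
DEFAULT_LOOP_RANGE = (1, 30)


@dataclass(frozen=True)
class PQSHit:
    start: int                       # within the scanned sequence
    end: int
    g_tract_lengths: tuple[int, int, int, int]
    loop_lengths: tuple[int, int, int]
    score: float

    @property
    def tetrads(self) -> int:
        return min(self.g_tract_lengths)


def pqs_score(tract_lengths: Sequence[int], loop_lengths: Sequence[int]) -> float:
    tetrads = min(tract_lengths)
    penalty = sum(max(0, loop - 3) for loop in loop_lengths)
    return 20.0 * (tetrads - 1) - penalty


def _candidates(
    sequence: str, min_tract: int, loop_range: tuple[int, int]
) -> list[PQSHit]:
    """Every quadruple of maximal G-runs satisfying the loop bounds."""
    runs = [
        (m.start(), m.end()) for m in _G_RUN.finditer(sequence) if m.end() - m.start() >= min_tract
    ]
    lo, hi = loop_range
    hits: list[PQSHit] = []
    n = len(runs)
    for i in range(n - 3):
        for j in range(i + 1, n - 2):
            l1 = runs[j][0] - runs[i][1]
            if l1 > hi:
                break
            if l1 < lo:
                continue
            for k in range(j + 1, n - 1):
                l2 = runs[k][0] - runs[j][1]
                if l2 > hi:
                    break
                if l2 < lo:
                    continue
                for m in range(k + 1, n):
                    l3 = runs[m][0] - runs[k][1]
                    if l3 > hi:
                        break
                    if l3 < lo:
                        continue
                    tracts = tuple(e - s for s, e in (runs[i], runs[j], runs[k], runs[m]))
                    hits.append(
                        PQSHit(
                            start=runs[i][0],
                            end=runs[m][1],
                            g_tract_lengths=tracts,  # type: ignore[arg-type]
                            loop_lengths=(l1, l2, l3),
                            score=pqs_score(tracts, (l1, l2, l3)),
                        )
                    )
    return hits


def scan_rg4(
    sequence: str,
    min_score: float = DEFAULT_MIN_SCORE,
    min_tract: int = DEFAULT_MIN_TRACT,
    loop_range: tuple[int, int] = DEFAULT_LOOP_RANGE,
) -> list[PQSHit]:
    """Non-overlapping PQS hits with score >= ``min_score``, selected
    greedily by descending score then leftmost position."""
    sequence = sequence.upper()
    cands = [
        h for h in _candidates(sequence, min_tract, loop_range) if h.score >= min_score
    ]
    cands.sort(key=lambda h: (-h.score, h.start, h.end))
    chosen: list[PQSHit] = []
    for cand in cands:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda h: h.start)
    return chosen


def extract_transcript_sequence(
    element: GenomicInterval, genome: GenomeSequence, strand: str | None = None
) -> str:
    """Transcript-sense sequence (DNA alphabet) of an element; minus-strand
    elements are reverse-complemented."""
    strand = strand or element.strand
    iv = GenomicInterval(element.chrom, element.start, element.end, strand, element.name)
    return genome.fetch(iv, stranded=True)


@dataclass
class RG4Label:
    element_id: str
    has_rg4: bool
    n_hits: int
    best_score: float | None
    strand_used: str


def classify_rg4_elements(
    elements: Sequence[GenomicInterval],
    genome: GenomeSequence,
    strand_calls: dict[str, str] | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    min_tract: int = DEFAULT_MIN_TRACT,
    loop_range: tuple[int, int] = DEFAULT_LOOP_RANGE,
) -> list[RG4Label]:
    """Label each element rG4-containing iff its transcript sequence has at
    least one reported hit.  Unstranded elements are scanned on both
    strands and the better-scoring strand kept (flagged via strand_used)."""
    labels = []
    for el in elements:
        eid = el.name or str(el)
        strand = (strand_calls or {}).get(eid, el.strand)
        if strand in "+-":
            variants = [(strand, extract_transcript_sequence(el, genome, strand))]
        else:
            variants = [
                ("+", extract_transcript_sequence(el, genome, "+")),
                ("-", extract_transcript_sequence(el, genome, "-")),
            ]
        best: tuple[str, list[PQSHit]] = (variants[0][0], [])
        for s, seq in variants:
            hits = scan_rg4(seq, min_score, min_tract, loop_range)
            if hits and (
                not best[1] or max(h.score for h in hits) > max(h.score for h in best[1])
            ):
                best = (s, hits)
        hits = best[1]
        labels.append(
            RG4Label(
                element_id=eid,
                has_rg4=bool(hits),
                n_hits=len(hits),
                best_score=max((h.score for h in hits), default=None),
                strand_used=best[0] if strand not in "+-" else strand,
            )
        )
    return labels


def rg4_enrichment(
    observed_count: int,
    null_element_sampler,
    genome: GenomeSequence,
    n_perm: int = 200,
    seed: int = 666,
    min_score: float = DEFAULT_MIN_SCORE,
) -> PermutationResult:
    """Permutation test of the rG4-containing count against same-length
    null placements (their sequences rescanned each draw)."""

    def stat(rng) -> float:
        elements = null_element_sampler(rng)
        labels = classify_rg4_elements(elements, genome, min_score=min_score)
        return sum(l.has_rg4 for l in labels)

    return permutation_enrichment(observed_count, stat, n_perm=n_perm, seed=seed)


def rg4_table(labels: Sequence[RG4Label]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": [l.element_id for l in labels],
            "has_rg4": [l.has_rg4 for l in labels],
            "n_hits": [l.n_hits for l in labels],
            "best_score": [l.best_score for l in labels],
            "strand_used": [l.strand_used for l in labels],
        }
    )
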