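"""Putative-enhancer calling by overlap with known enhancer sets and
permutation enrichment against shuffled nulls."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, overlap_length
from .stats import PermutationResult, permutation_enrichment


@dataclass
class EnhancerCall:
    tcne_id: str
    is_putative_enhancer: bool
    best_overlap_fraction: float
    supporting_sets: list[str] = field(default_factory=list)


def call_putative_enhancers(
    elements: Sequence[GenomicInterval],
    enhancer_sets: dict[str, IntervalSet],
    min_fraction: float = 0.8,
) -> list[EnhancerCall]:
    """An element is a putative enhancer when >= ``min_fraction`` of its
    own length is covered by at least one enhancer source (element-side,
    non-reciprocal; union over sources)."""
    calls = []
    for el in elements:
        best = 0.0
        support = []
        for label, regions in enhancer_sets.items():
            frac = regions.overlap_length(el) / el.length
            best = max(best, frac)
            if frac >= min_fraction:
                support.append(label)
        calls.append(
            EnhancerCall(
                tcne_id=el.name or str(el),
                is_putative_enhancer=bool(support),
                best_overlap_fraction=best,
                supporting_sets=sorted(support),
            )
        )
    return calls


def reciprocal_intersect(
    elements: Sequence[GenomicInterval],
    others: Sequence[GenomicInterval],
    f: float = 0.5,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Pairs overlapping by >= ``f`` of BOTH intervals (intersectBed -f f -r)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for o in others:
        by_chrom.setdefault(o.chrom, []).append(o)
    pairs = []
    for el in elements:
        for o in by_chrom.get(el.chrom, []):
            ov = overlap_length(el, o)
            if ov and ov / el.length >= f and ov / o.length >= f:
                pairs.append((el, o))
    return pairs


def count_enhancer_overlaps(
    elements: Sequence[GenomicInterval],
    enhancer_sets: dict[str, IntervalSet],
    min_fraction: float = 0.8,
) -> int:
    return sum(
        c.is_putative_enhancer
        for c in call_putative_enhancers(elements, enhancer_sets, min_fraction)
    )


def enhancer_enrichment(
    elements: Sequence[GenomicInterval],
    enhancer_sets: dict[str, IntervalSet],
    null_sampler: Callable[[np.random.Generator], list[GenomicInterval]],
    min_fraction: float = 0.8,
    n_perm: int = 1000,
    seed: int = 666,
) -> PermutationResult:
    """Permutation test of the putative-enhancer count against region sets
    drawn from ``null_sampler`` (typically blocklist-aware shuffling)."""
    observed = count_enhancer_overlaps(elements, enhancer_sets, min_fraction)

    def stat(rng: np.random.Generator) -> float:
        return count_enhancer_overlaps(null_sampler(rng), enhancer_sets, min_fraction)

    return permutation_enrichment(observed, stat, n_perm=n_perm, seed=seed)


def calls_table(calls: Sequence[EnhancerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tcne_id": [c.tcne_id for c in calls],
            "is_putative_enhancer": [c.is_putative_enhancer for c in calls],
            "best_overlap_fraction": [c.best_overlap_fraction for c in calls],
            "supporting_sets": [",".join(c.supporting_sets) for c in calls],
        }
    )
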