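"""Shuffled and matched control regions, and signal meta-profiles.

Shuffling mirrors bedtools shuffleBed with same-chromosome placement and an
excluded set: each source element is re-placed uniformly at random on its
own chromosome so that the placed interval avoids every excluded base, by
rejection sampling (default 1000 tries).  The default seed is 666 and every
stochastic entry point takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coverage import SignalTrack
from .genes import GeneModel
from .intervals import GenomicInterval, IntervalSet


class PlacementError(RuntimeError):
    pass


@dataclass
class ControlSet:
    kind: str  # "shuffled" | "matched_intronic" | "matched_intergenic"
    regions: list[GenomicInterval]
    seed: int | None = None
    flagged: list[str] = field(default_factory=list)


def _place_one(
    source: GenomicInterval,
    chrom_size: int,
    excluded: IntervalSet,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> GenomicInterval:
    """Uniform draw over every feasible start position on the chromosome.

    Sampling is exact (complement gaps are enumerated, then a start is
    drawn weighted by feasible width), so a single remaining slot is found
    deterministically; ``max_tries`` is kept for API compatibility only.
    """
    length = source.length
    if length > chrom_size:
        raise PlacementError(f"{source.name or source} longer than its chromosome")
    gaps = IntervalSet([GenomicInterval(source.chrom, 0, chrom_size)]).subtract(excluded)
    s, e = gaps.blocks(source.chrom)
    widths = (e - s) - length + 1
    ok = widths > 0
    if not ok.any():
        raise PlacementError(f"no placement for {source.name or source}")
    cap = np.where(ok, widths, 0)
    cum = np.cumsum(cap)
    pick = int(rng.integers(0, cum[-1]))
    i = int(np.searchsorted(cum, pick, side="right"))
    start = int(s[i] + (pick - (cum[i - 1] if i else 0)))
    return GenomicInterval(source.chrom, start, start + length, source.strand, source.name)


def shuffle_regions(
    sources: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
    excluded: IntervalSet | None = None,
    seed: int = 666,
    max_tries: int = 1000,
) -> ControlSet:
    """Same-chromosome, same-length random re-placement avoiding
    ``excluded``; deterministic given ``seed``."""
    excluded = excluded or IntervalSet()
    rng = np.random.default_rng(seed)
    # complement gaps once per chromosome, then exact weighted draws
    gaps_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {src.chrom for src in sources}:
        gaps = IntervalSet(
            [GenomicInterval(chrom, 0, chrom_sizes[chrom])]
        ).subtract(excluded)
        gaps_by_chrom[chrom] = gaps.blocks(chrom)
    regions = []
    for src in sources:
        s, e = gaps_by_chrom[src.chrom]
        widths = (e - s) - src.length + 1
        cap = np.where(widths > 0, widths, 0)
        if cap.sum() == 0:
            raise PlacementError(f"no placement for {src.name or src}")
        cum = np.cumsum(cap)
        pick = int(rng.integers(0, cum[-1]))
        i = int(np.searchsorted(cum, pick, side="right"))
        start = int(s[i] + (pick - (cum[i - 1] if i else 0)))
        regions.append(
            GenomicInterval(src.chrom, start, start + src.length, src.strand, src.name)
        )
    return ControlSet(kind="shuffled", regions=regions, seed=seed)


def matched_intronic_controls(
    element: GenomicInterval,
    genes: Sequence[GeneModel],
    excluded: IntervalSet,
    window: int = 2000,
) -> list[GenomicInterval]:
    """Intronic space within +-``window`` of an intronic element, minus the
    excluded set (all elements plus the blocklist).  Empty result means the
    element has no usable matched space and is flagged by the caller."""
    lo = max(0, element.start - window)
    hi = element.end + window
    win = GenomicInterval(element.chrom, lo, hi)
    intronic: list[GenomicInterval] = []
    for gene in genes:
        if gene.chrom != element.chrom:
            continue
        for tx in gene.transcripts:
            for intron in tx.introns():
                if intron.start < win.end and intron.end > win.start:
                    intronic.append(
                        GenomicInterval(
                            intron.chrom,
                            max(intron.start, win.start),
                            min(intron.end, win.end),
                        )
                    )
    space = IntervalSet(intronic).subtract(excluded)
    return list(space)


def matched_intergenic_controls(
    element: GenomicInterval,
    chrom_sizes: dict[str, int],
    genic: IntervalSet,
    excluded: IntervalSet,
    seed: int = 666,
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """Same-length random placement restricted to intergenic space on the
    element's chromosome (gene spans are added to the excluded set)."""
    avoid = genic.union(excluded)
    rng = np.random.default_rng(seed)
    return [_place_one(element, chrom_sizes[element.chrom], avoid, rng, max_tries)]


def meta_profile(
    track: SignalTrack,
    regions: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
    flank: int = 1000,
    body_bins: int = 1000,
    mode: str = "length_normalized",
) -> np.ndarray:
    """Average signal profile over a region set.

    ``length_normalized``: per-bp flanks around both edges plus the body
    rescaled to ``body_bins`` bins (per-bin mean), averaged across regions;
    vector length ``flank + body_bins + flank``.

    ``anchor_flanks``: per-bp profiles anchored at the start edge
    (``[start - flank, start + flank)``) and at the end edge, concatenated;
    vector length ``4 * flank``.

    Minus-strand regions are flipped so bin 0 is always the 5' side.
    Flanks running off a chromosome end are clipped and the per-bin
    averaging weights adjusted.
    """
    if not regions:
        raise ValueError("no regions")
    if mode == "length_normalized":
        width = flank + body_bins + flank
    elif mode == "anchor_flanks":
        width = 4 * flank
    else:
        raise ValueError(f"unknown mode {mode!r}")
    acc = np.zeros(width)
    wt = np.zeros(width)

    def window_values(chrom: str, a: int, b: int) -> tuple[np.ndarray, np.ndarray]:
        """values and validity weights over [a, b), clipped to the chromosome"""
        size = chrom_sizes[chrom]
        vals = np.zeros(b - a)
        ok = np.zeros(b - a)
        lo, hi = max(a, 0), min(b, size)
        if hi > lo:
            vals[lo - a : hi - a] = track.values(chrom, lo, hi)
            ok[lo - a : hi - a] = 1.0
        return vals, ok

    for region in regions:
        if mode == "length_normalized":
            upstream, up_ok = window_values(region.chrom, region.start - flank, region.start)
            downstream, dn_ok = window_values(region.chrom, region.end, region.end + flank)
            body = track.values(region.chrom, region.start, region.end)
            # rescale body to body_bins by per-bin mean
            edges = np.linspace(0, len(body), body_bins + 1)
            binned = np.array(
                [
                    body[int(edges[i]) : max(int(edges[i]) + 1, int(edges[i + 1]))].mean()
                    for i in range(body_bins)
                ]
            )
            prof = np.concatenate([upstream, binned, downstream])
            ok = np.concatenate([up_ok, np.ones(body_bins), dn_ok])
        else:
            sv, so = window_values(region.chrom, region.start - flank, region.start + flank)
            ev, eo = window_values(region.chrom, region.end - flank, region.end + flank)
            prof = np.concatenate([sv, ev])
            ok = np.concatenate([so, eo])
        if region.strand == "-":
            prof = prof[::-1]
            ok = ok[::-1]
        acc += prof * ok
        wt += ok
    with np.errstate(invalid="ignore"):
        out = acc / wt
    return np.where(wt > 0, out, 0.0)
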