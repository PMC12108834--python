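"""Genomic interval model and interval algebra.

All coordinates are 0-based, half-open (BED convention) throughout the
package; 1-based formats (GTF, VCF) are converted at the io boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``end > start`` and ``start >= 0`` are enforced; ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # chr6:52,416,350-52,416,570 style without commas
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by ``a`` and ``b`` (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of ``a`` covered by ``b``."""
    return overlap_length(a, b) / a.length


def overlap_passes(
    a: GenomicInterval, b: GenomicInterval, f: float, reciprocal: bool = False
) -> bool:
    """bedtools-style overlap decision: ``>= f`` of ``a`` (and of ``b`` when
    ``reciprocal``) must be covered by the other interval."""
    ov = overlap_length(a, b)
    if ov / a.length < f:
        return False
    if reciprocal and ov / b.length < f:
        return False
    return True


class IntervalSet:
    """Sorted, merged, per-chromosome interval arrays supporting the set
    algebra the filters need (merge, subtract, overlap and containment
    queries).  Construction merges overlapping and bookended input."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            s, e = _merge_pairs(pairs)
            self._starts[chrom] = s
            self._ends[chrom] = e

    @classmethod
    def _from_arrays(cls, arrays: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> "IntervalSet":
        out = cls()
        for chrom, (s, e) in arrays.items():
            if len(s):
                out._starts[chrom] = np.asarray(s, dtype=np.int64)
                out._ends[chrom] = np.asarray(e, dtype=np.int64)
        return out

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def __iter__(self):
        for chrom in self.chroms:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield GenomicInterval(chrom, int(s), int(e))

    def total_bases(self) -> int:
        return int(sum((self._ends[c] - self._starts[c]).sum() for c in self._starts))

    def overlap_length(self, iv: GenomicInterval) -> int:
        """Bases of ``iv`` covered by this set."""
        if iv.chrom not in self._starts:
            return 0
        s = self._starts[iv.chrom]
        e = self._ends[iv.chrom]
        ov = np.minimum(e, iv.end) - np.maximum(s, iv.start)
        return int(ov[ov > 0].sum())

    def overlaps(self, iv: GenomicInterval) -> bool:
        return self.overlap_length(iv) > 0

    def contains(self, iv: GenomicInterval) -> bool:
        """True iff ``iv`` lies entirely inside one merged block."""
        if iv.chrom not in self._starts:
            return False
        s = self._starts[iv.chrom]
        e = self._ends[iv.chrom]
        i = int(np.searchsorted(s, iv.start, side="right")) - 1
        return i >= 0 and e[i] >= iv.end

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Coverage of self minus coverage of ``other``."""
        arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self._starts:
            s, e = self._starts[chrom], self._ends[chrom]
            if chrom not in other._starts:
                arrays[chrom] = (s.copy(), e.copy())
                continue
            os_, oe = other._starts[chrom], other._ends[chrom]
            out_s: list[int] = []
            out_e: list[int] = []
            j = 0
            for a, b in zip(s, e):
                cur = a
                # advance to first excluder possibly overlapping [a, b)
                while j < len(oe) and oe[j] <= a:
                    j += 1
                k = j
                while k < len(os_) and os_[k] < b:
                    if os_[k] > cur:
                        out_s.append(cur)
                        out_e.append(int(os_[k]))
                    cur = max(cur, int(oe[k]))
                    k += 1
                if cur < b:
                    out_s.append(int(cur))
                    out_e.append(int(b))
            arrays[chrom] = (np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64))
        return IntervalSet._from_arrays(arrays)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        ivs = list(self) + list(other)
        return IntervalSet(ivs)

    def intersect_interval(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """The pieces of this set falling inside ``iv``."""
        out: list[GenomicInterval] = []
        if iv.chrom not in self._starts:
            return out
        for s, e in zip(self._starts[iv.chrom], self._ends[iv.chrom]):
            a, b = max(int(s), iv.start), min(int(e), iv.end)
            if b > a:
                out.append(GenomicInterval(iv.chrom, a, b))
        return out

    def blocks(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._starts:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return self._starts[chrom], self._ends[chrom]


def _merge_pairs(pairs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    pairs = sorted(pairs)
    out_s: list[int] = []
    out_e: list[int] = []
    for s, e in pairs:
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def subtract_and_merge(
    intervals: Iterable[GenomicInterval], excluded: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Merge ``intervals`` and remove every base covered by ``excluded``."""
    return list(IntervalSet(intervals).subtract(IntervalSet(excluded)))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Uppercase nucleotide sequences keyed by chromosome."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, iv: GenomicInterval, stranded: bool = False) -> str:
        """Sequence of ``iv``; reverse-complemented when ``stranded`` and
        the interval is on the minus strand."""
        if iv.chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        seq = self.sequences[iv.chrom]
        if iv.end > len(seq):
            raise IndexError(f"{iv} beyond end of {iv.chrom} ({len(seq)} bp)")
        sub = seq[iv.start : iv.end]
        if stranded and iv.strand == "-":
            sub = reverse_complement(sub)
        return sub
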