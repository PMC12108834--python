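"""Blocklist construction and the five-filter TCNE identification pipeline.

A candidate conserved non-coding element (CNE) becomes a transcribed CNE
(TCNE) when it survives, in order:

1. blocklist exclusion (structural RNAs, exons, gene flanks, UTRs, gaps);
2. containment within assembled full-length transcript regions;
3. independent transcription (CAGE signal above a per-track noise floor);
4. aggregate transcription above the normal-fit lower-quantile threshold;
5. recurrence (detected in at least a fraction of samples).

Candidates shorter than ``min_cne_length`` (strictly) never enter the
pipeline; every surviving-or-not candidate is audited with per-filter flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .coverage import (
    SignalTrack,
    TranscriptionThreshold,
    aggregate_tracks,
    fit_transcription_threshold,
    interval_signal,
)
from .genes import GeneModel, TranscriptModel
from .intervals import GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

BLOCKLIST_COMPONENTS = ("structural_rna", "exon", "upstream2k", "downstream1k", "utr", "gap")


@dataclass
class CallerConfig:
    min_cne_length: int = 200          # kept only if length strictly greater
    cage_noise_quantile: float = 0.05  # per-track CAGE noise floor
    detection_fraction: float = 0.05   # recurrence: detected in >= ceil(f * n)
    threshold_quantile: float = 0.05   # lower tail of the normal fit
    trim_fraction: float = 0.1         # per-tail trim of the cross-sample mean
    transform: str = "log2p1"
    upstream_bp: int = 2000
    downstream_bp: int = 1000
    exclude_chroms: tuple[str, ...] = ("chrY", "chrM")
    skip_independence: bool = False  # treat filter 3 as passed (no CAGE data)

    def __post_init__(self) -> None:
        for name in ("cage_noise_quantile", "detection_fraction", "threshold_quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    def min_detected(self, n_samples: int) -> int:
        # epsilon guards float noise in e.g. 0.05 * 20
        return max(1, math.ceil(self.detection_fraction * n_samples - 1e-9))


@dataclass
class Blocklist:
    components: dict[str, list[GenomicInterval]]
    merged: IntervalSet

    def __len__(self) -> int:
        return len(self.merged)


def build_blocklist(
    genes: Sequence[GeneModel],
    structural_rna: Iterable[GenomicInterval] = (),
    utrs: Iterable[GenomicInterval] = (),
    gaps: Iterable[GenomicInterval] = (),
    upstream_bp: int = 2000,
    downstream_bp: int = 1000,
) -> Blocklist:
    """Exons, strand-aware gene flanks (default 2 kb upstream / 1 kb
    downstream), structural RNAs, UTRs and assembly gaps, merged."""
    components: dict[str, list[GenomicInterval]] = {
        "structural_rna": list(structural_rna),
        "exon": [],
        "upstream2k": [],
        "downstream1k": [],
        "utr": list(utrs),
        "gap": list(gaps),
    }
    for gene in genes:
        components["exon"].extend(gene.exons())
        span = gene.span
        if gene.strand == "+":
            up = (span.start - upstream_bp, span.start)
            down = (span.end, span.end + downstream_bp)
        else:
            up = (span.end, span.end + upstream_bp)
            down = (span.start - downstream_bp, span.start)
        for (a, b), label in ((up, "upstream2k"), (down, "downstream1k")):
            if a < 0:
                logger.warning("clipping %s flank of %s to 0", label, gene.gene_id)
                a = 0
            if b > a:
                components[label].append(GenomicInterval(gene.chrom, a, b))
    merged = IntervalSet(iv for ivs in components.values() for iv in ivs)
    return Blocklist(components=components, merged=merged)


@dataclass
class TCNERecord:
    interval: GenomicInterval
    source_cne_id: str
    filter_flags: dict[str, bool] = field(default_factory=dict)
    aggregate_signal: float = 0.0      # transformed mean aggregate signal
    per_sample_signal: list[float] = field(default_factory=list)
    detected_in: int = 0
    strand_call: str = "."

    @property
    def is_tcne(self) -> bool:
        keys = ("blocklist", "containment", "independence", "threshold", "recurrence")
        return all(self.filter_flags.get(k, False) for k in keys)


def filter_length(cnes: Sequence[GenomicInterval], min_length: int = 200) -> list[GenomicInterval]:
    """Keep CNEs strictly longer than ``min_length`` bases."""
    return [c for c in cnes if c.length > min_length]


def filter_blocklist(
    cnes: Sequence[GenomicInterval], blocklist: Blocklist
) -> list[GenomicInterval]:
    """Remove any CNE overlapping the blocklist by >= 1 bp."""
    return [c for c in cnes if not blocklist.merged.overlaps(c)]


def filter_containment(
    cnes: Sequence[GenomicInterval], transcript_regions: IntervalSet
) -> list[GenomicInterval]:
    """Keep CNEs entirely inside the merged assembled-transcript regions."""
    return [c for c in cnes if transcript_regions.contains(c)]


def cage_noise_floors(
    cage_tracks: Sequence[SignalTrack], noise_quantile: float = 0.05
) -> list[float]:
    return [t.positive_quantile(noise_quantile) for t in cage_tracks]


def filter_independence(
    cnes: Sequence[GenomicInterval],
    cage_tracks: Sequence[SignalTrack],
    noise_quantile: float = 0.05,
) -> list[GenomicInterval]:
    """Keep CNEs with CAGE evidence above the per-track noise floor in at
    least one track (>= comparison at the floor)."""
    if not cage_tracks:
        raise ValueError("need at least one CAGE track")
    floors = cage_noise_floors(cage_tracks, noise_quantile)
    kept = []
    for c in cnes:
        for track, floor in zip(cage_tracks, floors):
            if interval_signal(track, c, "max") >= floor:
                kept.append(c)
                break
    return kept


def filter_threshold_and_recurrence(
    cnes: Sequence[GenomicInterval],
    per_sample_tracks: Sequence[SignalTrack],
    threshold: TranscriptionThreshold,
    detection_fraction: float = 0.05,
    records: dict[str, TCNERecord] | None = None,
    aggregate_track: SignalTrack | None = None,
) -> list[GenomicInterval]:
    """Filters 4 and 5.

    Filter 4 keeps elements whose transformed mean aggregate signal is
    >= tau; filter 5 keeps elements detected (per-sample transformed mean
    >= tau, the single global tau) in at least ceil(f * n) samples.
    Audit statistics are written into ``records`` when provided.
    """
    n = len(per_sample_tracks)
    min_detected = max(1, math.ceil(detection_fraction * n - 1e-9))
    kept = []
    for c in cnes:
        rec = records.get(_cne_key(c)) if records is not None else None
        if rec is not None:
            agg = rec.aggregate_signal
        elif aggregate_track is not None:
            agg = float(threshold.transform_values(interval_signal(aggregate_track, c, "mean")))
        else:
            raise ValueError("need either audit records or an aggregate track")
        per_sample = [
            float(threshold.transform_values(interval_signal(t, c, "mean")))
            for t in per_sample_tracks
        ]
        detected = sum(v >= threshold.tau for v in per_sample)
        passes4 = agg >= threshold.tau
        passes5 = detected >= min_detected
        if rec is not None:
            rec.per_sample_signal = per_sample
            rec.detected_in = detected
            rec.filter_flags["threshold"] = passes4
            rec.filter_flags["recurrence"] = passes5
        if passes4 and passes5:
            kept.append(c)
    return kept


def assign_strand(
    records: Sequence[TCNERecord], transcripts: Sequence[TranscriptModel]
) -> None:
    """Strand of the overlapping assembled transcript(s); '.' on conflict
    or no overlap."""
    spans = [t.span for t in transcripts]
    n_orphan = 0
    for rec in records:
        strands = {
            s.strand
            for s in spans
            if s.chrom == rec.interval.chrom
            and s.start < rec.interval.end
            and s.end > rec.interval.start
        }
        if len(strands) == 1:
            rec.strand_call = strands.pop()
        else:
            if not strands:
                n_orphan += 1
            rec.strand_call = "."
    if n_orphan:
        logger.warning("%d elements overlap no assembled transcript; strand '.'", n_orphan)


def _cne_key(c: GenomicInterval) -> str:
    return c.name or str(c)


@dataclass
class CallerResult:
    records: list[TCNERecord]
    threshold: TranscriptionThreshold
    n_samples: int
    config: CallerConfig
    filter_counts: dict[str, int] = field(default_factory=dict)

    @property
    def tcnes(self) -> list[TCNERecord]:
        return [r for r in self.records if r.is_tcne]

    def audit_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "cne_id": r.source_cne_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "length": r.interval.length,
                "strand_call": r.strand_call,
                "aggregate_signal": r.aggregate_signal,
                "detected_in": r.detected_in,
                "is_tcne": r.is_tcne,
            }
            for k in ("blocklist", "containment", "independence", "threshold", "recurrence"):
                row[f"pass_{k}"] = r.filter_flags.get(k, False)
            rows.append(row)
        return pd.DataFrame(rows)


def run_caller(
    cnes: Sequence[GenomicInterval],
    blocklist: Blocklist,
    transcript_regions: IntervalSet,
    cage_tracks: Sequence[SignalTrack],
    sample_tracks: Sequence[SignalTrack],
    config: CallerConfig | None = None,
    transcripts: Sequence[TranscriptModel] = (),
) -> CallerResult:
    """Run the full five-filter pipeline and return audited records.

    All five flags are evaluated for every length-passing candidate so the
    audit is complete; the transcription threshold is fitted on the
    candidates surviving filters 1-3 (configurable population would fit all
    candidates instead, but the downstream gate is the same).
    """
    config = config or CallerConfig()
    cnes = [c for c in cnes if c.chrom not in config.exclude_chroms]
    cnes = filter_length(cnes, config.min_cne_length)
    cnes = sorted(cnes, key=lambda c: (c.chrom, c.start, c.end))

    records = {
        _cne_key(c): TCNERecord(interval=c, source_cne_id=_cne_key(c)) for c in cnes
    }
    aggregate = aggregate_tracks(sample_tracks, config.trim_fraction)

    pass1 = set(map(_cne_key, filter_blocklist(cnes, blocklist)))
    pass2 = set(map(_cne_key, filter_containment(cnes, transcript_regions)))
    if config.skip_independence:
        pass3 = set(records)
    else:
        pass3 = set(
            map(_cne_key, filter_independence(cnes, cage_tracks, config.cage_noise_quantile))
        )
    for key, rec in records.items():
        rec.filter_flags["blocklist"] = key in pass1
        rec.filter_flags["containment"] = key in pass2
        rec.filter_flags["independence"] = key in pass3

    # threshold population: candidates surviving filters 1-3
    survivors = [c for c in cnes if _cne_key(c) in (pass1 & pass2 & pass3)]
    raw_means = {_cne_key(c): interval_signal(aggregate.track, c, "mean") for c in cnes}
    if len(survivors) >= 2:
        threshold = fit_transcription_threshold(
            [raw_means[_cne_key(c)] for c in survivors],
            quantile=config.threshold_quantile,
            transform=config.transform,
        )
    else:
        logger.warning("fewer than 2 candidates after filter 3; threshold from all candidates")
        threshold = fit_transcription_threshold(
            [raw_means[k] for k in records] or [0.0, 0.0],
            quantile=config.threshold_quantile,
            transform=config.transform,
        )
    for key, rec in records.items():
        rec.aggregate_signal = float(threshold.transform_values(raw_means[key]))

    filter_threshold_and_recurrence(
        cnes, sample_tracks, threshold, config.detection_fraction, records=records
    )
    record_list = list(records.values())
    assign_strand(record_list, transcripts)

    counts = {
        "candidates": len(cnes),
        "pass_blocklist": len(pass1),
        "pass_containment": len(pass2),
        "pass_independence": len(pass3),
        "pass_all": sum(r.is_tcne for r in record_list),
    }
    return CallerResult(
        records=record_list,
        threshold=threshold,
        n_samples=len(sample_tracks),
        config=config,
        filter_counts=counts,
    )
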