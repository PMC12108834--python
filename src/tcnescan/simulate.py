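"""Self-contained synthetic datasets with known ground truth for every
pipeline stage.

The generator emulates the study conditions at desk scale: a toy genome
(default 2 chromosomes x 1 Mb) carrying multi-exon genes on both strands,
candidate conserved elements planted in introns and intergenic space with
lengths 201-800 bp, per-sample RNA-seq coverage in which transcribed
elements are elevated by a signal-to-noise ratio (default 10) in a
controlled fraction of samples, CAGE TSS spikes at the 5' ends of
independently transcribed elements, correlated element/gene expression for
planted regulatory links, copy-number-corrupted null links, and SNVs whose
trinucleotide contexts follow a recorded signature mixture.

Every planted element carries the per-filter outcome expected under the
default caller configuration, serialized to ``truth.json`` next to the
fixture files; all randomness flows from one integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .coverage import SignalTrack
from .genes import GeneModel, TranscriptModel
from .intervals import GenomicInterval, GenomeSequence, IntervalSet, reverse_complement
from .variants import VariantRecord, synthetic_signature_matrix

# planted element categories and their default shares of n_cnes
CATEGORY_FRACTIONS = {
    "pass_intronic": 0.40,
    "pass_intergenic": 0.10,
    "fail_blocklist": 0.10,
    "fail_containment": 0.10,
    "fail_independence": 0.10,
    "fail_threshold": 0.10,
    "short": 0.10,
}

# expected five-filter flags per category under the default caller config
EXPECTED_FLAGS = {
    "pass_intronic": dict(blocklist=True, containment=True, independence=True,
                          threshold=True, recurrence=True),
    "pass_intergenic": dict(blocklist=True, containment=True, independence=True,
                            threshold=True, recurrence=True),
    "fail_blocklist": dict(blocklist=False, containment=True, independence=True,
                           threshold=True, recurrence=True),
    "fail_containment": dict(blocklist=True, containment=False, independence=True,
                             threshold=True, recurrence=True),
    "fail_independence": dict(blocklist=True, containment=True, independence=False,
                              threshold=True, recurrence=True),
    "fail_threshold": dict(blocklist=True, containment=True, independence=True,
                           threshold=False, recurrence=False),
}

RG4_CASSETTE = "GGGAGGGAGGGAGGG"  # three tetrads, 1-nt loops: score 40

_BG_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BG_PROBS = (0.38, 0.12, 0.12, 0.38)  # AT-rich background


@dataclass
class PlantedElement:
    element_id: str
    interval: GenomicInterval
    category: str
    host_strand: str            # strand of the covering transcript ('.' if none)
    expect: dict[str, bool]
    rg4: bool = False
    enhancer: bool = False
    host_gene_id: str | None = None

    @property
    def must_pass(self) -> bool:
        return self.category.startswith("pass")


@dataclass
class PlantedLink:
    tcne_id: str
    gene_id: str
    kind: str                   # "true" | "cna_null"
    rho_target: float


@dataclass
class Fixture:
    seed: int
    chrom_sizes: dict[str, int]
    genome: GenomeSequence
    genes: list[GeneModel]
    noncoding_transcripts: list[TranscriptModel]
    elements: list[PlantedElement]
    gaps: list[GenomicInterval] = field(default_factory=list)
    enhancer_sets: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    links: list[PlantedLink] = field(default_factory=list)
    corrupted_samples: list[str] = field(default_factory=list)
    variant_truth: dict = field(default_factory=dict)

    # -- derived views ------------------------------------------------

    def cnes(self) -> list[GenomicInterval]:
        return [e.interval for e in self.elements]

    def all_transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes for t in g.transcripts] + list(
            self.noncoding_transcripts
        )

    def transcript_regions(self) -> IntervalSet:
        return IntervalSet(t.span for t in self.all_transcripts())

    def noncoding_space(self) -> IntervalSet:
        """Transcribed space minus exons of coding genes (hosts the variant
        permutation null)."""
        exons = IntervalSet(e for g in self.genes for e in g.exons())
        return self.transcript_regions().subtract(exons)

    def truth_by_id(self) -> dict[str, PlantedElement]:
        return {e.element_id: e for e in self.elements}

    # -- serialization ------------------------------------------------

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_fasta(self.genome, outdir / "genome.fa")
        tio.write_gtf(self.genes, outdir / "genes.gtf")
        nc = [
            GeneModel(t.transcript_id, t.chrom, t.strand, [t])
            for t in self.noncoding_transcripts
        ]
        tio.write_gtf(nc, outdir / "noncoding_transcripts.gtf")
        tio.write_bed(
            [t.span for t in self.all_transcripts()], outdir / "transcripts.bed"
        )
        tio.write_bed(self.cnes(), outdir / "cnes.bed")
        for label, regions in self.enhancer_sets.items():
            tio.write_bed(regions, outdir / f"enhancers.{label}.bed")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth_dict(), fh, indent=1, sort_keys=True)

    def truth_dict(self) -> dict:
        return {
            "seed": self.seed,
            "chrom_sizes": self.chrom_sizes,
            "elements": {
                e.element_id: {
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "category": e.category,
                    "host_strand": e.host_strand,
                    "expect": e.expect,
                    "must_pass": e.must_pass,
                    "rg4": e.rg4,
                    "enhancer": e.enhancer,
                    "host_gene_id": e.host_gene_id,
                }
                for e in self.elements
            },
            "links": [
                {"tcne_id": l.tcne_id, "gene_id": l.gene_id, "kind": l.kind,
                 "rho_target": l.rho_target}
                for l in self.links
            ],
            "corrupted_samples": self.corrupted_samples,
            "variants": self.variant_truth,
        }


# --------------------------------------------------------------------
# genome


def _random_background(rng: np.random.Generator, length: int) -> bytearray:
    idx = rng.choice(4, size=length, p=_BG_PROBS)
    return bytearray(_BG_BASES[idx].tobytes())


def _make_gene(
    gene_id: str, chrom: str, start: int, strand: str, rng: np.random.Generator
) -> GeneModel:
    n_exons = int(rng.integers(4, 7))
    exons = []
    pos = start
    for i in range(n_exons):
        exon_len = int(rng.integers(150, 301))
        exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
        pos += exon_len
        if i < n_exons - 1:
            pos += int(rng.integers(3000, 6001))
    tx = TranscriptModel(f"{gene_id}.t1", chrom, strand, exons)
    transcripts = [tx]
    if rng.random() < 0.25 and n_exons >= 4:
        # a shorter second isoform (prefix of the exon chain)
        sub = exons[: n_exons - 2]
        transcripts.append(TranscriptModel(f"{gene_id}.t2", chrom, strand, list(sub)))
    return GeneModel(gene_id, chrom, strand, transcripts)


class PackingError(RuntimeError):
    pass


def simulate_genome(
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    n_genes: int = 40,
    n_cnes: int = 300,
    seed: int = 666,
    make_sequence: bool = True,
    category_fractions: dict[str, float] | None = None,
) -> Fixture:
    """Toy genome with planted candidate elements of every category.

    Gene bodies alternate with intergenic gaps; most elements sit in
    introns, a designated subset overlaps exons (must fail the blocklist
    filter) or lies outside any assembled transcript (must fail the
    containment filter).  Half of the must-pass elements carry a planted
    G-quadruplex cassette on the transcript sense; background sequence is
    AT-rich.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    fractions = dict(category_fractions or CATEGORY_FRACTIONS)
    counts = {cat: int(round(f * n_cnes)) for cat, f in fractions.items()}
    # rounding drift goes to the biggest category
    drift = n_cnes - sum(counts.values())
    if counts:
        counts[max(counts, key=counts.get)] += drift

    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    chrom_sizes = {c: chrom_length for c in chroms}
    genes: list[GeneModel] = []
    intergenic_slots: list[GenomicInterval] = []
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    for ci, chrom in enumerate(chroms):
        pos = 10_000
        for gi in range(per_chrom[ci]):
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _make_gene(f"G{ci}_{gi:03d}", chrom, pos, strand, rng)
            span = gene.span
            if span.end + 4000 > chrom_length:
                raise PackingError(f"genes do not fit on {chrom}")
            genes.append(gene)
            gap = int(rng.integers(9_000, 14_001))
            # usable intergenic slot: clear of 2 kb up / 1 kb down flanks
            slot_lo = span.end + 3_100
            slot_hi = span.end + gap - 3_100
            if slot_hi - slot_lo > 1_500:
                intergenic_slots.append(GenomicInterval(chrom, slot_lo, slot_hi))
            pos = span.end + gap
        if pos > chrom_length:
            raise PackingError(f"genes overflow {chrom}")

    # intron inventory (representative transcript, genome order), with margins
    intron_slots: list[dict] = []
    for gene in genes:
        for intron in sorted(gene.representative_transcript().introns(),
                             key=lambda i: i.start):
            intron_slots.append(
                {"gene": gene, "intron": intron,
                 "cursor": intron.start + 100, "end": intron.end - 100}
            )

    def place_intronic(length: int) -> tuple[GeneModel, GenomicInterval] | None:
        order = rng.permutation(len(intron_slots))
        for i in order:
            slot = intron_slots[int(i)]
            start = slot["cursor"]
            if start + length <= slot["end"]:
                slot["cursor"] = start + length + 300
                return slot["gene"], GenomicInterval(
                    slot["intron"].chrom, start, start + length
                )
        return None

    def reserve_intron_tail(gene: GeneModel, exon_start: int, length: int) -> None:
        """Shrink the slot of the intron ending at ``exon_start`` so later
        intronic placements cannot collide with an exon-overlapping element."""
        for slot in intron_slots:
            if slot["gene"] is gene and slot["intron"].end == exon_start:
                slot["end"] = min(slot["end"], exon_start - length - 100)
                return

    inter_cursor = {id(s): s.start for s in intergenic_slots}

    def place_intergenic(length: int, margin: int = 600) -> GenomicInterval | None:
        order = rng.permutation(len(intergenic_slots))
        for i in order:
            slot = intergenic_slots[int(i)]
            start = inter_cursor[id(slot)]
            if start + length + margin <= slot.end:
                inter_cursor[id(slot)] = start + length + margin
                return GenomicInterval(slot.chrom, start, start + length)
        return None

    elements: list[PlantedElement] = []
    noncoding: list[TranscriptModel] = []
    eid = 0

    def new_id() -> str:
        nonlocal eid
        eid += 1
        return f"CNE{eid:04d}"

    def elem_length() -> int:
        return int(rng.integers(201, 801))

    order_of_categories = [
        "fail_blocklist", "pass_intronic", "fail_independence", "fail_threshold",
        "pass_intergenic", "fail_containment", "short",
    ]
    block_gene_cycle = 0
    for cat in order_of_categories:
        for _ in range(counts.get(cat, 0)):
            el_id = new_id()
            if cat in ("pass_intronic", "fail_independence", "fail_threshold"):
                placed = place_intronic(elem_length())
                if placed is None:
                    raise PackingError("ran out of intronic space")
                gene, iv = placed
                elements.append(
                    PlantedElement(el_id, GenomicInterval(iv.chrom, iv.start, iv.end,
                                                          name=el_id),
                                   cat, gene.strand, dict(EXPECTED_FLAGS[cat]),
                                   host_gene_id=gene.gene_id)
                )
            elif cat in ("pass_intergenic", "fail_containment"):
                iv = place_intergenic(elem_length())
                if iv is None:
                    raise PackingError("ran out of intergenic space")
                strand = "+" if rng.random() < 0.5 else "-"
                if cat == "pass_intergenic":
                    # covering single-exon non-coding transcript
                    tx = TranscriptModel(
                        f"NC_{el_id}", iv.chrom, strand,
                        [GenomicInterval(iv.chrom, iv.start - 200, iv.end + 200, strand)],
                    )
                    noncoding.append(tx)
                    host = strand
                else:
                    host = "."
                elements.append(
                    PlantedElement(el_id, GenomicInterval(iv.chrom, iv.start, iv.end,
                                                          name=el_id),
                                   cat, host, dict(EXPECTED_FLAGS[cat]))
                )
            elif cat == "fail_blocklist":
                # overlap an internal exon by ~50 bp, reserving the intron tail
                gene = genes[block_gene_cycle % len(genes)]
                block_gene_cycle += 1
                tx = gene.representative_transcript()
                exon = tx.exons[1 + (block_gene_cycle // len(genes)) % (len(tx.exons) - 2)]
                length = elem_length()
                iv = GenomicInterval(gene.chrom, exon.start - (length - 50),
                                     exon.start + 50, name=el_id)
                reserve_intron_tail(gene, exon.start, length)
                elements.append(
                    PlantedElement(el_id, iv, cat, gene.strand,
                                   dict(EXPECTED_FLAGS[cat]), host_gene_id=gene.gene_id)
                )
            elif cat == "short":
                placed = place_intronic(int(rng.integers(120, 200)))
                if placed is None:
                    raise PackingError("ran out of intronic space")
                gene, iv = placed
                elements.append(
                    PlantedElement(el_id, GenomicInterval(iv.chrom, iv.start, iv.end,
                                                          name=el_id),
                                   cat, gene.strand, {}, host_gene_id=gene.gene_id)
                )

    # rG4 cassettes on half the must-pass elements
    passers = [e for e in elements if e.must_pass]
    for i, el in enumerate(passers):
        el.rg4 = i % 2 == 0

    # known-enhancer annotation: 30% of must-pass elements fully covered,
    # a further 20% only half covered (below the 0.8 calling fraction)
    enh_regions: list[GenomicInterval] = []
    for i, el in enumerate(passers):
        iv = el.interval
        if i % 10 < 3:
            el.enhancer = True
            enh_regions.append(GenomicInterval(iv.chrom, iv.start - 20, iv.end + 20))
        elif i % 10 < 5:
            enh_regions.append(
                GenomicInterval(iv.chrom, iv.start, iv.start + iv.length // 2)
            )
    # decoy enhancers in leftover intergenic space
    for _ in range(20):
        iv = place_intergenic(400, margin=200)
        if iv is not None:
            enh_regions.append(iv)

    genome = GenomeSequence({})
    if make_sequence:
        seqs: dict[str, bytearray] = {
            c: _random_background(rng, chrom_length) for c in chroms
        }
        for el in elements:
            if not el.rg4:
                continue
            cassette = RG4_CASSETTE
            strand = el.host_strand if el.host_strand in "+-" else "+"
            if strand == "-":
                cassette = reverse_complement(cassette)
            mid = el.interval.midpoint
            seqs[el.interval.chrom][mid : mid + len(cassette)] = cassette.encode()
        genome = GenomeSequence({c: s.decode() for c, s in seqs.items()})

    fixture = Fixture(
        seed=seed,
        chrom_sizes=chrom_sizes,
        genome=genome,
        genes=genes,
        noncoding_transcripts=noncoding,
        elements=elements,
        enhancer_sets={"synthetic_enhancers": enh_regions},
    )
    _plant_links(fixture, rng)
    return fixture


def _plant_links(fixture: Fixture, rng: np.random.Generator) -> None:
    """Choose planted regulatory links: true monotone links between
    must-pass intronic elements and their host genes, plus designated
    copy-number-corrupted null pairs."""
    intronic = [e for e in fixture.elements
                if e.category == "pass_intronic" and e.host_gene_id]
    rng.shuffle(intronic)
    # one link per gene and per element: expression rows are rewritten per
    # planted link, so sharing a gene would overwrite an earlier link
    seen_genes: set[str] = set()
    unique: list[PlantedElement] = []
    for el in intronic:
        if el.host_gene_id not in seen_genes:
            seen_genes.add(el.host_gene_id)
            unique.append(el)
    n_true = min(30, max(1, 2 * len(unique) // 3)) if unique else 0
    n_null = min(6, len(unique) - n_true) if len(unique) > n_true else 0
    for el in unique[:n_true]:
        fixture.links.append(PlantedLink(el.element_id, el.host_gene_id, "true", 0.9))
    for el in unique[n_true : n_true + n_null]:
        fixture.links.append(PlantedLink(el.element_id, el.host_gene_id, "cna_null", 0.0))


# --------------------------------------------------------------------
# coverage


@dataclass
class CoverageBundle:
    sample_tracks: list[SignalTrack]
    cage_tracks: list[SignalTrack]
    detected_samples: dict[str, list[int]]  # element id -> boosted sample indices

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for t in self.sample_tracks:
            tio.write_bedgraph(t, outdir / f"coverage.{t.sample_id}.bedgraph")
        for t in self.cage_tracks:
            tio.write_bedgraph(t, outdir / f"cage.{t.sample_id}.bedgraph")


def simulate_coverage(
    fixture: Fixture,
    n_samples: int = 20,
    depth: float = 2.0,
    snr: float = 10.0,
    detected_fraction: float = 0.8,
    detected_fraction_per_element: dict[str, float] | None = None,
    n_cage_tracks: int = 3,
    block: int = 50,
    seed: int | None = None,
) -> CoverageBundle:
    """Per-sample RNA-seq BedGraph coverage plus CAGE tracks.

    Background coverage is Poisson read-count noise (mean ``depth`` per
    base, piecewise constant over ``block``-bp windows) over transcribed
    regions; transcribed elements gain an additional Poisson component of
    mean ``snr * depth`` in a ``detected_fraction`` of samples.  CAGE
    spikes are written at the 5' ends of independence-positive elements
    only, on top of sparse positive background outside all elements.
    """
    rng = np.random.default_rng(fixture.seed + 1 if seed is None else seed)
    overrides = detected_fraction_per_element or {}

    boosted_cats = {
        "pass_intronic", "pass_intergenic", "fail_blocklist", "fail_containment",
        "fail_independence",
    }
    boosted: dict[str, list[int]] = {}
    for el in fixture.elements:
        frac = overrides.get(el.element_id,
                             detected_fraction if el.category in boosted_cats else 0.0)
        k = int(round(frac * n_samples))
        idx = sorted(rng.choice(n_samples, size=k, replace=False).tolist()) if k else []
        boosted[el.element_id] = idx

    # coverage universe: transcript regions plus any planted element space
    universe = fixture.transcript_regions().union(IntervalSet(fixture.cnes()))
    el_by_chrom: dict[str, list[PlantedElement]] = {}
    for el in fixture.elements:
        el_by_chrom.setdefault(el.interval.chrom, []).append(el)

    # shared segmentation: block grid cut at element boundaries
    segments: list[tuple[str, int, int, list[str]]] = []
    for region in universe:
        cuts = set(range(region.start, region.end, block))
        cuts.add(region.end)
        for el in el_by_chrom.get(region.chrom, []):
            iv = el.interval
            if iv.start < region.end and iv.end > region.start:
                cuts.add(max(iv.start, region.start))
                cuts.add(min(iv.end, region.end))
        bounds = sorted(cuts)
        for a, b in zip(bounds, bounds[1:]):
            owners = [
                el.element_id
                for el in el_by_chrom.get(region.chrom, [])
                if el.interval.start <= a and b <= el.interval.end
            ]
            segments.append((region.chrom, a, b, owners))

    widths = np.array([b - a for _, a, b, _ in segments], dtype=float)
    sample_tracks: list[SignalTrack] = []
    for si in range(n_samples):
        bg = rng.poisson(depth * widths) / widths
        boost = np.zeros_like(bg)
        for gi, (_, a, b, owners) in enumerate(segments):
            for owner in owners:
                if si in boosted[owner]:
                    boost[gi] += rng.poisson(snr * depth * widths[gi]) / widths[gi]
        values = bg + boost
        runs = [
            (seg[0], seg[1], seg[2], float(v))
            for seg, v in zip(segments, values)
            if v > 0
        ]
        sample_tracks.append(SignalTrack.from_runs(runs, sample_id=f"S{si:03d}"))

    cage_tracks = _simulate_cage(fixture, rng, n_cage_tracks)
    return CoverageBundle(sample_tracks, cage_tracks, boosted)


def _simulate_cage(
    fixture: Fixture, rng: np.random.Generator, n_tracks: int
) -> list[SignalTrack]:
    spike_cats = {
        "pass_intronic", "pass_intergenic", "fail_blocklist", "fail_containment",
        "fail_threshold",
    }
    element_space = IntervalSet(fixture.cnes())
    regions = list(fixture.transcript_regions())
    tracks = []
    for ti in range(n_tracks):
        runs: list[tuple[str, int, int, float]] = []
        # sparse positive background outside all elements
        for _ in range(400):
            region = regions[int(rng.integers(0, len(regions)))]
            pos = int(rng.integers(region.start, region.end))
            iv = GenomicInterval(region.chrom, pos, pos + 1)
            if not element_space.overlaps(iv):
                runs.append((region.chrom, pos, pos + 1, float(rng.integers(1, 11))))
        for el in fixture.elements:
            if el.category not in spike_cats:
                continue
            iv = el.interval
            if el.host_strand == "-":
                a, b = iv.end - 5, iv.end
            else:
                a, b = iv.start, iv.start + 5
            runs.append((iv.chrom, a, b, float(rng.integers(30, 81))))
        # deduplicate colliding background positions
        seen: dict[tuple[str, int], tuple[str, int, int, float]] = {}
        for r in runs:
            seen[(r[0], r[1])] = r
        tracks.append(
            SignalTrack.from_runs(seen.values(), sample_id=f"CAGE{ti}")
        )
    return tracks


# --------------------------------------------------------------------
# expression + copy number


@dataclass
class ExpressionBundle:
    tcne_expr: pd.DataFrame      # element x sample
    gene_expr: pd.DataFrame      # gene x sample
    cna_frame: pd.DataFrame      # sample, chrom, start, end, log2_segment_mean

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_tsv(self.tcne_expr.reset_index(names="tcne_id"),
                      outdir / "tcne_expression.tsv")
        tio.write_tsv(self.gene_expr.reset_index(names="gene_id"),
                      outdir / "gene_expression.tsv")
        tio.write_tsv(self.cna_frame, outdir / "cna_segments.tsv")


def _spearman_to_pearson(rho_s: float) -> float:
    """Latent bivariate-normal correlation giving the target Spearman."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def simulate_expression(
    fixture: Fixture,
    n_samples: int = 200,
    rho_target: float = 0.9,
    corrupted_fraction: float = 0.5,
    cna_log2: float = 2.0,
    seed: int | None = None,
) -> ExpressionBundle:
    """Element and gene expression matrices plus copy-number segments.

    Planted "true" links share a latent bivariate normal calibrated so the
    observed Spearman correlation is approximately ``rho_target``;
    "cna_null" links are independent at baseline but a corrupted half of
    the cohort receives co-amplified expression spikes together with
    |log2 segment mean| = ``cna_log2`` segments at both loci, so the pair
    passes the correlation gate only when the copy-number filter is off.
    """
    rng = np.random.default_rng(fixture.seed + 2 if seed is None else seed)
    samples = [f"P{si:03d}" for si in range(n_samples)]
    elements = [e for e in fixture.elements if e.must_pass]
    genes = fixture.genes
    tcne_expr = pd.DataFrame(
        np.exp(rng.normal(2.0, 1.0, size=(len(elements), n_samples))),
        index=[e.element_id for e in elements], columns=samples,
    )
    gene_expr = pd.DataFrame(
        np.exp(rng.normal(4.0, 1.0, size=(len(genes), n_samples))),
        index=[g.gene_id for g in genes], columns=samples,
    )
    rho_l = _spearman_to_pearson(rho_target)
    for link in fixture.links:
        if link.kind != "true":
            continue
        z1 = rng.normal(size=n_samples)
        z2 = rho_l * z1 + np.sqrt(1 - rho_l**2) * rng.normal(size=n_samples)
        tcne_expr.loc[link.tcne_id] = np.exp(2.0 + z1)
        gene_expr.loc[link.gene_id] = np.exp(4.0 + z2)

    n_corr = int(round(corrupted_fraction * n_samples))
    corrupted = sorted(rng.choice(n_samples, size=n_corr, replace=False).tolist())
    corrupted_ids = [samples[i] for i in corrupted]
    cna_rows: list[dict] = []
    gene_by_id = {g.gene_id: g for g in genes}
    el_by_id = {e.element_id: e for e in fixture.elements}
    null_windows: list[tuple[str, int, int]] = []
    for link in fixture.links:
        if link.kind != "cna_null":
            continue
        gene = gene_by_id[link.gene_id]
        el = el_by_id[link.tcne_id]
        # co-amplified, perfectly concordant spikes in the corrupted half
        u = rng.random(n_corr)
        tcne_expr.loc[link.tcne_id, corrupted_ids] = np.exp(8.0 + u)
        gene_expr.loc[link.gene_id, corrupted_ids] = np.exp(9.0 + 2.0 * u)
        lo = min(el.interval.midpoint, gene.span.start) - 1000
        hi = max(el.interval.midpoint, gene.span.end) + 1000
        null_windows.append((el.interval.chrom, max(0, lo), hi))

    for sample in samples:
        is_corr = sample in set(corrupted_ids)
        for chrom, size in fixture.chrom_sizes.items():
            windows = [w for w in null_windows if w[0] == chrom] if is_corr else []
            windows = sorted(set(windows), key=lambda w: w[1])
            pos = 0
            for _, lo, hi in windows:
                lo, hi = max(pos, lo), min(size, hi)
                if lo > pos:
                    cna_rows.append(dict(sample=sample, chrom=chrom, start=pos,
                                         end=lo, log2_segment_mean=0.0))
                if hi > lo:
                    cna_rows.append(dict(sample=sample, chrom=chrom, start=lo,
                                         end=hi, log2_segment_mean=cna_log2))
                pos = max(pos, hi)
            if pos < size:
                cna_rows.append(dict(sample=sample, chrom=chrom, start=pos,
                                     end=size, log2_segment_mean=0.0))

    fixture.corrupted_samples = corrupted_ids
    return ExpressionBundle(tcne_expr, gene_expr, pd.DataFrame(cna_rows))


# --------------------------------------------------------------------
# variants


def simulate_variants(
    fixture: Fixture,
    n_variants: int = 400,
    inside_fraction: float = 0.5,
    signature_weights: dict[str, float] | None = None,
    reference: pd.DataFrame | None = None,
    indel_fraction: float = 0.05,
    seed: int | None = None,
) -> list[VariantRecord]:
    """SNVs (genome-consistent reference base) and a few indels.

    ``inside_fraction`` of the variants land inside must-pass elements, the
    rest uniformly in non-coding transcribed space; SNV trinucleotide
    contexts are drawn from ``signature_weights`` over the ``reference``
    signature matrix (recorded in the fixture truth for refit checks).
    """
    rng = np.random.default_rng(fixture.seed + 3 if seed is None else seed)
    if reference is None:
        reference = synthetic_signature_matrix(n_signatures=5, seed=11)
    if signature_weights is None:
        signature_weights = {reference.columns[0]: 0.7, reference.columns[1]: 0.3}
    weights = np.array([signature_weights.get(c, 0.0) for c in reference.columns])
    weights = weights / weights.sum()
    class_probs = (reference.to_numpy() * weights).sum(axis=1)
    class_probs = class_probs / class_probs.sum()
    contexts = list(reference.index)

    inside_space = IntervalSet(e.interval for e in fixture.elements if e.must_pass)
    outside_space = fixture.noncoding_space().subtract(
        IntervalSet(fixture.cnes())
    )
    pools = {
        "inside": _context_positions(fixture.genome, inside_space),
        "outside": _context_positions(fixture.genome, outside_space),
    }
    variants: list[VariantRecord] = []
    n_indels = int(round(indel_fraction * n_variants))
    n_snvs = n_variants - n_indels
    for _ in range(n_snvs):
        where = "inside" if rng.random() < inside_fraction else "outside"
        pool = pools[where]
        for _try in range(100):
            label = contexts[int(rng.choice(96, p=class_probs))]
            tri, alt = _label_parts(label)
            candidates = pool.get(tri, [])
            rc = False
            if not candidates:
                candidates = pool.get(reverse_complement(tri), [])
                rc = True
            if candidates:
                chrom, pos = candidates[int(rng.integers(0, len(candidates)))]
                ref = fixture.genome.sequences[chrom][pos]
                a = reverse_complement(alt) if rc else alt
                variants.append(VariantRecord(chrom, pos, ref, a))
                break
    space = list(outside_space)
    for _ in range(n_indels):
        region = space[int(rng.integers(0, len(space)))]
        pos = int(rng.integers(region.start, region.end - 3))
        ref = fixture.genome.sequences[region.chrom][pos : pos + 3]
        variants.append(VariantRecord(region.chrom, pos, ref, ref[0]))  # deletion
    fixture.variant_truth = {
        "n_variants": len(variants),
        "inside_fraction": inside_fraction,
        "signature_weights": {k: float(v) for k, v in
                              zip(reference.columns, weights)},
    }
    return variants


def _label_parts(label: str) -> tuple[str, str]:
    # "A[C>T]G" -> ("ACG", "T")
    five, rest = label[0], label[2:]
    ref, alt = rest[0], rest[2]
    three = label[-1]
    return f"{five}{ref}{three}", alt


def _context_positions(
    genome: GenomeSequence, space: IntervalSet
) -> dict[str, list[tuple[str, int]]]:
    """Trinucleotide -> candidate SNV positions (center base) inside a space."""
    pools: dict[str, list[tuple[str, int]]] = {}
    for region in space:
        seq = genome.sequences.get(region.chrom)
        if seq is None:
            continue
        lo = max(region.start, 1)
        hi = min(region.end, len(seq) - 1)
        for pos in range(lo, hi):
            tri = seq[pos - 1 : pos + 2]
            if "N" in tri:
                continue
            pools.setdefault(tri, []).append((region.chrom, pos))
    return pools


def write_variants_tsv(variants: Sequence[VariantRecord], path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
        }
    )
    tio.write_tsv(df, path)
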