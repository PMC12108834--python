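"""Variant-element intersection, permutation enrichment inside non-coding
transcribed space, multi-element gene shortlisting, and mutational-signature
refitting on the 96 trinucleotide contexts.

SNVs are binned in the pyrimidine frame: a substitution at a purine
reference base is reverse-complemented (with its flanks) before being
assigned to one of the 96 (5' base, C/T ref, alt, 3' base) classes, the
convention used by COSMIC-style signature matrices.  Refitting is
non-negative least squares with the small-weight drop-and-refit rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .intervals import GenomicInterval, GenomeSequence, IntervalSet, reverse_complement
from .stats import PermutationResult, permutation_enrichment

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: canonical 96-context labels, e.g. "A[C>A]A", grouped by substitution
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in _BASES for three in _BASES
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 0-based position of the first reference base
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + max(1, len(self.ref)))


def read_variant_table(df: pd.DataFrame, one_based: bool = False) -> list[VariantRecord]:
    """Columns: chrom, pos, ref, alt.  ``one_based=True`` for VCF-style
    coordinates (converted to 0-based here)."""
    off = 1 if one_based else 0
    return [
        VariantRecord(str(r.chrom), int(r.pos) - off, str(r.ref).upper(), str(r.alt).upper())
        for r in df.itertuples(index=False)
    ]


def read_vcf(path) -> list[VariantRecord]:
    """Sites-only plain-text VCF; multiallelic records become one variant
    per ALT allele."""
    out: list[VariantRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alts = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            for alt in alts.split(","):
                out.append(VariantRecord(chrom, pos - 1, ref.upper(), alt.upper()))
    return out


def intersect_variants(
    variants: Sequence[VariantRecord], elements: Sequence[GenomicInterval]
) -> dict[str, list[VariantRecord]]:
    """Per-element variant lists; a variant hits an element when its
    affected span (1 bp for an SNV) overlaps the element."""
    hits: dict[str, list[VariantRecord]] = {(e.name or str(e)): [] for e in elements}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for e in elements:
        by_chrom.setdefault(e.chrom, []).append(e)
    for v in variants:
        span = v.span
        for e in by_chrom.get(v.chrom, []):
            if span.start < e.end and span.end > e.start:
                hits[e.name or str(e)].append(v)
    return hits


def count_elements_with_variants(
    variants: Sequence[VariantRecord], elements: Sequence[GenomicInterval]
) -> int:
    return sum(bool(v) for v in intersect_variants(variants, elements).values())


def variant_permutation_test(
    elements: Sequence[GenomicInterval],
    variants: Sequence[VariantRecord],
    allowed_space: IntervalSet,
    n_perm: int = 1000,
    seed: int = 666,
    max_tries: int = 1000,
) -> PermutationResult:
    """Observed statistic: number of elements containing >= 1 variant.
    Null: same-length elements placed uniformly inside ``allowed_space``
    on the same chromosome."""
    observed = count_elements_with_variants(variants, elements)
    # precompute placeable blocks per chromosome
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {
        c: allowed_space.blocks(c) for c in allowed_space.chroms
    }

    def place(el: GenomicInterval, rng: np.random.Generator) -> GenomicInterval:
        s, e = blocks.get(el.chrom, (np.empty(0), np.empty(0)))
        widths = (e - s) - el.length
        ok = widths >= 0
        if not ok.any():
            raise ValueError(f"no non-coding transcript block can host {el}")
        cap = np.where(ok, widths + 1, 0)
        cum = np.cumsum(cap)
        pick = rng.integers(0, cum[-1])
        i = int(np.searchsorted(cum, pick, side="right"))
        start = int(s[i] + (pick - (cum[i - 1] if i else 0)))
        return GenomicInterval(el.chrom, start, start + el.length)

    def stat(rng: np.random.Generator) -> float:
        null_elements = [place(el, rng) for el in elements]
        return count_elements_with_variants(variants, null_elements)

    return permutation_enrichment(observed, stat, n_perm=n_perm, seed=seed)


def shortlist_multi_tcne_genes(
    gene_to_elements: dict[str, set[str]],
    elements_with_variants: set[str],
    min_tcnes: int = 2,
) -> set[str]:
    """Genes supported by at least ``min_tcnes`` variant-containing elements."""
    return {
        gene
        for gene, els in gene_to_elements.items()
        if len(els & elements_with_variants) >= min_tcnes
    }


@dataclass
class MutationSpectrum:
    counts: np.ndarray  # length 96, CONTEXTS_96 order
    total: int
    skipped: int = 0

    def normalized(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty mutation spectrum")
        return self.counts / self.counts.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"context": CONTEXTS_96, "count": self.counts.astype(int)})


def snv_context(v: VariantRecord, genome: GenomeSequence) -> str | None:
    """96-class label of an SNV, or None when the reference base does not
    match the genome (or flanks run off the chromosome / contain N)."""
    seq = genome.sequences[v.chrom]
    if not 1 <= v.pos < len(seq) - 1:
        return None
    ref_base = seq[v.pos]
    if ref_base != v.ref:
        return None
    tri = seq[v.pos - 1 : v.pos + 2]
    alt = v.alt
    if ref_base in "AG":  # purine frame: reverse-complement
        tri = reverse_complement(tri)
        alt = reverse_complement(alt)
    label = f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"
    return label if label in _CONTEXT_INDEX else None


def trinucleotide_spectrum(
    variants: Sequence[VariantRecord], genome: GenomeSequence
) -> MutationSpectrum:
    """96-context spectrum over SNVs; indels and reference-mismatching
    records contribute nothing (counted as skipped)."""
    counts = np.zeros(96)
    skipped = 0
    for v in variants:
        if v.kind != "SNV":
            continue
        label = snv_context(v, genome)
        if label is None:
            skipped += 1
            continue
        counts[_CONTEXT_INDEX[label]] += 1
    if skipped:
        logger.warning("%d SNVs skipped (reference mismatch or edge)", skipped)
    return MutationSpectrum(counts=counts, total=int(counts.sum()), skipped=skipped)


@dataclass
class SignatureFit:
    weights: dict[str, float]
    residual: float
    dropped: set[str] = field(default_factory=set)


def refit_signatures(
    spectrum: MutationSpectrum,
    reference: pd.DataFrame,
    min_weight: float = 0.06,
) -> SignatureFit:
    """Non-negative least squares of the normalized spectrum on reference
    signature columns (96 contexts x K signatures, each column a
    probability vector).  Weights below ``min_weight`` (after
    normalization) are zeroed and the fit repeated on the survivors; the
    final weights are renormalized to sum 1 and the residual is the L2
    distance between the normalized spectrum and its reconstruction."""
    if spectrum.total == 0:
        raise ValueError("cannot refit an empty spectrum")
    ref = reference.reindex(list(CONTEXTS_96))
    if ref.isna().any().any():
        raise ValueError("reference matrix missing trinucleotide contexts")
    target = spectrum.normalized()
    sigs = list(ref.columns)
    active = sigs
    while True:
        A = ref[active].to_numpy(dtype=float)
        w, _ = nnls(A, target)
        total = w.sum()
        norm_w = w / total if total > 0 else w
        weak = [s for s, wn in zip(active, norm_w) if 0 < wn < min_weight]
        nonzero = [s for s, wi in zip(active, w) if wi > 0]
        if not weak:
            break
        active = [s for s in nonzero if s not in weak]
        if not active:  # everything weak: keep the strongest signature
            active = [sigs[int(np.argmax(w))]]
            A = ref[active].to_numpy(dtype=float)
            w, _ = nnls(A, target)
            break
    A = ref[active].to_numpy(dtype=float)
    w, _ = nnls(A, target)
    recon = A @ w
    residual = float(np.linalg.norm(target - recon))
    total = w.sum()
    weights = {s: 0.0 for s in sigs}
    for s, wi in zip(active, w):
        weights[s] = float(wi / total) if total > 0 else 0.0
    dropped = {s for s in sigs if weights[s] == 0.0}
    return SignatureFit(weights=weights, residual=residual, dropped=dropped)


def synthetic_signature_matrix(n_signatures: int = 5, seed: int = 1, alpha: float = 0.3) -> pd.DataFrame:
    """A synthetic COSMIC-shaped reference (96 x K Dirichlet probability
    columns) for fixtures and tests; labelled synthetic, not COSMIC data."""
    rng = np.random.default_rng(seed)
    cols = {}
    for k in range(n_signatures):
        col = rng.dirichlet(np.full(96, alpha))
        cols[f"SynthSig{k + 1}"] = col
    return pd.DataFrame(cols, index=list(CONTEXTS_96))
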