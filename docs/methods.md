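# Methods

This note documents the models, rules and numerical choices implemented in
`tcnescan`, the reasoning behind the defaults, and what the synthetic data
generator does and does not emulate.

## Coordinates and containers

All internal coordinates are 0-based half-open (BED convention); GTF and
VCF are converted at the io boundary (1-based inclusive → half-open).
Printed element coordinates such as `chr6:52416350-52416570` are treated
as BED-convention.  Strand `"."` (unstranded) is allowed everywhere;
operations that require orientation (TSS distances, transcript-sense
sequence extraction) reject or branch on it explicitly.

Per-base signal (RNA-seq read density, CAGE, chromatin marks) is held
run-length encoded: sorted non-overlapping runs `(start, end, value ≥ 0)`
per chromosome, with absent bases meaning zero.  Every interval statistic
is defined on the implied dense per-base vector, and the test suite checks
run-length results against dense-array oracles.

## TCNE identification

A candidate conserved element enters the pipeline only if strictly longer
than 200 bp (`min_cne_length`, strict `>`); records on excludable
chromosomes (default `chrY`, `chrM`, as in cohorts of female patients
where the mitochondrial signal is confounding) are dropped at load.

**Aggregation.**  The cohort signal is the per-base trimmed mean across
samples.  The trim fraction is 0.1 per tail by default — a standard robust
choice protecting the aggregate against a few outlier samples; 0 recovers
the plain mean.  `floor(f·n)` values are removed from each tail.

**Filter 1 — blocklist.**  The blocklist is the merged union of structural
RNAs, annotated exons, strand-aware gene flanks (2 kb upstream of the TSS,
1 kb downstream of the TES), UTRs and assembly gaps.  Exclusion is
any-overlap (≥ 1 bp): regulatory candidacy is interpreted strictly, and
the rule matches default interval-intersection semantics.

**Filter 2 — containment.**  The element must lie entirely inside the
merged union of assembled-transcript spans, so an element bridging two
overlapping isoforms still passes.

**Filter 3 — independent transcription.**  For each CAGE track the noise
floor is the 5% quantile (`cage_noise_quantile`) of the track's *positive*
per-base values, weighted by run width.  Including the zero mass would
drive the quantile to 0 and disable the filter, because CAGE tracks are
mostly empty.  An element passes if its maximum in-element signal reaches
the floor (≥, boundary passes) in at least one track — evidence of
autonomous initiation rather than host-gene read-through.  A track with no
positive signal gets an infinite floor and a warning.  The filter can be
skipped (`--skip-independence`) when no CAGE data exist; the audit then
records the filter as skipped.

**Filter 4 — transcription threshold.**  Per-element mean aggregate
signals of the candidates surviving filters 1–3 are transformed with
log2(x+1) (variance-stabilizing; the per-element signal distribution is
near log-normal) and fitted with a normal distribution: μ̂ and σ̂ are the
sample mean and standard deviation (ddof = 1), and the threshold is the
lower 5th percentile of the fit, τ = μ̂ + σ̂·Φ⁻¹(0.05) (Φ⁻¹(0.05) ≈
−1.64485, so μ = 10, σ = 2 gives τ ≈ 6.7103).  τ lives on the transformed
scale.  Design choices that were genuinely open: the fit population is the
per-candidate mean (one number per element) rather than per-base signal,
because the threshold is applied to elements; and the population is
candidates-after-filter-3 (configurable), the set the threshold must
separate.  Degenerate input (all values equal) yields σ̂ = 0 and τ = μ̂
with a logged warning.

**Filter 5 — recurrence.**  An element is "detected" in a sample when the
sample's transformed in-element mean is ≥ τ — the same single global τ as
filter 4 rather than per-sample refits (simpler, and stated in the
audit).  The element must be detected in at least ⌈f·n⌉ samples
(`detection_fraction` = 0.05; 10 samples for n = 199, 1 for n = 20).  The
ceiling is computed with a 10⁻⁹ guard against float noise in `f·n`.

Every candidate, kept or dropped, is audited with all five boolean flags,
its aggregate and per-sample signals and its detection count
(`tcnes.audit.tsv`); filter counts always telescope.  Element strand is
the strand of its overlapping assembled transcript(s), `"."` on conflict
or no overlap.

## Context annotation

The representative transcript of a gene is its longest isoform
(configurable to an externally supplied list).  An element is *intronic*
when wholly inside an intron of the representative transcript of a
covering gene; introns are indexed 1..k in transcription order (5′→3′
along the strand).  When the introns of several overlapping genes contain
the element, the gene with the closer TSS wins and the annotation is
flagged ambiguous; elements straddling an exon boundary are classified by
majority base overlap and flagged.  Distances use element midpoints:
`tss_distance` is midpoint − TSS on `+` genes and TSS − midpoint on `−`
genes (positive = downstream), and the normalized position is that
distance over the gene-span length clamped to [0, 1].  Distance–expression
relationships use tie-aware Spearman correlation.

## Control regions and meta-profiles

Shuffled controls re-place each element on its own chromosome, same
length, avoiding an excluded set (typically the blocklist plus all
elements).  Placement draws uniformly over the *exact* feasible start
space (complement gaps are enumerated and weighted by width) rather than
rejection sampling, so a single feasible slot is found deterministically
and the uniform-placement contract holds exactly; the default seed is 666
and every stochastic entry point takes an explicit seed.  Matched intronic
controls are the intronic space within ±2 kb of an intronic element minus
all elements and the blocklist, returned as regions and pooled per base
for bulk comparisons; matched intergenic controls reuse the shuffling
restricted to intergenic space.

Meta-profiles average signal over a region set in two modes:
`length_normalized` (per-bp flanks plus the body rescaled to a fixed
number of bins by per-bin means) and `anchor_flanks` (per-bp windows
anchored at the start and end edges, concatenated).  Minus-strand regions
are flipped so bin 0 is always 5′; flanks clipped at chromosome ends have
their averaging weights adjusted.

## Enhancer overlap and permutation enrichment

A TCNE is a putative enhancer when ≥ 80% *of its own length*
(element-side, non-reciprocal; the side is an interpretation the source
description leaves open) is covered by at least one known enhancer set;
per-source support is recorded and one supporting source suffices (the
evidence sets are pooled without a voting rule).  Reciprocal 50%
intersection (both sides ≥ 0.5, bedtools `-f 0.5 -r` semantics) is
provided for matching against typical-enhancer catalogues.  Enrichment
against shuffled nulls uses the add-one empirical p-value
p = (1 + #{null ≥ observed})/(N + 1), which is never exactly 0; extreme
results are reported as `< 1/(N+1)`.  Under a null where the observed
statistic is itself drawn from the sampler, these p-values are
approximately uniform (checked by a seeded KS calibration test).

## TCNE-to-gene linking

Candidate pairs are element/gene combinations with |element midpoint −
gene TSS| ≤ 500 kb on the same chromosome.  Samples whose copy number is
aberrant at either locus — |log2 segment mean| > 1.5, strictly, two-sided
by default because deletions distort correlation as amplifications do
(a literal one-sided "above 1.5" mode exists) — are dropped from the
correlation rather than the link being discarded ("eliminating" the
copy-number-driven evidence; a flag drops the whole link instead).
Samples with no covering segment are retained and flagged.  Links with at
least 8 retained samples are tested with tie-aware Spearman correlation
(asymptotic p); p-values are Benjamini–Hochberg adjusted within the full
candidate family of the run (Holm available by flag), and a link passes
when ρ > 0.8 (positive only — the biological hypothesis is activating
regulation) and adjusted p < 0.01.  Topology summaries count elements per
gene, genes per element, and for each link the number of distinct gene
TSSs strictly between the element midpoint and the target TSS ("skipped"
genes).

## RNA G-quadruplex scanning

The scanner uses an explicit, fully testable motif grammar: a putative
quadruplex is four G-tracts of ≥ 2 guanines separated by three loops of
1–30 nt.  Tracts are maximal G-runs — loops never begin or end with G,
though a loop may contain an interior G-run when a run is skipped — which
makes every candidate decomposition unambiguous and exhaustively
enumerable.  The score is

    score = 20·(tetrads − 1) − Σᵢ max(0, loopᵢ − 3),

with tetrads the shortest tract length.  The coefficients are calibrated
so canonical three-tetrad quadruplexes with short loops score 40 and pass
the default reporting threshold of 25, while two-tetrad arrangements score
at most 20 and fail, reproducing the qualitative behavior of established
quadruplex scoring tools; equivalence with any external scorer is
explicitly not claimed, and bulged or mismatched tracts are not modeled.
Reported hits are selected greedily by descending score (leftmost on
ties) and never overlap.  Minus-strand elements are scanned on the
reverse complement; unstranded elements are scanned on both strands and
the better-scoring strand kept, flagged.  `N` bases break tracts.

## Variants and mutational signatures

A variant hits an element when its affected reference span (1 bp for an
SNV) overlaps the element; multiallelic records count as separate
variants.  Enrichment of variant-containing elements uses the same
add-one permutation machinery with same-length, same-chromosome
placements drawn uniformly inside non-coding transcribed space.  SNVs are
binned into the 96 trinucleotide classes in the pyrimidine frame
(purine-reference variants are reverse-complemented with their flanks);
reference-mismatching or chromosome-edge SNVs and all indels are skipped
with a warning count.  Signature refitting is non-negative least squares
of the normalized spectrum on a 96 × K reference matrix of probability
columns; normalized weights below 0.06 (the established refitting
default) are zeroed and the fit repeated on the survivors, final weights
renormalized to sum 1, and the residual reported as the L2 distance
between the spectrum and its reconstruction.  NNLS replaces iterative
forward selection; both minimize reconstruction error under
non-negativity.  The bundled `synthetic_signature_matrix` generates
Dirichlet probability columns for fixtures and tests; it is synthetic and
carries no external signature data.

## Synthetic data generator

`tcnescan.simulate` produces fully self-contained fixtures with
machine-checkable truth.  Default scale: 2 chromosomes × 1 Mb, 40
multi-exon genes on both strands (4–6 exons of 150–300 bp, introns
3–6 kb), 300 planted candidate elements with lengths 201–800 bp (the range
real element catalogues concentrate in), 20 coverage samples, 200
expression samples, 3 CAGE tracks — every stage runs in seconds.  Planted
categories isolate one filter each: elements overlapping an exon (filter
1), outside any transcript (filter 2), transcribed but without a CAGE
spike (filter 3), covered at background level only (filter 4), and
sub-200-bp records (length gate); the remainder must pass everything.
Expected per-filter flags under the default configuration are recorded in
`truth.json`.

Coverage is Poisson read-count noise (mean 2 reads/base, piecewise
constant over 50-bp blocks) over transcribed regions, with transcribed
elements elevated by an additional Poisson component at signal-to-noise
10 in 80% of samples; CAGE spikes (values 30–80 over the element's first
5 bases, transcript-sense) are written only for independence-positive
elements, on sparse positive background (the background is kept outside
all elements so the noise floor is well defined and planted negatives
stay negative).  Expression for planted true links shares a latent
bivariate normal with Pearson ρ = 2·sin(π·0.9/6) ≈ 0.908, the value whose
induced Spearman correlation is 0.9; monotone (exponential) marginals
preserve it.  Copy-number-corrupted null pairs are independent at
baseline, but half the cohort receives perfectly rank-concordant
co-amplification spikes together with |log2 segment mean| = 2.0 segments
at both loci: a perfectly concordant top block of m of n samples yields
Spearman ≈ 1 − ((n−m)/n)³, so m/n = 0.5 gives ρ ≈ 0.875 > 0.8 — the pair
passes the gate only when the copy-number filter is disabled, making the
filter load-bearing in tests.  Variants are SNVs whose reference base
matches the genome and whose trinucleotide contexts are sampled from a
recorded mixture of two synthetic signatures (0.7/0.3), placed inside
must-pass elements at a controlled fraction, plus a few deletions.
Half of the must-pass elements carry a planted three-tetrad quadruplex
cassette on the transcript sense; background sequence is AT-rich (38/12/
12/38), under which a spurious score-25 quadruplex is vanishingly rare.

What the generator does **not** emulate: mappability and GC biases,
fragment-level autocorrelation of RNA-seq coverage, isoform switching,
library-size variation (no TPM/FPKM normalization anywhere — inputs are
assumed depth-comparable), linkage between variants, and genome-scale
repeat structure.  Passing tests therefore demonstrate algorithmic
correctness and calibrated error control under the stated generative
conditions, not performance on real cohorts.

## Determinism and problem sizes

Every stochastic step consumes an explicit integer seed; the CLI threads
one seed from the run configuration through all stages, and rerunning any
subcommand with the same config reproduces byte-identical data outputs
(run reports carry wall times and are excluded from the comparison).  The
test suite exercises oracle equivalence on fifty 2 × 1 Mb genomes with 5
coverage samples each, recovery at the default 300-element scale across
three seeds, and link recovery at 200 expression samples across three
seeds — sizes chosen so the whole suite completes in about a minute while
the per-stage statistics (recall, false-link fraction, calibration KS
distance) remain well determined.

## Known limitations

- The CNA segment lookup is a linear scan per (sample, locus); adequate at
  cohort scale here, but an interval index would be needed for
  genome-wide segment files with thousands of segments per sample.
- `bedgraph` input is required for coverage; BAM-to-coverage conversion
  and BigWig writing are out of scope (BigWig reading can be added via
  pyBigWig without touching the module surfaces).
- The quadruplex grammar models perfect tracts only; bulges, two-tetrad
  stabilized structures and thermodynamic folding are not scored.
- Survival analysis, motif discovery/enrichment, pathway/GO/GWAS
  enrichment and network construction are deliberately outside the
  package; their standard tools consume the TSV/BED outputs directly.
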