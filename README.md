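# tcnescan

Genome-wide identification and characterization of **transcribed conserved
non-coding elements (TCNEs)** from multi-sample RNA-seq coverage.

Conserved non-coding elements (CNEs) are genomic sequences (here, > 200 bp)
deeply conserved across mammalian genomes that often act as regulatory
elements near developmental and cancer genes.  A large fraction of them are
transcribed, and their transcripts can behave like enhancer RNAs.  Given a
catalogue of known CNEs and per-sample RNA-seq read-density tracks from a
tumor cohort, `tcnescan` decides which CNEs are *independently and
recurrently transcribed* and then characterizes the resulting TCNEs:
genic context, enhancer overlap, RNA G-quadruplex content, candidate
target genes, and the variants and mutational signatures they carry.

## The method

**Identification (five filters).**  Per-base read densities are aggregated
across the cohort with a trimmed mean (trim fraction 0.1 per tail), and a
candidate CNE (length > 200 bp, strictly) becomes a TCNE iff it

1. overlaps no base of a *blocklist* (structural RNAs, annotated exons,
   2 kb upstream and 1 kb downstream of genes, UTRs, assembly gaps);
2. lies entirely within assembled full-length transcript regions;
3. shows independent transcription initiation: CAGE signal inside the
   element at or above a per-track noise floor (the 5% quantile of the
   track's positive per-base values) in at least one track;
4. has aggregate transcription above a threshold τ fitted on the
   candidate population: with per-element mean aggregate signal
   x transformed to log2(x+1), τ = μ̂ + σ̂·Φ⁻¹(0.05);
5. is detected (per-sample transformed mean ≥ τ) in at least
   ⌈0.05·n⌉ samples (10 of a 199-sample cohort).

**Downstream.**  Each TCNE is classified intronic/intergenic against the
host gene's longest transcript with its intron index and (strand-aware)
TSS distance; putative enhancers are TCNEs whose length is covered ≥ 80%
by a known enhancer set, with enrichment assessed by permutation against
blocklist-aware shuffled placements (add-one empirical
p = (1 + #{null ≥ obs})/(N+1)); TCNE-to-gene links are candidate pairs
within 500 kb of a gene TSS that reach Spearman ρ > 0.8 and
Benjamini–Hochberg adjusted p < 0.01 after removing samples whose copy
number (|log2 segment mean| > 1.5) is aberrant at either locus; RNA
G-quadruplexes are scanned with an explicit grammar (four maximal G-tracts
≥ 2 nt, loops 1–30 nt) scored 20·(tetrads − 1) − Σ max(0, loopᵢ − 3) at a
reporting threshold of 25; SNVs intersecting TCNEs are tested by
permutation inside non-coding transcribed space, binned into the 96
pyrimidine-frame trinucleotide contexts and refit against a signature
matrix by non-negative least squares (weights < 0.06 dropped and refit).

A fully synthetic data generator (`tcnescan.simulate`) plants elements of
every category with known per-filter outcomes, correlated element/gene
expression, copy-number-corrupted null links, G-quadruplex cassettes and
signature-mixture variants, so every stage is testable end to end.

## Worked example

```sh
tcnescan simulate --seed 666 --n-chroms 1 --chrom-length 400000 \
    --n-genes 10 --n-cnes 60 --n-samples 10 --n-expression-samples 100 -o demo
tcnescan all -c demo/config.yaml
```

prints

```
30 TCNEs of 54 candidates
24/30 intronic
30 shuffled, 78 matched controls
9/30 putative enhancers, p < 0.00497512
5 passed links of 300 candidates
15/30 rG4-containing
30 variant-containing elements, p < 0.00497512
```

Reading the numbers: of 60 planted candidates, 54 are longer than 200 bp
and enter the pipeline and exactly the 30 planted transcribed elements
survive all five filters (the audit of every candidate, flag by flag, is
in `demo/tcnes.audit.tsv`).  24 of the 30 TCNEs sit in introns; 9 are
covered ≥ 80% by the synthetic enhancer annotation — more than any of the
200 shuffled placements, hence the floor p-value 1/201.  Five
element–gene pairs pass the ρ > 0.8, BH p < 0.01 gate out of 300
candidate pairs within 500 kb; 15 elements carry a quadruplex motif
scoring ≥ 25; and all 30 TCNEs that received planted variants are
recovered, again exceeding every shuffled null.

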