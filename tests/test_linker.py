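import numpy as np
import pandas as pd
import pytest

from tcnescan.genes import GeneModel, TranscriptModel
from tcnescan.intervals import GenomicInterval
from tcnescan.linker import test_link as link_stat  # noqa: avoid pytest collection
from tcnescan.linker import (
    CNASegments,
    candidate_pairs,
    cna_sample_filter,
    link_candidates,
    link_topology,
)
from tcnescan.stats import bh_adjust, spearman

from _oracles import bh_oracle, spearman_oracle


def iv(start, end, chrom="chr1", name=None):
    return GenomicInterval(chrom, start, end, name=name)


def make_gene(gene_id, tss, chrom="chr1", strand="+", length=2000):
    if strand == "+":
        exons = [(tss, tss + 200), (tss + length - 200, tss + length)]
    else:
        exons = [(tss - length, tss - length + 200), (tss - 200, tss)]
    return GeneModel(
        gene_id, chrom, strand,
        [TranscriptModel(f"{gene_id}.t", chrom, strand,
                         [GenomicInterval(chrom, a, b, strand) for a, b in exons])],
    )


class TestCandidatePairs:
    def test_window_boundary(self):
        gene = make_gene("g", 1_000_000)
        near = iv(1_399_800, 1_400_200, name="near")      # 400 kb
        far = iv(1_599_800, 1_600_200, name="far")        # 600 kb
        other = iv(1_000_000, 1_000_400, chrom="chr2", name="oc")
        pairs = candidate_pairs([near, far, other], [gene])
        assert [(e.name, g.gene_id) for e, g in pairs] == [("near", "g")]


class TestCnaFilter:
    def _segments(self, value):
        rows = pd.DataFrame(
            {"sample": ["s1"], "chrom": ["chr1"], "start": [0],
             "end": [10_000_000], "log2_segment_mean": [value]}
        )
        return CNASegments.from_frame(rows)

    @pytest.mark.parametrize(
        "value,retained",
        [(1.6, False), (1.5, True), (-1.6, False), (0.0, True)],
    )
    def test_two_sided_strict_cutoff(self, value, retained):
        gene = make_gene("g", 50_000)
        kept, _ = cna_sample_filter(iv(10_000, 10_400), gene, ["s1"],
                                    self._segments(value))
        assert (kept == ["s1"]) is retained

    def test_one_sided_mode_keeps_deletions(self):
        gene = make_gene("g", 50_000)
        kept, _ = cna_sample_filter(iv(10_000, 10_400), gene, ["s1"],
                                    self._segments(-1.6), two_sided=False)
        assert kept == ["s1"]

    def test_uncovered_locus_retained_and_flagged(self):
        segs = CNASegments({"s1": []})
        gene = make_gene("g", 50_000)
        kept, flagged = cna_sample_filter(iv(10_000, 10_400), gene, ["s1"], segs)
        assert kept == ["s1"] and flagged


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert link_stat(x, np.exp(x))[0] == pytest.approx(1.0)
        assert link_stat(x, -x**3)[0] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            link_stat([1.0] * 10, list(range(10)))

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 10, n).astype(float)  # ties included
            y = rng.normal(size=n)
            if len(set(x)) < 2:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestBH:
    def test_step_up_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)
            assert (bh_adjust(p) >= p - 1e-15).all()

    def test_holm_available(self):
        got = bh_adjust([0.01, 0.04], method="holm")
        np.testing.assert_allclose(got, [0.02, 0.04])


class TestLinkingPipeline:
    def _setup(self, n_samples=60, seed=0):
        rng = np.random.default_rng(seed)
        genes = [make_gene("gA", 100_000), make_gene("gB", 300_000)]
        els = [iv(150_000, 150_400, name="e1"), iv(340_000, 340_400, name="e2")]
        samples = [f"s{i}" for i in range(n_samples)]
        z = rng.normal(size=n_samples)
        tcne = pd.DataFrame(
            {s: [np.exp(z[i]), np.exp(rng.normal())] for i, s in enumerate(samples)},
            index=["e1", "e2"],
        )
        gene_expr = pd.DataFrame(
            {s: [np.exp(2 + 0.99 * z[i]), np.exp(rng.normal())]
             for i, s in enumerate(samples)},
            index=["gA", "gB"],
        )
        return els, genes, tcne, gene_expr

    def test_true_link_passes_null_does_not(self):
        els, genes, tcne, gene_expr = self._setup()
        records = link_candidates(els, genes, tcne, gene_expr)
        by_pair = {(r.tcne_id, r.gene_id): r for r in records}
        assert by_pair[("e1", "gA")].passed
        assert not by_pair[("e2", "gB")].passed

    def test_sample_order_invariance(self):
        els, genes, tcne, gene_expr = self._setup()
        r1 = link_candidates(els, genes, tcne, gene_expr)
        perm = list(tcne.columns)[::-1]
        r2 = link_candidates(els, genes, tcne[perm], gene_expr[perm])
        assert {(r.tcne_id, r.gene_id, round(r.rho, 12)) for r in r1} == \
               {(r.tcne_id, r.gene_id, round(r.rho, 12)) for r in r2}

    def test_negative_correlation_never_passes(self):
        els, genes, tcne, gene_expr = self._setup()
        gene_expr.loc["gA"] = 1.0 / gene_expr.loc["gA"]
        records = link_candidates(els, genes, tcne, gene_expr)
        r = {(x.tcne_id, x.gene_id): x for x in records}[("e1", "gA")]
        assert r.rho < -0.9 and not r.passed

    def test_too_few_samples_skips(self):
        els, genes, tcne, gene_expr = self._setup(n_samples=5)
        records = link_candidates(els, genes, tcne, gene_expr)
        assert all(r.skip_reason == "too few retained samples" for r in records)


class TestTopology:
    def test_skipped_gene_counts(self):
        gA = make_gene("gA", 100_000)
        gB = make_gene("gB", 160_000)
        el = iv(80_000, 80_400, name="e")  # midpoint 80_200, upstream of both
        records = link_candidates(
            [el], [gA, gB],
            pd.DataFrame([[1, 2, 3, 4, 5, 6, 7, 8.0]], index=["e"],
                         columns=list("abcdefgh")),
            pd.DataFrame([[1, 2, 3, 4, 5, 6, 7, 8.0],
                          [2, 4, 6, 8, 10, 12, 14, 16.0]],
                         index=["gA", "gB"], columns=list("abcdefgh")),
        )
        by_pair = {(r.tcne_id, r.gene_id): r for r in records}
        assert by_pair[("e", "gA")].genes_skipped == 0   # nearest gene
        assert by_pair[("e", "gB")].genes_skipped == 1   # gA's TSS intervenes
        topo = link_topology(records)
        assert topo["tcnes_per_gene"].to_dict() == {"gA": 1, "gB": 1}
        assert topo["genes_per_tcne"].to_dict() == {"e": 2}
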