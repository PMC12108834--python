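import numpy as np
import pytest

from tcnescan.intervals import IntervalSet
from tcnescan.simulate import (
    simulate_coverage,
    simulate_expression,
    simulate_genome,
    simulate_variants,
)
from tcnescan.stats import spearman


class TestGenome:
    def test_same_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            fx = simulate_genome(n_chroms=1, chrom_length=300_000, n_genes=8,
                                 n_cnes=40, seed=13)
            simulate_coverage(fx, n_samples=4).write(tmp_path / sub)
            fx.write(tmp_path / sub)
        for name in ("genome.fa", "genes.gtf", "cnes.bed", "truth.json",
                     "coverage.S000.bedgraph", "cage.CAGE0.bedgraph"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_zero_cnes_valid(self):
        fx = simulate_genome(n_chroms=1, chrom_length=200_000, n_genes=5,
                             n_cnes=0, seed=1)
        assert fx.elements == []
        assert len(fx.genes) == 5

    def test_truth_joinable_and_categories_planted(self, toy_fixture):
        truth = toy_fixture.truth_by_id()
        assert set(truth) == {e.element_id for e in toy_fixture.elements}
        cats = {e.category for e in toy_fixture.elements}
        assert {"pass_intronic", "pass_intergenic", "fail_blocklist",
                "fail_containment", "fail_independence", "fail_threshold",
                "short"} <= cats

    def test_planted_geometry_matches_category(self, toy_fixture):
        exons = IntervalSet(e for g in toy_fixture.genes for e in g.exons())
        regions = toy_fixture.transcript_regions()
        for el in toy_fixture.elements:
            if el.category == "fail_blocklist":
                assert exons.overlaps(el.interval), el.element_id
            if el.category in ("pass_intronic", "fail_independence", "fail_threshold"):
                assert not exons.overlaps(el.interval)
                assert regions.contains(el.interval)
            if el.category == "fail_containment":
                assert not regions.contains(el.interval)
            if el.category == "short":
                assert el.interval.length <= 200
            else:
                assert 200 < el.interval.length <= 800

    def test_element_lengths_in_study_range(self, toy_fixture):
        lengths = [e.interval.length for e in toy_fixture.elements
                   if e.category != "short"]
        assert min(lengths) >= 201 and max(lengths) <= 800


class TestCoverageTruth:
    def test_boosted_elements_have_elevated_signal(self, toy_fixture, toy_coverage):
        from tcnescan.coverage import interval_signal

        truth = toy_fixture.truth_by_id()
        for el in toy_fixture.elements:
            if el.category not in ("pass_intronic", "fail_threshold"):
                continue
            boosted = toy_coverage.detected_samples[el.element_id]
            means = [interval_signal(t, el.interval, "mean")
                     for t in toy_coverage.sample_tracks]
            if el.category == "pass_intronic":
                assert len(boosted) > 0
                rest = [m for i, m in enumerate(means) if i not in boosted]
                boosted_mean = np.mean([means[i] for i in boosted])
                if rest:
                    assert boosted_mean > 4 * np.mean(rest)
            else:
                assert boosted == []

    def test_cage_spikes_only_where_planted(self, toy_fixture, toy_coverage):
        from tcnescan.coverage import interval_signal

        spiked = {"pass_intronic", "pass_intergenic", "fail_blocklist",
                  "fail_containment", "fail_threshold"}
        for el in toy_fixture.elements:
            mx = max(interval_signal(t, el.interval, "max")
                     for t in toy_coverage.cage_tracks)
            if el.category in spiked:
                assert mx >= 30, el.element_id
            else:
                assert mx == 0.0, el.element_id


class TestExpressionTruth:
    def test_planted_rho_across_seeds(self, toy_fixture):
        for seed in (101, 102, 103):
            bundle = simulate_expression(toy_fixture, n_samples=200, seed=seed)
            for link in toy_fixture.links:
                x = bundle.tcne_expr.loc[link.tcne_id].to_numpy()
                y = bundle.gene_expr.loc[link.gene_id].to_numpy()
                rho, _ = spearman(x, y)
                if link.kind == "true":
                    assert 0.8 <= rho <= 0.97, (seed, link.tcne_id, rho)

    def test_independent_pairs_uncorrelated(self, toy_fixture):
        bundle = simulate_expression(toy_fixture, n_samples=200, seed=104)
        linked = {(l.tcne_id, l.gene_id) for l in toy_fixture.links}
        # members of copy-number-corrupted null pairs co-spike in the same
        # corrupted samples, so they are only independent after filtering
        corrupted_members = {l.tcne_id for l in toy_fixture.links if l.kind == "cna_null"}
        corrupted_members |= {l.gene_id for l in toy_fixture.links if l.kind == "cna_null"}
        rng = np.random.default_rng(0)
        elements = [e for e in bundle.tcne_expr.index if e not in corrupted_members]
        genes = [g for g in bundle.gene_expr.index if g not in corrupted_members]
        checked = 0
        for _ in range(60):
            e = elements[int(rng.integers(len(elements)))]
            g = genes[int(rng.integers(len(genes)))]
            if (e, g) in linked:
                continue
            rho, _ = spearman(bundle.tcne_expr.loc[e], bundle.gene_expr.loc[g])
            assert abs(rho) < 0.3
            checked += 1
        assert checked > 40

    def test_cna_corruption_recorded(self, toy_fixture):
        bundle = simulate_expression(toy_fixture, n_samples=100, seed=105)
        assert len(toy_fixture.corrupted_samples) == 50
        cna = bundle.cna_frame
        aberrant = cna[cna.log2_segment_mean.abs() > 1.5]
        assert set(aberrant["sample"]) <= set(toy_fixture.corrupted_samples)
        if len([l for l in toy_fixture.links if l.kind == "cna_null"]):
            assert len(aberrant) > 0


class TestVariantTruth:
    def test_reference_bases_match_genome(self, toy_fixture):
        variants = simulate_variants(toy_fixture, n_variants=150, seed=9)
        for v in variants:
            got = toy_fixture.genome.sequences[v.chrom][v.pos : v.pos + len(v.ref)]
            assert got == v.ref

    def test_inside_fraction_extremes(self, toy_fixture):
        variants = simulate_variants(toy_fixture, n_variants=100,
                                     inside_fraction=1.0, indel_fraction=0.0, seed=10)
        passers = [e.interval for e in toy_fixture.elements if e.must_pass]
        inside = IntervalSet(passers)
        assert all(inside.overlaps(v.span) for v in variants)

    def test_truth_records_mixture(self, toy_fixture):
        simulate_variants(toy_fixture, n_variants=50, seed=11)
        w = toy_fixture.variant_truth["signature_weights"]
        assert sum(w.values()) == pytest.approx(1.0)
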