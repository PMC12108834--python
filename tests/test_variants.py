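import numpy as np
import pandas as pd
import pytest

from tcnescan.intervals import GenomicInterval, GenomeSequence, IntervalSet
from tcnescan.variants import (
    CONTEXTS_96,
    MutationSpectrum,
    VariantRecord,
    intersect_variants,
    read_variant_table,
    refit_signatures,
    shortlist_multi_tcne_genes,
    snv_context,
    synthetic_signature_matrix,
    trinucleotide_spectrum,
    variant_permutation_test,
)


def iv(start, end, chrom="chr1", name=None):
    return GenomicInterval(chrom, start, end, name=name)


class TestIntersect:
    def test_snv_inside_element(self):
        el = iv(100, 400, name="e")
        hits = intersect_variants([VariantRecord("chr1", 250, "C", "T")], [el])
        assert len(hits["e"]) == 1

    def test_deletion_straddles_boundary(self):
        el = iv(100, 400, name="e")
        deletion = VariantRecord("chr1", 395, "ACGTACGTAC", "A")
        hits = intersect_variants([deletion], [el])
        assert len(hits["e"]) == 1
        before = VariantRecord("chr1", 90, "ACGTACGTAC", "A")  # ends at 100
        assert intersect_variants([before], [el])["e"] == []

    def test_other_chromosome_misses(self):
        el = iv(100, 400, name="e")
        hits = intersect_variants([VariantRecord("chr2", 250, "C", "T")], [el])
        assert hits["e"] == []

    def test_variant_kinds(self):
        assert VariantRecord("chr1", 0, "C", "T").kind == "SNV"
        assert VariantRecord("chr1", 0, "C", "CAT").kind == "insertion"
        assert VariantRecord("chr1", 0, "CAT", "C").kind == "deletion"


class TestSpectrum:
    def test_pyrimidine_frame_direct(self):
        genome = GenomeSequence({"chr1": "ACAT"})
        assert snv_context(VariantRecord("chr1", 1, "C", "T"), genome) == "A[C>T]A"

    def test_purine_reverse_complemented(self):
        genome = GenomeSequence({"chr1": "TGA"})
        assert snv_context(VariantRecord("chr1", 1, "G", "A"), genome) == "T[C>T]A"

    def test_reference_mismatch_skipped(self):
        genome = GenomeSequence({"chr1": "AAAA"})
        spec = trinucleotide_spectrum([VariantRecord("chr1", 1, "C", "T")], genome)
        assert spec.total == 0 and spec.skipped == 1

    def test_indels_contribute_nothing(self):
        genome = GenomeSequence({"chr1": "ACATACAT"})
        spec = trinucleotide_spectrum(
            [VariantRecord("chr1", 1, "CAT", "C"), VariantRecord("chr1", 1, "C", "G")],
            genome,
        )
        assert spec.total == 1
        assert spec.counts[CONTEXTS_96.index("A[C>G]A")] == 1

    def test_every_snv_maps_to_one_bin(self, toy_fixture):
        from tcnescan.simulate import simulate_variants

        variants = simulate_variants(toy_fixture, n_variants=120)
        snvs = [v for v in variants if v.kind == "SNV"]
        spec = trinucleotide_spectrum(snvs, toy_fixture.genome)
        assert spec.skipped == 0
        assert spec.total == len(snvs)


class TestRefit:
    REF = synthetic_signature_matrix(n_signatures=4, seed=5)

    def _spectrum(self, probs, n=100_000):
        counts = np.asarray(probs) * n
        return MutationSpectrum(counts=counts, total=int(counts.sum()))

    def test_single_signature_identity(self):
        fit = refit_signatures(self._spectrum(self.REF.iloc[:, 0].to_numpy()), self.REF)
        assert fit.weights[self.REF.columns[0]] == pytest.approx(1.0, abs=1e-9)
        assert fit.residual < 1e-9

    def test_noiseless_mixture_recovered(self):
        mix = 0.6 * self.REF.iloc[:, 0] + 0.4 * self.REF.iloc[:, 2]
        fit = refit_signatures(self._spectrum(mix.to_numpy()), self.REF)
        assert fit.weights[self.REF.columns[0]] == pytest.approx(0.6, abs=1e-6)
        assert fit.weights[self.REF.columns[2]] == pytest.approx(0.4, abs=1e-6)

    def test_multinomial_noise_within_tolerance(self):
        mix = (0.7 * self.REF.iloc[:, 1] + 0.3 * self.REF.iloc[:, 3]).to_numpy()
        rng = np.random.default_rng(3)
        counts = rng.multinomial(500, mix)
        fit = refit_signatures(
            MutationSpectrum(counts=counts.astype(float), total=500), self.REF
        )
        assert fit.weights[self.REF.columns[1]] == pytest.approx(0.7, abs=0.1)
        assert fit.weights[self.REF.columns[3]] == pytest.approx(0.3, abs=0.1)

    def test_weights_sum_to_one_and_nonnegative(self):
        rng = np.random.default_rng(4)
        spec = MutationSpectrum(counts=rng.integers(0, 30, 96).astype(float), total=1)
        spec.total = int(spec.counts.sum())
        fit = refit_signatures(spec, self.REF)
        assert min(fit.weights.values()) >= 0.0
        assert sum(fit.weights.values()) == pytest.approx(1.0)
        nonzero = [w for w in fit.weights.values() if w > 0]
        assert all(w >= 0.06 - 1e-9 for w in nonzero)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            refit_signatures(MutationSpectrum(counts=np.zeros(96), total=0), self.REF)


class TestShortlist:
    def test_min_two_boundary(self):
        mapping = {"gA": {"t1", "t2"}, "gB": {"t3"}, "gC": {"t4", "t5", "t6"}}
        with_var = {"t1", "t2", "t3", "t4", "t5"}
        assert shortlist_multi_tcne_genes(mapping, with_var) == {"gA", "gC"}

    def test_empty_mapping(self):
        assert shortlist_multi_tcne_genes({}, {"t"}) == set()


class TestPermutation:
    def test_all_variants_inside_gives_floor_p(self):
        elements = [iv(1000, 1400, name="e1"), iv(3000, 3400, name="e2")]
        allowed = IntervalSet([iv(0, 50_000)])
        variants = [VariantRecord("chr1", 1100, "C", "T"),
                    VariantRecord("chr1", 3100, "C", "T")]
        res = variant_permutation_test(elements, variants, allowed, n_perm=99, seed=2)
        assert res.observed == 2
        assert res.p_value <= 0.05

    def test_zero_variants_p_one(self):
        elements = [iv(1000, 1400, name="e")]
        res = variant_permutation_test(
            elements, [], IntervalSet([iv(0, 10_000)]), n_perm=49, seed=1
        )
        assert res.observed == 0 and res.p_value == 1.0

    def test_unplaceable_element_rejected(self):
        with pytest.raises(ValueError):
            variant_permutation_test(
                [iv(0, 5000, name="big")], [], IntervalSet([iv(0, 100)]),
                n_perm=9, seed=1,
            )


def test_read_variant_table_coordinates():
    df = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["c"], "alt": ["t"]})
    (v0,) = read_variant_table(df)
    assert (v0.pos, v0.ref, v0.alt) == (100, "C", "T")
    (v1,) = read_variant_table(df, one_based=True)
    assert v1.pos == 99
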