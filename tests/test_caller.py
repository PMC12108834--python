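import numpy as np
import pytest

from tcnescan.caller import (
    CallerConfig,
    build_blocklist,
    filter_blocklist,
    filter_containment,
    filter_independence,
    filter_length,
    filter_threshold_and_recurrence,
    run_caller,
    assign_strand,
    TCNERecord,
)
from tcnescan.coverage import SignalTrack
from tcnescan.genes import GeneModel, TranscriptModel
from tcnescan.intervals import GenomicInterval, IntervalSet


def iv(start, end, chrom="chr1", name=None):
    return GenomicInterval(chrom, start, end, name=name)


def make_gene(gene_id, chrom, strand, exon_coords):
    exons = [GenomicInterval(chrom, a, b, strand) for a, b in exon_coords]
    return GeneModel(gene_id, chrom, strand, [TranscriptModel(f"{gene_id}.t1", chrom, strand, exons)])


class TestBlocklist:
    def test_plus_strand_flanks(self):
        gene = make_gene("g", "chr1", "+", [(5000, 5200), (7800, 8000)])
        bl = build_blocklist([gene])
        flanks = {(i.start, i.end) for i in bl.components["upstream2k"]}
        assert flanks == {(3000, 5000)}
        downs = {(i.start, i.end) for i in bl.components["downstream1k"]}
        assert downs == {(8000, 9000)}

    def test_minus_strand_flanks(self):
        gene = make_gene("g", "chr1", "-", [(5000, 5200), (7800, 8000)])
        bl = build_blocklist([gene])
        assert {(i.start, i.end) for i in bl.components["upstream2k"]} == {(8000, 10000)}
        assert {(i.start, i.end) for i in bl.components["downstream1k"]} == {(4000, 5000)}

    def test_empty_inputs(self):
        assert len(build_blocklist([])) == 0

    def test_negative_flank_clipped(self):
        gene = make_gene("g", "chr1", "+", [(500, 600), (900, 1000)])
        bl = build_blocklist([gene])
        assert {(i.start, i.end) for i in bl.components["upstream2k"]} == {(0, 500)}


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [(220, True), (200, False), (201, True)])
    def test_strictly_greater_than_200(self, length, kept):
        out = filter_length([iv(1000, 1000 + length)])
        assert bool(out) is kept


class TestBlocklistFilter:
    def test_single_base_overlap_removes(self):
        gene = make_gene("g", "chr1", "+", [(5000, 5200), (9000, 9200)])
        bl = build_blocklist([gene])
        inside_intron = iv(6000, 6300)
        touching_exon = iv(8701, 9001)  # 1 bp into the exon
        out = filter_blocklist([inside_intron, touching_exon], bl)
        assert out == [inside_intron]

    def test_empty_blocklist_identity(self):
        cnes = [iv(0, 300), iv(400, 800)]
        assert filter_blocklist(cnes, build_blocklist([])) == cnes


class TestContainment:
    def test_containment_rules(self):
        regions = IntervalSet([iv(100, 400)])
        kept = filter_containment([iv(150, 350), iv(150, 450)], regions)
        assert [(c.start, c.end) for c in kept] == [(150, 350)]

    def test_no_transcripts_removes_all(self):
        assert filter_containment([iv(0, 300)], IntervalSet()) == []

    def test_merged_isoform_union(self):
        # element spanning two overlapping transcript spans still contained
        regions = IntervalSet([iv(0, 250), iv(200, 500)])
        assert filter_containment([iv(100, 400)], regions) == [iv(100, 400)]


class TestIndependence:
    def test_boundary_at_floor_passes(self):
        # positive values 1..100 -> 5% noise floor is 5
        cage = SignalTrack.from_runs(
            [("chr1", i * 10, i * 10 + 1, float(i + 1)) for i in range(100)]
        )
        floor = cage.positive_quantile(0.05)
        at_floor = iv(40, 50)    # max in-element signal exactly 5
        below = iv(30, 40)       # max in-element signal 4 < floor
        assert floor == 5.0
        assert filter_independence([at_floor, below], [cage]) == [at_floor]

    def test_zero_signal_fails(self):
        cage = SignalTrack.from_runs([("chr1", 0, 1, 50.0)])
        assert filter_independence([iv(1000, 1300)], [cage]) == []

    def test_any_track_suffices(self):
        quiet = SignalTrack.from_runs([("chr1", 0, 1, 1.0)])
        loud = SignalTrack.from_runs([("chr1", 1500, 1505, 40.0), ("chr1", 0, 1, 1.0)])
        el = iv(1400, 1700)
        assert filter_independence([el], [quiet, loud]) == [el]

    def test_empty_track_warns_and_disables(self):
        empty = SignalTrack.from_runs([])
        with pytest.warns(UserWarning):
            out = filter_independence([iv(0, 300)], [empty])
        assert out == []


class TestRecurrenceArithmetic:
    @pytest.mark.parametrize("n,expected", [(199, 10), (20, 1), (40, 2), (21, 2)])
    def test_min_detected_ceiling(self, n, expected):
        assert CallerConfig().min_detected(n) == expected

    def test_threshold_gate_and_detection(self):
        el = iv(0, 400, name="el")
        high = [SignalTrack.from_runs([("chr1", 0, 400, 30.0)], sample_id=f"h{i}")
                for i in range(3)]
        low = [SignalTrack.from_runs([("chr1", 0, 400, 0.5)], sample_id="l")]
        tracks = high + low
        from tcnescan.coverage import TranscriptionThreshold

        thr = TranscriptionThreshold(mu=3.0, sigma=1.0, quantile=0.05, tau=2.0,
                                     transform="log2p1")
        rec = TCNERecord(interval=el, source_cne_id="el",
                         aggregate_signal=float(np.log2(31.0)))
        kept = filter_threshold_and_recurrence(
            [el], tracks, thr, detection_fraction=0.5, records={"el": rec}
        )
        assert kept == [el]
        assert rec.detected_in == 3
        # below-tau aggregate is dropped regardless of recurrence
        rec2 = TCNERecord(interval=el, source_cne_id="el", aggregate_signal=0.0)
        assert filter_threshold_and_recurrence(
            [el], tracks, thr, detection_fraction=0.5, records={"el": rec2}
        ) == []
        assert rec2.filter_flags["recurrence"] is True


class TestStrandAssignment:
    def test_unanimous_and_conflicting(self):
        plus = TranscriptModel("p", "chr1", "+", [GenomicInterval("chr1", 0, 1000, "+")])
        minus = TranscriptModel("m", "chr1", "-", [GenomicInterval("chr1", 500, 1500, "-")])
        r1 = TCNERecord(interval=iv(100, 400), source_cne_id="a")
        r2 = TCNERecord(interval=iv(600, 900), source_cne_id="b")
        r3 = TCNERecord(interval=iv(2000, 2300), source_cne_id="c")
        assign_strand([r1, r2, r3], [plus, minus])
        assert r1.strand_call == "+"
        assert r2.strand_call == "."  # overlaps both strands
        assert r3.strand_call == "."  # no overlap


class TestPipeline:
    def test_order_invariance(self, toy_fixture, toy_coverage):
        from tcnescan.caller import build_blocklist

        bl = build_blocklist(toy_fixture.genes)
        regions = toy_fixture.transcript_regions()
        cnes = toy_fixture.cnes()
        res1 = run_caller(cnes, bl, regions, toy_coverage.cage_tracks,
                          toy_coverage.sample_tracks)
        rng = np.random.default_rng(0)
        shuffled = list(cnes)
        rng.shuffle(shuffled)
        res2 = run_caller(shuffled, bl, regions, toy_coverage.cage_tracks,
                          toy_coverage.sample_tracks)
        ids1 = {r.source_cne_id for r in res1.tcnes}
        assert ids1 == {r.source_cne_id for r in res2.tcnes}
        assert res1.threshold.tau == res2.threshold.tau

    def test_stricter_settings_never_gain_calls(self, toy_fixture, toy_coverage):
        bl = build_blocklist(toy_fixture.genes)
        regions = toy_fixture.transcript_regions()
        args = (toy_fixture.cnes(), bl, regions, toy_coverage.cage_tracks,
                toy_coverage.sample_tracks)
        base = len(run_caller(*args, CallerConfig()).tcnes)
        higher_tau = len(run_caller(*args, CallerConfig(threshold_quantile=0.4)).tcnes)
        more_recur = len(run_caller(*args, CallerConfig(detection_fraction=0.6)).tcnes)
        longer = len(run_caller(*args, CallerConfig(min_cne_length=500)).tcnes)
        assert higher_tau <= base
        assert more_recur <= base
        assert longer <= base

    def test_audit_covers_all_candidates(self, toy_fixture, toy_coverage):
        bl = build_blocklist(toy_fixture.genes)
        res = run_caller(toy_fixture.cnes(), bl, toy_fixture.transcript_regions(),
                         toy_coverage.cage_tracks, toy_coverage.sample_tracks)
        table = res.audit_table()
        expected = sum(1 for c in toy_fixture.cnes() if c.length > 200)
        assert len(table) == expected
        assert table["is_tcne"].sum() == len(res.tcnes)
        assert (table["length"] > 200).all()
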