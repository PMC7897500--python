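"""Filters, junction calling, episome gate, clustering, TSD estimation."""

import numpy as np
import pytest

from lvis import align, iscall, simulate
from lvis._util import revcomp
from lvis.model import ArmSpec, arm_specs
from lvis.seqio import LongRead


def _read(rid, length, q):
    return LongRead(rid, "A" * length, [q] * length)


class TestQualityFilter:
    def test_high_quality_kept(self):
        kept, dropped = iscall.quality_filter([_read("r", 100, 40)])
        assert len(kept) == 1 and dropped == 0

    def test_boundary_mean_q9_dropped(self):
        # the cutoff is strictly greater-than
        kept, dropped = iscall.quality_filter([_read("r", 100, 9)])
        assert kept == [] and dropped == 1

    def test_mixed_set_matches_hand_tally(self):
        reads = [
            LongRead("a", "ACGT", [8, 9, 10, 9]),    # mean 9.0 -> dropped
            LongRead("b", "ACGT", [9, 9, 10, 10]),   # mean 9.5 -> kept
            LongRead("c", "ACGT", [2, 2, 2, 2]),     # mean 2.0 -> dropped
            LongRead("d", "ACGT", [40, 0, 0, 0]),    # mean 10.0 -> kept
        ]
        kept, dropped = iscall.quality_filter(reads)
        assert [r.id for r in kept] == ["b", "d"]
        assert dropped == 2


def _specs(arm_lengths=(700, 950, 800, 600)):
    return [
        ArmSpec(arm="left", cut_position=al, arm_length=al,
                outward_direction="toward_left_terminus", guide_name=f"g{i}")
        for i, al in enumerate(arm_lengths)
    ]


class TestSizeSelect:
    def test_threshold_is_min_arm_plus_anchor(self):
        kept, dropped = iscall.size_select(
            [_read("short", 799, 40), _read("ok", 800, 40)],
            _specs(), min_host_anchor=200,
        )
        assert [r.id for r in kept] == ["ok"] and dropped == 1

    def test_read_shorter_than_shortest_arm_dropped(self):
        kept, _ = iscall.size_select([_read("tiny", 400, 40)], _specs())
        assert kept == []

    def test_empty_arm_specs_errors(self):
        with pytest.raises(ValueError, match="arm specs"):
            iscall.size_select([_read("r", 1000, 40)], [])

    def test_long_left_arm_raises_threshold(self):
        # a 3 kb arm forces junction reads over 3.2 kb
        specs = _specs((3000, 3100, 3200, 3050))
        kept, _ = iscall.size_select([_read("r", 3199, 40)], specs)
        assert kept == []
        kept, _ = iscall.size_select([_read("r", 3200, 40)], specs)
        assert len(kept) == 1


@pytest.fixture(scope="module")
def triage_env(construct):
    rng = np.random.default_rng(13)
    host = {"chrZ": "".join(rng.choice(list("ACGT"), 200_000))}
    return {
        "host": host,
        "host_index": align.build_index(host),
        "cidx": align.build_index({construct.name: construct.sequence}),
        "specs": arm_specs(construct),
    }


def _triage_one(seq, env):
    read = LongRead("x", seq, [40] * len(seq))
    return align.triage_read(read, env["cidx"], env["host_index"])


class TestCallJunction:
    def test_error_free_reads_call_at_truth(self, sim_error_free, construct,
                                            pipeline_error_free):
        truth = {(t.chromosome, t.position): t for t in sim_error_free.truth}
        assert len(pipeline_error_free.calls) == len(sim_error_free.reads)
        for call in pipeline_error_free.calls:
            t = truth[(call.chromosome,
                       call.position if call.boundary == "downstream"
                       else call.position - 6)]
            assert call.vector_strand_in_host == t.strand

    def test_lv_span_short_of_terminus_is_short_arm(self, construct, triage_env):
        left_cut = min(g.cut_position for g in construct.guides if g.arm == "left")
        # vector arm stops 300 bp short of the left terminus, then host
        seq = revcomp(construct.sequence[300:left_cut]) + triage_env["host"]["chrZ"][50_000:55_000]
        tr = _triage_one(seq, triage_env)
        assert tr.classification == "junction_candidate"
        call, reason = iscall.call_junction_ex(tr, construct, triage_env["specs"])
        assert call is None and reason == "short_arm"

    def test_read_not_starting_at_cut(self, construct, triage_env):
        left_cut = min(g.cut_position for g in construct.guides if g.arm == "left")
        seq = revcomp(construct.sequence[0 : left_cut - 200]) \
            + triage_env["host"]["chrZ"][50_000:55_000]
        tr = _triage_one(seq, triage_env)
        call, reason = iscall.call_junction_ex(tr, construct, triage_env["specs"])
        assert call is None and reason == "no_cut_site"

    def test_garbage_prefix_rejected(self, construct, triage_env):
        rng = np.random.default_rng(31)
        left_cut = min(g.cut_position for g in construct.guides if g.arm == "left")
        seq = "".join(rng.choice(list("ACGT"), 100)) \
            + revcomp(construct.sequence[0:left_cut]) \
            + triage_env["host"]["chrZ"][50_000:55_000]
        tr = _triage_one(seq, triage_env)
        call, reason = iscall.call_junction_ex(tr, construct, triage_env["specs"])
        assert call is None and reason == "no_cut_at_read_start"

    def test_minus_strand_site_positions_exact(self, construct):
        params = simulate.SimParams(
            n_chromosomes=1, chrom_length=250_000, n_genes=0, n_integrations=4,
            tsd_length=6, reads_per_end=2, error_rate=0.0, outward_bias=1.0,
            seed=17,
        )
        bundle = simulate.simulate_run(params, construct)
        assert any(t.strand == "-" for t in bundle.truth)
        host_index = align.build_index(bundle.host.chromosomes)
        res = iscall.run_pipeline(bundle.reads, construct, host_index)
        got = {(s.chromosome, s.position, s.strand) for s in res.sites}
        want = {(t.chromosome, t.position, t.strand) for t in bundle.truth}
        assert got == want


class TestDetectEpisome:
    def test_two_ltr_circle_read(self, construct, triage_env):
        left_cut = min(g.cut_position for g in construct.guides if g.arm == "left")
        circ = construct.sequence + construct.sequence
        L = left_cut + 1500
        seq = revcomp(circ[construct.length + left_cut - L : construct.length + left_cut])
        tr = _triage_one(seq, triage_env)
        assert tr.classification == "vector_only"
        assert iscall.classify_episome(tr, construct) == "circle_junction"

    def test_genuine_junction_read_not_episome(self, construct, triage_env):
        right_cut = min(g.cut_position for g in construct.guides if g.arm == "right")
        seq = construct.sequence[right_cut:] + triage_env["host"]["chrZ"][80_000:86_000]
        tr = _triage_one(seq, triage_env)
        assert tr.classification == "junction_candidate"
        assert not iscall.detect_episome(tr, construct)

    def test_read_ending_exactly_at_terminus_conservative(self, construct, triage_env):
        right_cut = min(g.cut_position for g in construct.guides if g.arm == "right")
        seq = construct.sequence[right_cut:]
        tr = _triage_one(seq, triage_env)
        assert tr.classification == "vector_only"
        assert iscall.classify_episome(tr, construct) == "too_short_to_judge"

    def test_unmappable_tail_beyond_terminus(self, construct, triage_env):
        rng = np.random.default_rng(41)
        right_cut = min(g.cut_position for g in construct.guides if g.arm == "right")
        seq = construct.sequence[right_cut:] + "".join(rng.choice(list("ACGT"), 1500))
        tr = _triage_one(seq, triage_env)
        assert iscall.classify_episome(tr, construct) == "no_host_anchor"

    def test_inward_truncated_read_not_episome(self, construct, triage_env):
        # stops 300 bp short of any terminus: not episomal, just structureless
        seq = construct.sequence[1000:-300]
        tr = _triage_one(seq, triage_env)
        assert tr.classification == "vector_only"
        assert iscall.classify_episome(tr, construct) is None


def _call(rid, pos, host_strand, vector_end, chrom="chr1"):
    return iscall.JunctionCall(
        read_id=rid, chromosome=chrom, position=pos, host_strand=host_strand,
        vector_end=vector_end, vector_strand_in_host="+", cut_site_used="g",
    )


class TestClusterCalls:
    def test_same_end_window_clustering(self):
        calls = [
            _call("a", 100, "+", "left_terminus"),
            _call("b", 103, "+", "left_terminus"),
            _call("c", 500, "+", "left_terminus"),
        ]
        sites = iscall.cluster_calls(calls, merge_window=10)
        assert sorted(s.support for s in sites) == [1, 2]
        assert all(not s.bidirectional for s in sites)

    def test_bidirectional_pair_offset_by_tsd(self):
        calls = [
            _call("a", 1000, "+", "left_terminus"),
            _call("b", 1006, "-", "right_terminus"),
        ]
        (site,) = iscall.cluster_calls(calls)
        assert site.bidirectional
        assert site.position == 1000
        assert site.support == 2
        assert site.tsd_estimate == 6

    def test_single_call_single_site(self):
        (site,) = iscall.cluster_calls([_call("a", 42, "+", "left_terminus")])
        assert site.support == 1 and not site.bidirectional
        assert site.tsd_estimate is None

    def test_different_chromosomes_never_merge(self):
        calls = [
            _call("a", 100, "+", "left_terminus", chrom="chr1"),
            _call("b", 100, "+", "left_terminus", chrom="chr2"),
        ]
        assert len(iscall.cluster_calls(calls)) == 2

    def test_far_opposite_end_calls_not_merged(self):
        calls = [
            _call("a", 1000, "+", "left_terminus"),
            _call("b", 1100, "-", "right_terminus"),
        ]
        assert len(iscall.cluster_calls(calls)) == 2

    def test_support_sum_equals_call_count(self, pipeline_error_free):
        assert sum(s.support for s in pipeline_error_free.sites) == len(
            pipeline_error_free.calls
        )


class TestEstimateTsd:
    @pytest.mark.parametrize("tsd", [0, 5, 6])
    def test_simulated_tsd_recovered_exactly(self, construct, tsd):
        params = simulate.SimParams(
            n_chromosomes=1, chrom_length=150_000, n_genes=0, n_integrations=2,
            tsd_length=tsd, reads_per_end=2, error_rate=0.0, outward_bias=1.0,
            seed=23 + tsd,
        )
        bundle = simulate.simulate_run(params, construct)
        host_index = align.build_index(bundle.host.chromosomes)
        res = iscall.run_pipeline(bundle.reads, construct, host_index)
        assert len(res.sites) == 2
        for s in res.sites:
            assert s.bidirectional and s.tsd_estimate == tsd

    def test_unidirectional_site_has_no_estimate(self):
        (site,) = iscall.cluster_calls([_call("a", 7, "+", "left_terminus")])
        assert iscall.estimate_tsd(site) is None


class TestPipelineConservation:
    def test_every_read_in_exactly_one_bucket(self, sim_error_free, pipeline_error_free):
        res = pipeline_error_free
        assert res.conserved()
        assert set(res.decisions) == {r.id for r in sim_error_free.reads}

    def test_error_free_round_trip_recovers_all_truth(self, sim_error_free,
                                                      pipeline_error_free):
        got = {(s.chromosome, s.position) for s in pipeline_error_free.sites}
        want = {(t.chromosome, t.position) for t in sim_error_free.truth}
        assert got == want
        for s in pipeline_error_free.sites:
            assert s.bidirectional and s.tsd_estimate == 6

    def test_mixed_inputs_all_bucketed(self, construct):
        params = simulate.SimParams(
            n_chromosomes=1, chrom_length=150_000, n_genes=0, n_integrations=2,
            tsd_length=6, reads_per_end=2, error_rate=0.05, outward_bias=0.7,
            background_fraction=0.25, circle_fraction=0.25, seed=29,
        )
        bundle = simulate.simulate_run(params, construct)
        # one read below the quality cutoff
        bad = LongRead("lowq", bundle.reads[0].sequence,
                       [5] * len(bundle.reads[0]))
        reads = bundle.reads + [bad]
        host_index = align.build_index(bundle.host.chromosomes)
        res = iscall.run_pipeline(reads, construct, host_index)
        assert res.conserved()
        assert res.counts["dropped_quality"] == 1
        assert res.n_input == len(reads)
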