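"""CNVR merging, classification, summaries and group presence."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from _oracles import connected_components_regions
from cnvpop import CnvCall, Cnvr, classify_cnvr, make_layout, merge_calls, summarize
from cnvpop.cnvr import group_presence, individual_copy_numbers, read_cnvrs, write_cnvrs


def call(ind="s0", chrom="chr1", start=100, end=500, ctype="deletion", cn=1.0):
    return CnvCall(ind, chrom, start, end, ctype, cn, 1e-5, 0.1)


class TestMergeCalls:
    def test_single_call_keeps_coordinates(self):
        [cnvr] = merge_calls([call()])
        assert (cnvr.chrom, cnvr.start, cnvr.end) == ("chr1", 100, 500)
        assert cnvr.supporting_calls == (call(),)

    def test_overlapping_calls_merge_to_union(self):
        [cnvr] = merge_calls([call("a", end=500), call("b", start=400, end=900)])
        assert (cnvr.start, cnvr.end) == (100, 900)
        assert set(cnvr.individuals) == {"a", "b"}

    def test_abutting_calls_do_not_merge(self):
        cnvrs = merge_calls(
            [call("a", start=100, end=200), call("b", start=200, end=300)]
        )
        assert len(cnvrs) == 2

    def test_malformed_interval_identified(self):
        bad = SimpleNamespace(
            individual_id="s0", chrom="chr1", start=500, end=100,
            call_type="deletion", cn=1.0,
        )
        with pytest.raises(ValueError, match="malformed"):
            merge_calls([call(), bad])

    def test_matches_brute_force_components(self, rng):
        for _ in range(50):
            n = rng.integers(1, 50)
            starts = rng.integers(0, 9_500, size=n)
            lengths = rng.integers(50, 600, size=n)
            calls = [
                call(f"s{i % 5}", start=int(s), end=int(s + l))
                for i, (s, l) in enumerate(zip(starts, lengths))
            ]
            expected, _labels = connected_components_regions(
                [(c.chrom, c.start, c.end) for c in calls]
            )
            got = [(c.chrom, c.start, c.end) for c in merge_calls(calls)]
            assert sorted(got) == expected
            # conservation: every call in exactly one CNVR
            assert sum(len(c.supporting_calls) for c in merge_calls(calls)) == n

    def test_merge_is_idempotent_and_order_invariant(self, rng):
        starts = rng.integers(0, 9_000, size=30)
        calls = [
            call(f"s{i}", start=int(s), end=int(s + 400)) for i, s in enumerate(starts)
        ]
        first = merge_calls(calls)
        shuffled = list(calls)
        rng.shuffle(shuffled)
        again = merge_calls(shuffled)
        assert [(c.chrom, c.start, c.end) for c in first] == [
            (c.chrom, c.start, c.end) for c in again
        ]
        # re-merging the regions themselves changes nothing
        region_calls = [
            call("x", start=c.start, end=c.end) for c in first
        ]
        assert [(c.start, c.end) for c in merge_calls(region_calls)] == [
            (c.start, c.end) for c in first
        ]

    def test_span_bounds_member_calls(self, rng):
        starts = rng.integers(0, 9_000, size=40)
        calls = [call("s0", start=int(s), end=int(s + rng.integers(100, 800)))
                 for s in starts]
        for cnvr in merge_calls(calls):
            assert cnvr.length >= max(c.size for c in cnvr.supporting_calls)
            assert cnvr.length <= sum(c.size for c in cnvr.supporting_calls)

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError, match="missing from population"):
            merge_calls([call("stranger")], population={"s0": "A"})

    def test_min_support_drops_singleton_regions(self):
        calls = [
            call("a", start=100, end=500),
            call("b", start=400, end=900),
            call("c", start=5000, end=6000),  # supported by one individual
        ]
        assert len(merge_calls(calls)) == 2
        kept = merge_calls(calls, min_support=2)
        assert [(c.start, c.end) for c in kept] == [(100, 900)]
        assert kept[0].id == "CNVR_00001"  # ids renumbered after the cut


class TestClassifyCnvr:
    def build(self, cns, ctypes=None):
        calls = tuple(
            call(f"s{i}", ctype=(ctypes[i] if ctypes else "deletion"), cn=cn)
            for i, cn in enumerate(cns)
        )
        return Cnvr("r1", "chr1", 100, 500, "deletion", calls)

    @pytest.mark.parametrize(
        "cn, state",
        [(0.3, "deleted"), (0.4, "conserved"), (1.6, "conserved"), (1.61, "duplicated")],
    )
    def test_state_thresholds(self, cn, state):
        cls = classify_cnvr(self.build([cn]))
        assert cls.states["s0"] == state

    def test_mixed_states_give_both(self):
        cls = classify_cnvr(self.build([0.2, 3.1], ctypes=["deletion", "duplication"]))
        assert cls.region_type == "both"

    def test_all_conserved_falls_back_to_call_types(self):
        cls = classify_cnvr(self.build([1.0, 1.2]))
        assert set(cls.states.values()) == {"conserved"}
        assert cls.region_type == "deletion"

    def test_negative_cn_rejected(self):
        bad_call = SimpleNamespace(individual_id="s0", cn=-1.0, size=100)
        bad = Cnvr("r2", "chr1", 0, 100, "deletion", ())
        object.__setattr__(bad, "supporting_calls", (bad_call,))
        with pytest.raises(ValueError, match="negative"):
            individual_copy_numbers(bad)

    def test_length_weighted_mean_cn(self):
        calls = (
            call("s0", start=0, end=300, cn=1.0),
            call("s0", start=200, end=300, cn=4.0),
        )
        cnvr = Cnvr("r1", "chr1", 0, 300, "both", calls)
        cns = individual_copy_numbers(cnvr)
        assert cns["s0"] == pytest.approx((300 * 1.0 + 100 * 4.0) / 400)


class TestSummarize:
    def test_lengths_and_genome_fraction(self):
        layout = make_layout([("chr1", 1_000_000)], 100)
        cnvrs = [
            Cnvr("r1", "chr1", 0, 1000, "deletion", ()),
            Cnvr("r2", "chr1", 5000, 7000, "deletion", ()),
            Cnvr("r3", "chr1", 10_000, 13_000, "duplication", ()),
        ]
        s = summarize(cnvrs, layout)
        assert s.n_cnvrs == 3
        assert s.total_length_mb == 0.01  # 6 kb, 2 decimals
        assert s.mean_length_kb == 2.0
        assert s.genome_fraction_pct == 0.60
        assert s.n_deletion == 2 and s.n_duplication == 1 and s.n_both == 0

    def test_counts_proportional_to_length_give_r2_one(self):
        layout = make_layout(
            [("chr1", 400_000), ("chr2", 200_000), ("chr3", 100_000)], 100
        )
        cnvrs = []
        for chrom, n in [("chr1", 4), ("chr2", 2), ("chr3", 1)]:
            for i in range(n):
                cnvrs.append(
                    Cnvr(f"{chrom}_{i}", chrom, i * 2000, i * 2000 + 1000, "deletion", ())
                )
        s = summarize(cnvrs, layout)
        assert s.count_length_r2 == pytest.approx(1.0, abs=1e-12)

    def test_empty_summary_is_all_zero_with_undefined_r2(self):
        s = summarize([], make_layout([("chr1", 10_000)], 100))
        assert s.n_cnvrs == 0
        assert s.total_length_mb == 0.0
        assert math.isnan(s.count_length_r2)
        assert math.isnan(s.mean_length_kb)

    def test_type_counts_partition_total(self, rng):
        types = rng.choice(["deletion", "duplication", "both"], size=25)
        cnvrs = [
            Cnvr(f"r{i}", "chr1", i * 2000, i * 2000 + 1000, t, ())
            for i, t in enumerate(types)
        ]
        s = summarize(cnvrs)
        assert s.n_deletion + s.n_duplication + s.n_both == s.n_cnvrs


class TestGroupPresence:
    def region(self, rid, inds, start):
        calls = tuple(call(i, start=start, end=start + 1000) for i in inds)
        return Cnvr(rid, "chr1", start, start + 1000, "deletion", calls)

    def test_single_group_region(self):
        pop = {"a1": "A", "a2": "A", "b1": "B"}
        pres = group_presence([self.region("r1", ["a1", "a2"], 0)], pop)
        assert pres.per_group == {"A": {"r1"}, "B": set()}
        assert pres.venn_cells == {frozenset({"A"}): 1}

    def test_four_group_shared_cell(self):
        pop = {f"{g}1": g for g in "ABCD"}
        pres = group_presence(
            [self.region("r1", ["A1", "B1", "C1", "D1"], 0)], pop
        )
        assert pres.shared_by_all() == 1

    def test_unknown_individual_rejected(self):
        with pytest.raises(KeyError):
            group_presence([self.region("r1", ["zz"], 0)], {"a1": "A"})

    def test_cells_match_brute_force_and_partition(self, rng):
        groups = ["A", "B", "C", "D"]
        pop = {f"i{k}": groups[k % 4] for k in range(12)}
        regions = []
        for i in range(30):
            n = int(rng.integers(1, 6))
            inds = list(rng.choice(sorted(pop), size=n, replace=False))
            regions.append(self.region(f"r{i}", inds, i * 2000))
        pres = group_presence(regions, pop)
        assert sum(pres.venn_cells.values()) == len(regions)
        # brute-force set arithmetic per region
        for r in regions:
            expected = frozenset(pop[i] for i in r.individuals)
            for g in groups:
                assert (r.id in pres.per_group[g]) == (g in expected)


def test_cnvr_io_round_trip(tmp_path):
    cnvrs = [
        Cnvr("r1", "chr1", 0, 1000, "deletion",
             (call("s0", end=1000),), frozenset({"A"})),
        Cnvr("r2", "chr2", 500, 2500, "both",
             (call("s1", chrom="chr2", start=500, end=2500),), frozenset({"A", "B"})),
    ]
    write_cnvrs(cnvrs, tmp_path / "cnvrs.tsv")
    back = read_cnvrs(tmp_path / "cnvrs.tsv")
    assert [(c.id, c.chrom, c.start, c.end, c.region_type, c.groups_present)
            for c in back] == [
        ("r1", "chr1", 0, 1000, "deletion", frozenset({"A"})),
        ("r2", "chr2", 500, 2500, "both", frozenset({"A", "B"})),
    ]
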