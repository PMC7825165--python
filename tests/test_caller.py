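"""Caller behaviour: normalization, segmentation, genotyping, filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvpop import (
    CnvCall,
    PopulationDesign,
    call_cnvs,
    call_from_segments,
    filter_calls,
    make_layout,
    normalize,
    plant_truth,
    segment,
    simulate_depth,
)
from cnvpop.synthetic import DepthProfile


def constant_profile(value: int, n_windows: int = 2000, chrom: str = "chr1"):
    layout = make_layout([(chrom, n_windows * 100)], 100)
    counts = {chrom: np.full(n_windows, value, dtype=np.int64)}
    q0 = {chrom: np.zeros(n_windows)}
    return DepthProfile("toy", layout, counts, q0)


def profile_from_counts(counts: np.ndarray, chrom: str = "chr1"):
    layout = make_layout([(chrom, len(counts) * 100)], 100)
    return DepthProfile(
        "toy",
        layout,
        {chrom: counts.astype(np.int64)},
        {chrom: np.zeros(len(counts))},
    )


class TestNormalize:
    def test_constant_counts_give_rd_two(self):
        norm = normalize(constant_profile(30))
        np.testing.assert_allclose(norm.rd["chr1"], 2.0)

    def test_half_depth_region_has_rd_one(self):
        counts = np.full(5000, 30)
        counts[1000:1050] = 15  # small enough to barely move the mean
        norm = normalize(profile_from_counts(counts))
        np.testing.assert_allclose(norm.rd["chr1"][1000:1050], 1.0, atol=0.02)

    def test_plain_mean_rescaling_is_exact(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(30, size=4000)
        norm = normalize(profile_from_counts(counts), trimmed=False)
        assert abs(norm.genome_mean() - 2.0) < 1e-9

    def test_trimmed_mean_matches_direct_arithmetic(self):
        # 20-window toy track, 10% cut from each tail: drop the 2 smallest
        # and 2 largest values, average the middle 16.
        values = np.array(
            [12, 33, 29, 31, 30, 28, 35, 27, 30, 31,
             90, 29, 32, 28, 30, 31, 29, 30, 5, 30]
        )
        layout = make_layout([("chr1", 10_000), ("chr2", 2_000)], 100)
        profile = DepthProfile(
            "toy",
            layout,
            {"chr1": np.repeat(values, 5), "chr2": np.full(20, 30)},
            {"chr1": np.zeros(100), "chr2": np.zeros(20)},
        )
        pooled = np.concatenate([np.repeat(values, 5), np.full(20, 30)])
        expected_mean = np.sort(pooled)[12:-12].mean()  # trim 10% of 120
        norm = normalize(profile, trimmed=True)
        assert norm.global_mean_raw == pytest.approx(expected_mean, abs=1e-12)
        np.testing.assert_allclose(
            norm.rd["chr2"], 2 * 30 / expected_mean, atol=1e-12
        )

    def test_all_zero_track_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize(constant_profile(0))

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="100 windows"):
            normalize(constant_profile(30, n_windows=50))

    def test_gc_correction_flattens_wave(self):
        design = PopulationDesign(individuals=(("s0", "A"),), seed=9,
                                  n_shared_cnvs=0, n_group_specific_cnvs=0)
        layout = make_layout([("chr1", 400_000)], 100)
        profile = simulate_depth(layout, [], "s0", design, gc_bias=(0.4, 400))
        raw = normalize(profile, gc_correct=False)
        fixed = normalize(profile, gc_correct=True)
        wave = np.sin(2 * np.pi * np.arange(4000) / 400)
        assert abs(np.corrcoef(fixed.rd["chr1"], wave)[0, 1]) < 0.2
        assert np.corrcoef(raw.rd["chr1"], wave)[0, 1] > 0.5


class TestSegment:
    def test_constant_track_one_segment_per_chromosome(self):
        layout = make_layout([("chr1", 50_000), ("chr2", 30_000)], 100)
        profile = DepthProfile(
            "toy",
            layout,
            {"chr1": np.full(500, 30), "chr2": np.full(300, 30)},
            {"chr1": np.zeros(500), "chr2": np.zeros(300)},
        )
        segs = segment(normalize(profile))
        assert [(s.chrom, s.start, s.end) for s in segs] == [
            ("chr1", 0, 50_000),
            ("chr2", 0, 30_000),
        ]

    def test_noise_free_step_track_recovers_breakpoints(self):
        counts = np.concatenate([np.full(50, 30), np.full(20, 15), np.full(50, 30)])
        segs = segment(normalize(profile_from_counts(counts), trimmed=False))
        assert len(segs) == 3
        assert abs(segs[0].end - 5000) <= 100  # +- 1 window
        assert abs(segs[1].end - 7000) <= 100
        assert segs[1].mean_rd == pytest.approx(1.0, abs=0.1)

    def test_noisy_step_recovery_within_one_window(self, rng):
        counts = rng.poisson(
            np.concatenate([np.full(200, 30), np.full(30, 15), np.full(200, 30)])
        )
        segs = segment(normalize(profile_from_counts(counts)))
        dels = [s for s in segs if s.mean_rd < 1.5]
        assert len(dels) == 1
        assert abs(dels[0].start - 20_000) <= 200
        assert abs(dels[0].end - 23_000) <= 200

    def test_segments_tile_each_chromosome(self, rng):
        counts = rng.poisson(30, size=3000)
        counts[400:450] = rng.poisson(60, size=50)
        norm = normalize(profile_from_counts(counts))
        segs = segment(norm)
        segs.sort(key=lambda s: s.start)
        assert segs[0].start == 0
        assert segs[-1].end == 300_000
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start
        assert all(s.end - s.start == s.n_windows * 100 for s in segs)

    def test_deterministic(self, rng):
        counts = rng.poisson(30, size=2000)
        norm = normalize(profile_from_counts(counts))
        assert segment(norm) == segment(norm)

    def test_empty_chromosome_handled(self):
        layout = make_layout([("chr1", 20_000)], 100)
        profile = DepthProfile(
            "toy", layout, {"chr1": np.full(200, 30)}, {"chr1": np.zeros(200)}
        )
        segs = segment(normalize(profile))
        assert len(segs) == 1


class TestCallFromSegments:
    def _sim(self, seed, **overrides):
        layout = make_layout([("chr1", 2_000_000)], 100)
        params = dict(
            individuals=(("s0", "A"), ("s1", "A")),
            seed=seed,
            n_shared_cnvs=6,
            n_group_specific_cnvs=0,
            shared_frequency=1.0,
        )
        params.update(overrides)
        design = PopulationDesign(**params)
        truth = plant_truth(layout, design)
        profile = simulate_depth(layout, truth, "s0", design)
        return layout, truth, profile

    def test_diploid_segment_not_called(self):
        norm = normalize(constant_profile(30))
        segs = segment(norm)
        assert call_from_segments(segs, norm, constant_profile(30)) == []

    @pytest.mark.parametrize(
        "cn_choices, dup_fraction, expected_cn",
        [((0,), 0.0, 0.0), ((3,), 1.0, 3.0)],
    )
    def test_planted_cn_recovered_within_tolerance(
        self, cn_choices, dup_fraction, expected_cn
    ):
        key = "duplication_cn_choices" if dup_fraction else "deletion_cn_choices"
        layout, truth, profile = self._sim(
            21, duplication_fraction=dup_fraction, **{key: cn_choices}
        )
        calls = call_cnvs(profile)
        mine = [t for t in truth if t.individual_id == "s0"]
        for t in mine:
            matched = [c for c in calls if c.start < t.end and c.end > t.start]
            assert matched, f"planted CNV {t} not recovered"
            best = max(matched, key=lambda c: c.size)
            assert best.cn == pytest.approx(expected_cn, abs=0.3)
            expected_type = "deletion" if expected_cn < 2 else "duplication"
            assert best.call_type == expected_type

    def test_single_window_segment_gets_e_val_one_and_flag(self):
        from cnvpop.caller import Segment

        profile = constant_profile(30)
        norm = normalize(profile)
        seg = Segment("chr1", 0, 100, 0.5, 1)
        calls = call_from_segments([seg], norm, profile)
        assert calls[0].e_val == 1.0
        assert "single_window" in calls[0].flags

    def test_q0_is_read_weighted(self):
        profile = constant_profile(30, n_windows=200)
        profile.q0_fraction["chr1"][:10] = 0.9
        norm = normalize(profile)
        from cnvpop.caller import Segment

        seg = Segment("chr1", 0, 2000, 1.0, 20)  # half the windows are dirty
        call = call_from_segments([seg], norm, profile)[0]
        assert call.q0 == pytest.approx(0.45, abs=1e-9)


class TestFilterCalls:
    @staticmethod
    def call(size=1500, e_val=1e-5, q0=0.1) -> CnvCall:
        return CnvCall("s0", "chr1", 10_000, 10_000 + size, "deletion", 1.0, e_val, q0)

    def test_paper_filter_examples(self):
        kept = filter_calls(
            [
                self.call(size=800),  # removed: size
                self.call(e_val=0.02),  # removed: significance
                self.call(q0=0.6),  # removed: q0
                self.call(),  # survives
            ]
        )
        assert kept == [self.call()]

    def test_size_bound_is_strict(self):
        assert filter_calls([self.call(size=1000)]) == []
        assert filter_calls([self.call(size=1001)]) != []

    @given(
        st.lists(
            st.tuples(
                st.integers(100, 3000),
                st.floats(0, 1, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
            ),
            max_size=30,
        )
    )
    def test_filter_is_a_pure_predicate(self, specs):
        calls = [self.call(size=s, e_val=e, q0=q) for s, e, q in specs]
        once = filter_calls(calls)
        assert filter_calls(once) == once
        assert len(once) <= len(calls)


class TestDiploidFalseCalls:
    def test_false_discovery_rate_below_one_per_ten_megabases(self):
        total_calls = 0
        total_mb = 0
        for seed in range(4):
            layout = make_layout([("chr1", 5_000_000)], 100)
            design = PopulationDesign(
                individuals=(("s0", "A"),), seed=seed,
                n_shared_cnvs=0, n_group_specific_cnvs=0,
            )
            profile = simulate_depth(layout, [], "s0", design)
            total_calls += len(call_cnvs(profile))
            total_mb += 5
        assert total_calls / total_mb * 10 <= 1.0
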