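import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rigstruct.cnv import (
    CNVThresholds,
    arm_alteration_frequencies,
    call_gene_cnv,
    classify_segment,
    classify_segments,
    cnv_count_per_sample,
    split_at_centromere,
)
from rigstruct.genome import GeneLocus
from rigstruct.model import CNSegment, InputError

from conftest import make_segment


class TestClassifySegment:
    def test_focal_gain(self, toy_genome):
        # 2 Mb on a 60 Mb arm at +0.5
        [call] = classify_segment(make_segment(0, 2_000_000, 0.5), toy_genome)
        assert call.direction == "gain" and call.extent == "focal"
        assert call.arm == "p"

    def test_neutral(self, toy_genome):
        [call] = classify_segment(make_segment(0, 2_000_000, 0.0), toy_genome)
        assert call.direction == "neutral" and call.extent == "not-applicable"

    def test_broad_loss(self, toy_genome):
        # 80% of the 60 Mb p arm at -0.3
        [call] = classify_segment(make_segment(0, 48_000_000, -0.3), toy_genome)
        assert call.direction == "loss" and call.extent == "broad"
        assert call.arm_fraction == pytest.approx(0.8)

    @pytest.mark.parametrize(
        "seg_mean,direction",
        [(0.2, "gain"), (0.19999, "neutral"), (-0.2, "loss"), (-0.19999, "neutral")],
    )
    def test_inclusive_thresholds(self, toy_genome, seg_mean, direction):
        [call] = classify_segment(make_segment(0, 1000, seg_mean), toy_genome)
        assert call.direction == direction

    def test_wgs_preset(self, toy_genome):
        [call] = classify_segment(
            make_segment(0, 1000, 0.22), toy_genome, CNVThresholds.wgs_preset()
        )
        assert call.direction == "neutral"

    def test_3mb_mode(self, toy_genome):
        t = CNVThresholds(focal_mode="3mb")
        [small] = classify_segment(make_segment(0, 3_000_000, 0.5), toy_genome, t)
        [large] = classify_segment(make_segment(0, 3_000_001, 0.5), toy_genome, t)
        assert small.extent == "focal" and large.extent == "broad"

    def test_centromere_spanning_split(self, toy_genome):
        calls = classify_segment(make_segment(50_000_000, 70_000_000, 0.4), toy_genome)
        assert [c.arm for c in calls] == ["p", "q"]
        assert calls[0].segment.end == 60_000_000
        assert calls[1].segment.start == 60_000_000
        assert all(c.direction == "gain" for c in calls)

    def test_out_of_bounds_rejected(self, toy_genome):
        with pytest.raises(InputError):
            classify_segment(make_segment(0, 200_000_000, 0.0), toy_genome)
        with pytest.raises(InputError):
            classify_segment(make_segment(0, 10, 0.0, chrom="chrZ"), toy_genome)

    @given(st.floats(-3, 3), st.floats(0.05, 1.0))
    @settings(max_examples=50)
    def test_total_function(self, toy_genome, seg_mean, frac):
        end = max(1, int(frac * 60_000_000))
        [call] = classify_segment(make_segment(0, end, seg_mean), toy_genome)
        assert call.direction in ("gain", "loss", "neutral")
        assert call.extent in ("focal", "broad", "not-applicable")
        assert 0 < call.arm_fraction <= 1

    @given(st.floats(-1, 1), st.floats(0.21, 1.0))
    @settings(max_examples=50)
    def test_threshold_monotonicity(self, toy_genome, seg_mean, higher_gain):
        seg = make_segment(0, 1000, seg_mean)
        strict = classify_segment(seg, toy_genome, CNVThresholds(gain=higher_gain))[0]
        lax = classify_segment(seg, toy_genome)[0]
        if strict.direction == "gain":
            assert lax.direction == "gain"

    @given(st.floats(-1, 1), st.integers(1, 59_999_999))
    @settings(max_examples=50)
    def test_split_invariance(self, toy_genome, seg_mean, cut):
        seg = make_segment(0, 60_000_000, seg_mean)
        whole = classify_segment(seg, toy_genome)[0]
        left = classify_segment(make_segment(0, cut, seg_mean), toy_genome)[0]
        right = classify_segment(make_segment(cut, 60_000_000, seg_mean), toy_genome)[0]
        assert left.direction == right.direction == whole.direction


class TestArmFrequencies:
    def _cohort(self, toy_genome, n=25, n_loss=10):
        calls = []
        for i in range(n):
            sample = f"S{i}"
            seg_mean = -0.5 if i < n_loss else 0.0
            seg = make_segment(0, 48_000_000, seg_mean, sample=sample)
            calls.extend(classify_segment(seg, toy_genome))
        return calls

    def test_forty_percent_1p_loss(self, toy_genome):
        freq = arm_alteration_frequencies(self._cohort(toy_genome))
        row = freq[(freq.arm == "p") & (freq.direction == "loss")].iloc[0]
        assert row.n_samples == 10 and row.n_cohort == 25
        assert row.frequency == pytest.approx(0.40)

    def test_no_alterations(self, toy_genome):
        calls = classify_segments(
            [make_segment(0, 1000, 0.0, sample=f"S{i}") for i in range(3)], toy_genome
        )
        assert arm_alteration_frequencies(calls).empty

    def test_reorder_invariance(self, toy_genome):
        calls = self._cohort(toy_genome)
        fwd = arm_alteration_frequencies(calls)
        rev = arm_alteration_frequencies(calls[::-1])
        assert fwd.equals(rev)

    def test_empty_cohort_rejected(self):
        with pytest.raises(InputError):
            arm_alteration_frequencies([])

    def test_matches_brute_force_scan(self, toy_genome, rng):
        # oracle: per-sample scan over raw calls
        calls = []
        for i in range(8):
            for _ in range(rng.integers(1, 4)):
                start = int(rng.integers(0, 30_000_000))
                end = start + int(rng.integers(1_000_000, 30_000_000))
                seg = make_segment(start, end, float(rng.normal(0, 0.5)), sample=f"S{i}")
                calls.extend(classify_segment(seg, toy_genome))
        freq = arm_alteration_frequencies(calls)
        samples = {c.segment.sample for c in calls}
        for _, row in freq.iterrows():
            expected = sum(
                1
                for s in samples
                if any(
                    c.segment.sample == s
                    and c.arm == row.arm
                    and c.direction == row.direction
                    and c.extent == "broad"
                    for c in calls
                )
            )
            assert row.n_samples == expected


class TestGeneCalls:
    gene = GeneLocus("PDGFRA", "chr1", 10_000_000, 10_100_000)

    def test_amplification(self):
        segs = [make_segment(9_000_000, 11_000_000, 2.5)]
        assert call_gene_cnv(segs, self.gene).call == "amplification"

    def test_neutral_coverage(self):
        segs = [make_segment(9_000_000, 11_000_000, 0.0)]
        call = call_gene_cnv(segs, self.gene)
        assert call.call == "neutral" and not call.no_coverage

    def test_no_coverage_flag(self):
        segs = [make_segment(50_000_000, 51_000_000, 1.0)]
        call = call_gene_cnv(segs, self.gene)
        assert call.call == "neutral" and call.no_coverage

    def test_max_abs_seg_mean_rule(self):
        segs = [
            make_segment(9_000_000, 10_050_000, 0.1),
            make_segment(10_050_000, 11_000_000, -0.4),
        ]
        assert call_gene_cnv(segs, self.gene).call == "loss"

    def test_gain_below_amplification(self):
        segs = [make_segment(9_000_000, 11_000_000, 1.0)]
        assert call_gene_cnv(segs, self.gene).call == "gain"


class TestCNVCount:
    def test_empty(self):
        assert cnv_count_per_sample([]).total == 0

    def test_three_gains_two_losses(self, toy_genome):
        segs = [make_segment(i * 10_000_000, i * 10_000_000 + 1_000_000, m)
                for i, m in enumerate([0.5, 0.5, 0.5, -0.5, -0.5, 0.0])]
        calls = classify_segments(segs, toy_genome)
        count = cnv_count_per_sample(calls)
        assert (count.gains, count.losses, count.total) == (3, 2, 5)

    def test_matches_brute_force_filter(self, toy_genome, rng):
        segs = [
            make_segment(
                int(i * 2_000_000), int(i * 2_000_000 + 1_000_000), float(rng.normal(0, 0.4))
            )
            for i in range(20)
        ]
        calls = classify_segments(segs, toy_genome)
        expected = len([c for c in calls if c.direction != "neutral"])
        assert cnv_count_per_sample(calls).total == expected
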