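import numpy as np
import pytest

from rigstruct.model import DegenerateSimulationError, InputError
from rigstruct.stats import median_and_range
from rigstruct.synthetic import (
    SimulationConfig,
    sample_rng,
    simulate_chromothriptic_chromosome,
    simulate_clinical_table,
    simulate_cohort,
    simulate_eccdna,
    simulate_progressive_rearrangement,
    simulate_variant_calls,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        SimulationConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fragment_retention_prob": 1.5},
            {"somatic_fold_b": 0.0},
            {"n_breakpoints": 5},
            {"n_fragments": 6},
            {"spectrum": (0.5, 0.5, 0, 0, 0, 0.1)},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(InputError):
            SimulationConfig(**kwargs)


class TestChromothripticChromosome:
    def test_seeded_determinism(self):
        cfg = SimulationConfig()
        out1 = simulate_chromothriptic_chromosome(cfg, "chr2", sample_rng(3, 0))
        out2 = simulate_chromothriptic_chromosome(cfg, "chr2", sample_rng(3, 0))
        assert out1[0] == out2[0] and out1[1] == out2[1]

    def test_segments_tile_without_overlap(self):
        cfg = SimulationConfig()
        segs, _, truth = simulate_chromothriptic_chromosome(cfg, "chr5", sample_rng(1, 0))
        ordered = sorted(segs, key=lambda s: s.start)
        for a, b in zip(ordered[:-1], ordered[1:]):
            assert a.end == b.start
        lo, hi = truth["window"]
        assert ordered[0].start >= lo and ordered[-1].end <= hi

    def test_two_state_profile(self):
        cfg = SimulationConfig()
        segs, _, truth = simulate_chromothriptic_chromosome(cfg, "chr5", sample_rng(1, 0))
        for seg, kept in zip(segs, truth["retained"]):
            target = 0.0 if kept else -1.0
            assert abs(seg.seg_mean - target) < 0.3

    def test_breakends_on_segment_boundaries(self):
        cfg = SimulationConfig()
        segs, joins, _ = simulate_chromothriptic_chromosome(cfg, "chr7", sample_rng(2, 0))
        boundaries = {s.start for s in segs} | {s.end for s in segs}
        for j in joins:
            assert j.pos_a in boundaries and j.pos_b in boundaries

    def test_switch_fraction_over_seeds(self):
        # retention 0.5 -> adjacent-state switch probability 0.5
        cfg = SimulationConfig(fragment_retention_prob=0.5, n_breakpoints=30)
        fractions = []
        for seed in range(100):
            _, _, truth = simulate_chromothriptic_chromosome(cfg, "chr2", sample_rng(seed, 0))
            kept = truth["retained"]
            switches = sum(1 for a, b in zip(kept, kept[1:]) if a != b)
            fractions.append(switches / (len(kept) - 1))
        assert np.mean(fractions) >= 0.4

    def test_degenerate_retention_rejected(self):
        cfg = SimulationConfig(fragment_retention_prob=0.0)
        with pytest.raises(DegenerateSimulationError):
            simulate_chromothriptic_chromosome(cfg, "chr1", sample_rng(0, 0))

    def test_unknown_chromosome(self):
        with pytest.raises(InputError):
            simulate_chromothriptic_chromosome(SimulationConfig(), "chrZ", sample_rng(0, 0))


class TestProgressive:
    def test_multi_state_profile(self):
        cfg = SimulationConfig(n_events=8)
        segs, _, _ = simulate_progressive_rearrangement(cfg, "chr3", sample_rng(0, 0))
        states = {max(0, round(2 * 2**s.seg_mean)) for s in segs}
        assert len(states) >= 3

    def test_single_event_single_join(self):
        cfg = SimulationConfig(n_events=1)
        _, joins, _ = simulate_progressive_rearrangement(cfg, "chr3", sample_rng(0, 0))
        assert len(joins) == 1

    def test_joins_follow_reference_order(self):
        cfg = SimulationConfig()
        _, joins, _ = simulate_progressive_rearrangement(cfg, "chr3", sample_rng(4, 0))
        for j in joins:
            assert j.pos_a < j.pos_b  # event start before event end

    def test_segments_tile_chromosome(self):
        cfg = SimulationConfig()
        segs, _, _ = simulate_progressive_rearrangement(cfg, "chr3", sample_rng(4, 0))
        ordered = sorted(segs, key=lambda s: s.start)
        assert ordered[0].start == 0
        assert ordered[-1].end == cfg.genome.length("chr3")
        for a, b in zip(ordered[:-1], ordered[1:]):
            assert a.end == b.start


class TestEccDNA:
    def test_join_count_equals_fragments(self):
        for n in (2, 3, 4, 5):
            cfg = SimulationConfig(n_fragments=n)
            segs, joins, _ = simulate_eccdna(cfg, "chr4", sample_rng(0, 0))
            assert len(segs) == n and len(joins) == n

    def test_breakends_on_fragment_boundaries(self):
        cfg = SimulationConfig(n_fragments=3)
        segs, joins, truth = simulate_eccdna(cfg, "chr4", sample_rng(1, 0))
        boundaries = {b for f in truth.fragments for b in f}
        for j in joins:
            assert j.pos_a in boundaries and j.pos_b in boundaries

    def test_fragments_disjoint(self):
        cfg = SimulationConfig(n_fragments=5, fragment_size_range_bp=(1_000_000, 9_000_000))
        _, _, truth = simulate_eccdna(cfg, "chr20", sample_rng(9, 0))
        for (a0, b0), (a1, b1) in zip(truth.fragments[:-1], truth.fragments[1:]):
            assert b0 < a1

    def test_amplified_log2_floor(self):
        cfg = SimulationConfig(amplified_log2=2.0)
        segs, _, _ = simulate_eccdna(cfg, "chr4", sample_rng(2, 0))
        assert all(s.seg_mean >= 2.0 for s in segs)


class TestVariants:
    def test_rates_and_groups(self):
        cfg = SimulationConfig()
        va = simulate_variant_calls(cfg, "a", "A", sample_rng(0, 0))
        vb = simulate_variant_calls(cfg, "b", "B", sample_rng(0, 1))
        som_a = sum(1 for v in va if v.compartment == "somatic")
        som_b = sum(1 for v in vb if v.compartment == "somatic")
        assert som_b > 3 * som_a  # 9x in expectation

    def test_fold_recovery_small(self):
        cfg = SimulationConfig()
        ratios = []
        for seed in range(30):
            va = simulate_variant_calls(cfg, "a", "A", sample_rng(seed, 0))
            vb = simulate_variant_calls(cfg, "b", "B", sample_rng(seed, 1))
            ratios.append(
                sum(v.compartment == "somatic" for v in vb)
                / max(1, sum(v.compartment == "somatic" for v in va))
            )
        assert 6.0 <= np.mean(ratios) <= 13.0

    def test_germline_rate_shared(self):
        cfg = SimulationConfig()
        germ = {g: [] for g in "AB"}
        for seed in range(30):
            for g, idx in (("A", 0), ("B", 1)):
                vs = simulate_variant_calls(cfg, "s", g, sample_rng(seed, idx))
                germ[g].append(sum(1 for v in vs if v.compartment == "germline"))
        expected = cfg.germline_rate_per_mb * cfg.coding_mb
        assert abs(np.mean(germ["A"]) - expected) < 0.1 * expected
        assert abs(np.mean(germ["B"]) - expected) < 0.1 * expected

    def test_hypermutator_flag_scales_rate(self):
        cfg = SimulationConfig()
        normal = simulate_variant_calls(cfg, "s", "A", sample_rng(5, 0))
        hyper = simulate_variant_calls(cfg, "s", "A", sample_rng(5, 0), hypermutator=True)
        assert sum(v.compartment == "somatic" for v in hyper) > 10 * sum(
            v.compartment == "somatic" for v in normal
        )

    def test_support_consistency(self):
        cfg = SimulationConfig()
        for v in simulate_variant_calls(cfg, "s", "A", sample_rng(1, 0)):
            assert 0 <= v.alt_reads <= v.total_depth
            assert v.qual is not None and v.qual >= 0


class TestClinical:
    def test_row_count_and_nonnegative_ages(self):
        recs = simulate_clinical_table(SimulationConfig(), sample_rng(0, 99), n=27)
        assert len(recs) == 27
        assert all(r.age is None or r.age >= 0 for r in recs)

    def test_seeded_determinism(self):
        a = simulate_clinical_table(SimulationConfig(), sample_rng(0, 99), n=10)
        b = simulate_clinical_table(SimulationConfig(), sample_rng(0, 99), n=10)
        assert a == b

    def test_latency_median_recovered(self):
        cfg = SimulationConfig(clinical_missing_prob=0.0)
        recs = simulate_clinical_table(cfg, sample_rng(0, 99), n=2000)
        med, _, _, _ = median_and_range([r.latency_y for r in recs])
        assert abs(med - cfg.latency_median_y) < 1.0


class TestCohort:
    def test_byte_identical_repeats(self):
        cfg = SimulationConfig(seed=11, n_samples_group_a=2, n_samples_group_b=2)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.segments == b.segments
        assert a.joins == b.joins
        assert a.clinical == b.clinical

    def test_coordinate_sanity(self):
        cfg = SimulationConfig(seed=1, n_samples_group_a=2, n_samples_group_b=2)
        data = simulate_cohort(cfg)
        by_key = {}
        for s in data.segments:
            assert 0 <= s.start < s.end <= cfg.genome.length(s.chrom)
            by_key.setdefault((s.sample, s.chrom), []).append(s)
        for segs in by_key.values():
            ordered = sorted(segs, key=lambda s: s.start)
            for a, b in zip(ordered[:-1], ordered[1:]):
                assert a.end <= b.start

    def test_truth_covers_all_samples(self):
        cfg = SimulationConfig(seed=2, n_samples_group_a=1, n_samples_group_b=2)
        data = simulate_cohort(cfg)
        assert set(data.truth.samples) == set(data.joins) == set(data.variants)
        groups = [st.group for st in data.truth.samples.values()]
        assert groups.count("A") == 1 and groups.count("B") == 2
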