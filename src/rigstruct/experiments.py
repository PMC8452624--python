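"""Planted-truth recovery and null-calibration experiments.

Each function generates data with :mod:`rigstruct.synthetic`, runs the
relevant pipeline stage, and scores the result against the planted
ground truth. They back both the validation test suite and the
acceptance report script.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .chromothripsis import (
    ChromothripsisParams,
    call_chromothripsis,
    criterion_join_randomness,
    criterion_order_randomness,
)
from .eccdna import EccDNAParams, reconstruct_structures, verify_cycle
from .genome import load_default_genome
from .model import BreakpointJoin
from .mutload import LoadFilterParams, compare_groups, summarize_sample
from .stats import logrank
from .synthetic import (
    SimulationConfig,
    sample_rng,
    simulate_chromothriptic_chromosome,
    simulate_eccdna,
    simulate_progressive_rearrangement,
    simulate_variant_calls,
)

__all__ = [
    "chromothripsis_recovery",
    "eccdna_recovery",
    "mutation_load_recovery",
    "mutation_null_calibration",
    "randomness_null_calibration",
    "logrank_null_calibration",
]


def _autosomes() -> List[str]:
    g = load_default_genome()
    return [c for c in g.chromosomes if c not in ("chrX", "chrY")]


def chromothripsis_recovery(
    n_chromosomes: int = 100,
    seed: int = 0,
    config: SimulationConfig | None = None,
    params: ChromothripsisParams = ChromothripsisParams(),
) -> Dict[str, float]:
    """Sensitivity on chromothriptic chromosomes and false-positive rate
    on progressive-rearrangement controls (one of each per seed)."""
    config = config or SimulationConfig()
    genome = config.genome
    chroms = _autosomes()
    tp = fp = 0
    for i in range(n_chromosomes):
        chrom = chroms[i % len(chroms)]
        segs, joins, _ = simulate_chromothriptic_chromosome(
            config, chrom, sample_rng(seed, 2 * i), "P"
        )
        tp += call_chromothripsis(segs, joins, genome.length(chrom), params).call
        segs, joins, _ = simulate_progressive_rearrangement(
            config, chrom, sample_rng(seed, 2 * i + 1), "N"
        )
        fp += call_chromothripsis(segs, joins, genome.length(chrom), params).call
    return {
        "sensitivity": tp / n_chromosomes,
        "false_positive_rate": fp / n_chromosomes,
        "n": n_chromosomes,
    }


def eccdna_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    params: EccDNAParams = EccDNAParams(),
) -> Dict[str, float]:
    """Exact planted-fragment-set recovery rate of the top-ranked cycle,
    cycling the fragment count through 2-5, plus independent cycle
    verification of every reported cycle."""
    chroms = _autosomes()
    recovered = verified = total_cycles = 0
    for i in range(n_seeds):
        config = SimulationConfig(n_fragments=2 + i % 4)
        chrom = chroms[i % len(chroms)]
        segs, joins, truth = simulate_eccdna(config, chrom, sample_rng(seed, i), "S")
        report = reconstruct_structures(segs, joins, params)
        if report.cycles:
            got = {(s.start, s.end) for s, _ in report.cycles[0].segments}
            if got == set(truth.fragments):
                recovered += 1
        for cyc in report.cycles:
            total_cycles += 1
            verified += verify_cycle(cyc, joins, params.tolerance_bp)
    return {
        "recovery_rate": recovered / n_seeds,
        "verified_fraction": verified / total_cycles if total_cycles else float("nan"),
        "n": n_seeds,
    }


def mutation_load_recovery(
    n_per_group: int = 100,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> Dict[str, float]:
    """Estimate the planted somatic fold change B/A and compare germline
    loads between groups (which should be indistinguishable)."""
    from scipy import stats as sps

    config = config or SimulationConfig()
    params = LoadFilterParams(coding_mb=config.coding_mb)
    summaries = {"A": [], "B": []}
    for group in ("A", "B"):
        offset = 0 if group == "A" else 10_000
        for i in range(n_per_group):
            variants = simulate_variant_calls(
                config, f"{group}{i}", group, sample_rng(seed, offset + i)
            )
            summaries[group].append(summarize_sample(f"{group}{i}", group, variants, params))
    comparison = compare_groups(summaries["A"], summaries["B"], params=params)
    germ_a = [s.germline_load for s in summaries["A"]]
    germ_b = [s.germline_load for s in summaries["B"]]
    _, germ_p = sps.ttest_ind(germ_a, germ_b, equal_var=True)
    return {
        "fold_change": comparison.fold_change,
        "t_p_value": comparison.t_p_value,
        "germline_p_value": float(germ_p),
        "n_per_group": n_per_group,
    }


def mutation_null_calibration(
    n_replicates: int = 1000,
    n_per_group: int = 15,
    seed: int = 0,
) -> Dict[str, float]:
    """Type-I error of the group comparison with no planted difference.

    The germline rate is turned down (it plays no role in the somatic
    t-test) to keep the experiment fast.
    """
    config = SimulationConfig(
        somatic_fold_b=1.0, germline_rate_per_mb=0.1, somatic_rate_a_per_mb=1.0
    )
    params = LoadFilterParams(coding_mb=config.coding_mb, hypermutator_per_mb=float("inf"))
    rejections = 0
    for rep in range(n_replicates):
        summaries = {"A": [], "B": []}
        for group in ("A", "B"):
            offset = 0 if group == "A" else 10_000
            for i in range(n_per_group):
                variants = simulate_variant_calls(
                    config, "s", group, sample_rng(seed + 1 + rep, offset + i)
                )
                summaries[group].append(summarize_sample("s", group, variants, params))
        comparison = compare_groups(summaries["A"], summaries["B"], params=params)
        rejections += comparison.t_p_value < 0.05
    return {"rejection_rate": rejections / n_replicates, "n_replicates": n_replicates}


def randomness_null_calibration(
    n_replicates: int = 1000,
    n_joins: int = 40,
    seed: int = 0,
    span: int = 100_000_000,
) -> Dict[str, float]:
    """Rejection rates of C3 (join orientation) and C4 (fragment order)
    on joins drawn under their own nulls: independent uniform breakend
    positions and uniform strand pairs."""
    rng = np.random.default_rng(seed)
    rej3 = rej4 = 0
    for _ in range(n_replicates):
        joins = []
        pos = rng.integers(0, span, size=(n_joins, 2))
        strands = rng.choice(["+", "-"], size=(n_joins, 2))
        for (pa, pb), (sa, sb) in zip(pos, strands):
            joins.append(
                BreakpointJoin("chr1", int(pa), str(sa), "chr1", int(pb), str(sb))
            )
        rej3 += not criterion_join_randomness(joins).satisfied
        rej4 += not criterion_order_randomness(joins).satisfied
    return {
        "c3_rejection_rate": rej3 / n_replicates,
        "c4_rejection_rate": rej4 / n_replicates,
        "n_replicates": n_replicates,
    }


def logrank_null_calibration(
    n_replicates: int = 1000,
    n_per_group: int = 30,
    seed: int = 0,
    censor_prob: float = 0.2,
) -> Dict[str, float]:
    """Type-I error of the log-rank test under a shared exponential
    survival model with independent censoring."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        groups = []
        for _ in range(2):
            times = rng.exponential(10.0, size=n_per_group)
            events = rng.random(n_per_group) >= censor_prob
            groups.append(list(zip(times, events)))
        _, p = logrank(groups[0], groups[1])
        rejections += p < 0.05
    return {"rejection_rate": rejections / n_replicates, "n_replicates": n_replicates}
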