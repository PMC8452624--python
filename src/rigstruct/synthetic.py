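"""Seeded synthetic cohort generator.

Plants, with known ground truth, exactly the signatures the downstream
stages test for: shattered chromosomes with two-state oscillating copy
number, clustered breakpoints and shuffled/random-orientation joins;
progressive-rearrangement negative controls with nested multi-state copy
number and reference-ordered joins; highly amplified circular amplicons;
two tumor groups with a configurable somatic burden ratio but a shared
germline rate; and a clinical table.

All randomness flows from ``numpy.random.Generator`` streams derived
from ``(master seed, sample index)``, so outputs are reproducible
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome import GenomeModel, load_default_genome
from .model import (
    BreakpointJoin,
    ClinicalRecord,
    CNSegment,
    DegenerateSimulationError,
    InputError,
    VariantCall,
)
from .mutload import SPECTRUM_CLASSES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SampleTruth",
    "PlantedCycle",
    "CohortData",
    "sample_rng",
    "simulate_chromothriptic_chromosome",
    "simulate_progressive_rearrangement",
    "simulate_eccdna",
    "simulate_variant_calls",
    "simulate_clinical_table",
    "simulate_cohort",
]

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples_group_a: int = 3
    n_samples_group_b: int = 6
    genome: GenomeModel = field(default_factory=load_default_genome)

    # chromothripsis signature
    n_breakpoints: int = 30
    cluster_window_bp: Optional[int] = None  # None -> 10% of the chromosome
    fragment_retention_prob: float = 0.5
    retained_log2: float = 0.0
    lost_log2: float = -1.0
    seg_mean_noise_sd: float = 0.05

    # progressive-rearrangement control
    n_events: int = 8
    event_size_range_bp: Tuple[int, int] = (10_000_000, 60_000_000)

    # eccDNA amplicons
    n_fragments: int = 3
    amplified_log2: float = 2.5
    fragment_size_range_bp: Tuple[int, int] = (100_000, 1_000_000)

    # small variants
    germline_rate_per_mb: float = 10.0
    somatic_rate_a_per_mb: float = 0.5
    somatic_fold_b: float = 9.0
    coding_mb: float = 34.0
    depth_mean: float = 60.0
    qual_mean: float = 80.0
    qual_sd: float = 15.0
    spectrum: Tuple[float, ...] = (1 / 6,) * 6  # over SPECTRUM_CLASSES
    hypermutator_fold: float = 50.0

    # clinical table
    age_median_y: float = 7.0
    latency_median_y: float = 8.0
    survival_median_months: float = 9.0
    clinical_missing_prob: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragment_retention_prob <= 1.0:
            raise InputError("fragment_retention_prob must be in [0, 1]")
        if not 0.0 <= self.clinical_missing_prob <= 1.0:
            raise InputError("clinical_missing_prob must be in [0, 1]")
        if self.somatic_fold_b <= 0:
            raise InputError("somatic_fold_b must be > 0")
        if self.n_breakpoints < 10:
            raise InputError("n_breakpoints must be >= 10")
        if not 2 <= self.n_fragments <= 5:
            raise InputError("n_fragments must be in [2, 5]")
        if abs(sum(self.spectrum) - 1.0) > 1e-9 or any(p < 0 for p in self.spectrum):
            raise InputError("spectrum must be a probability vector over 6 classes")


@dataclass
class PlantedCycle:
    chrom: str
    fragments: List[Tuple[int, int]]  # reference order, 0-based half-open
    order: List[int]  # traversal order (indices into fragments)
    orientations: List[str]


@dataclass
class SampleTruth:
    sample: str
    group: str
    chromothriptic_chroms: List[str] = field(default_factory=list)
    progressive_chroms: List[str] = field(default_factory=list)
    cycles: List[PlantedCycle] = field(default_factory=list)
    germline_count: int = 0
    somatic_count: int = 0
    hypermutator: bool = False


@dataclass
class GroundTruth:
    samples: Dict[str, SampleTruth] = field(default_factory=dict)


@dataclass
class CohortData:
    segments: List[CNSegment]
    joins: Dict[str, List[BreakpointJoin]]  # per sample
    variants: Dict[str, List[VariantCall]]  # per sample
    clinical: List[ClinicalRecord]
    truth: GroundTruth


def sample_rng(master_seed: int, sample_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one sample."""
    return np.random.default_rng([master_seed, sample_index])


def _join_between(
    chrom: str,
    frag_a: Tuple[int, int],
    orient_a: str,
    frag_b: Tuple[int, int],
    orient_b: str,
    name: str,
) -> BreakpointJoin:
    """Derived-chromosome adjacency between two oriented fragments.

    The exit breakend of a '+' fragment is its right boundary (strand
    '+'), of a '-' fragment its left boundary (strand '-'); entry is the
    mirror image.
    """
    exit_pos = frag_a[1] if orient_a == "+" else frag_a[0]
    exit_strand = "+" if orient_a == "+" else "-"
    entry_pos = frag_b[0] if orient_b == "+" else frag_b[1]
    entry_strand = "-" if orient_b == "+" else "+"
    return BreakpointJoin(
        chrom_a=chrom,
        pos_a=exit_pos,
        strand_a=exit_strand,
        chrom_b=chrom,
        pos_b=entry_pos,
        strand_b=entry_strand,
        name=name,
    )


def simulate_chromothriptic_chromosome(
    config: SimulationConfig,
    chrom: str,
    rng: np.random.Generator,
    sample: str = "S",
) -> Tuple[List[CNSegment], List[BreakpointJoin], Dict]:
    """Shatter one chromosome inside a clustering window.

    Breakpoints are drawn uniformly inside the window; the fragments
    between consecutive breakpoints are independently retained (baseline
    log2 ~ 0) or lost (~ -1), giving the two-state oscillating profile.
    Retained fragments are shuffled and randomly oriented and the joins
    of the resulting derived chromosome are emitted.
    """
    if chrom not in config.genome:
        raise InputError(f"unknown chromosome {chrom!r}")
    p = config.fragment_retention_prob
    if p <= 0.0 or p >= 1.0:
        raise DegenerateSimulationError(
            "fragment_retention_prob of 0 or 1 cannot produce oscillation"
        )
    length = config.genome.length(chrom)
    window = config.cluster_window_bp or max(1, int(0.1 * length))
    window = min(window, length)
    start = int(rng.integers(0, length - window + 1))
    while True:
        bps = np.unique(rng.integers(start, start + window, size=config.n_breakpoints))
        if len(bps) == config.n_breakpoints:
            break
    fragments = [(int(a), int(b)) for a, b in zip(bps[:-1], bps[1:])]
    retained_mask = rng.random(len(fragments)) < p

    segments = []
    for (a, b), kept in zip(fragments, retained_mask):
        base = config.retained_log2 if kept else config.lost_log2
        seg_mean = base + rng.normal(0.0, config.seg_mean_noise_sd)
        segments.append(
            CNSegment(sample=sample, chrom=chrom, start=a, end=b, seg_mean=float(seg_mean))
        )

    retained_idx = [i for i, kept in enumerate(retained_mask) if kept]
    order = list(rng.permutation(len(retained_idx)))
    orients = ["+" if rng.random() < 0.5 else "-" for _ in retained_idx]
    joins = []
    for k in range(len(order) - 1):
        i, j = retained_idx[order[k]], retained_idx[order[k + 1]]
        joins.append(
            _join_between(
                chrom,
                fragments[i],
                orients[order[k]],
                fragments[j],
                orients[order[k + 1]],
                name=sample,
            )
        )
    truth = {
        "kind": "chromothripsis",
        "chrom": chrom,
        "window": (start, start + window),
        "fragments": fragments,
        "retained": [bool(x) for x in retained_mask],
    }
    return segments, joins, truth


def simulate_progressive_rearrangement(
    config: SimulationConfig,
    chrom: str,
    rng: np.random.Generator,
    sample: str = "S",
) -> Tuple[List[CNSegment], List[BreakpointJoin], Dict]:
    """Negative control: sequential deletions/duplications across the
    whole chromosome, producing nested multi-state copy number and joins
    whose partner positions follow reference order."""
    if chrom not in config.genome:
        raise InputError(f"unknown chromosome {chrom!r}")
    if config.n_events < 1:
        raise InputError("n_events must be >= 1")
    length = config.genome.length(chrom)
    lo, hi = config.event_size_range_bp

    events = []  # (start, end, +1 dup / -1 del)
    joins = []
    for k in range(config.n_events):
        size = int(rng.integers(lo, hi + 1))
        if size > 0.4 * length:  # keep events a sub-chromosomal fraction
            size = int(rng.uniform(0.05, 0.4) * length)
        a = int(rng.integers(0, length - size))
        b = a + size
        kind = -1 if k % 2 == 0 else +1  # alternate del / dup
        events.append((a, b, kind))
        if kind == -1:  # deletion join: (+ at left flank end, - at right flank start)
            joins.append(
                BreakpointJoin(chrom, a, "+", chrom, b, "-", name=sample)
            )
        else:  # tandem duplication join
            joins.append(
                BreakpointJoin(chrom, a, "-", chrom, b, "+", name=sample)
            )

    # segment the resulting integer CN profile
    bounds = sorted({0, length} | {a for a, _, _ in events} | {b for _, b, _ in events})
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        cn = 2
        for ea, eb, kind in events:
            if ea <= a and b <= eb:
                cn += kind
        cn = max(cn, 0)
        seg_mean = np.log2(max(cn, 0.125) / 2) + rng.normal(0.0, config.seg_mean_noise_sd)
        segments.append(
            CNSegment(sample=sample, chrom=chrom, start=a, end=b, seg_mean=float(seg_mean))
        )
    truth = {"kind": "progressive", "chrom": chrom, "events": events}
    return segments, joins, truth


def simulate_eccdna(
    config: SimulationConfig,
    chrom: str,
    rng: np.random.Generator,
    sample: str = "S",
) -> Tuple[List[CNSegment], List[BreakpointJoin], PlantedCycle]:
    """Plant a circular amplicon: disjoint highly amplified fragments plus
    the joins closing them into a single cycle (one join per fragment)."""
    if chrom not in config.genome:
        raise InputError(f"unknown chromosome {chrom!r}")
    length = config.genome.length(chrom)
    lo, hi = config.fragment_size_range_bp

    while True:  # rejection-sample disjoint fragments
        frags = []
        for _ in range(config.n_fragments):
            size = int(rng.integers(lo, hi + 1))
            a = int(rng.integers(0, length - size))
            frags.append((a, a + size))
        frags.sort()
        if all(b0 < a1 for (_, b0), (a1, _) in zip(frags[:-1], frags[1:])):
            break

    segments = []
    for a, b in frags:
        seg_mean = config.amplified_log2 + abs(rng.normal(0.0, config.seg_mean_noise_sd))
        segments.append(
            CNSegment(sample=sample, chrom=chrom, start=a, end=b, seg_mean=float(seg_mean))
        )

    order = list(rng.permutation(config.n_fragments))
    orients = ["+" if rng.random() < 0.5 else "-" for _ in order]
    joins = []
    for k in range(len(order)):
        nk = (k + 1) % len(order)
        joins.append(
            _join_between(
                chrom,
                frags[order[k]],
                orients[k],
                frags[order[nk]],
                orients[nk],
                name=sample,
            )
        )
    truth = PlantedCycle(
        chrom=chrom,
        fragments=frags,
        order=[int(i) for i in order],
        orientations=orients,
    )
    return segments, joins, truth


_CLASS_PAIRS = [tuple(c.split(">")) for c in SPECTRUM_CLASSES]


def simulate_variant_calls(
    config: SimulationConfig,
    sample: str,
    group: str,
    rng: np.random.Generator,
    hypermutator: bool = False,
) -> List[VariantCall]:
    """Germline + somatic variant calls for one sample.

    Germline counts are Poisson at the shared rate; somatic counts are
    Poisson at rate * coding_mb * fold with fold 1 for group A and
    ``somatic_fold_b`` for group B (times ``hypermutator_fold`` for
    flagged samples). Read support is binomial at the drawn VAF.
    """
    if group not in ("A", "B"):
        raise InputError(f"group must be 'A' or 'B', got {group!r}")
    if config.germline_rate_per_mb <= 0 or config.somatic_rate_a_per_mb <= 0:
        raise InputError("variant rates must be > 0")
    fold = 1.0 if group == "A" else config.somatic_fold_b
    if hypermutator:
        fold *= config.hypermutator_fold
    n_germ = int(rng.poisson(config.germline_rate_per_mb * config.coding_mb))
    n_som = int(rng.poisson(config.somatic_rate_a_per_mb * config.coding_mb * fold))

    chroms = config.genome.chromosomes
    lengths = np.asarray([config.genome.length(c) for c in chroms])
    out: List[VariantCall] = []
    for compartment, count in (("germline", n_germ), ("somatic", n_som)):
        if count == 0:
            continue
        chrom_idx = rng.integers(0, len(chroms), size=count)
        pos = 1 + (rng.random(count) * lengths[chrom_idx]).astype(np.int64)
        cls_idx = rng.choice(6, size=count, p=np.asarray(config.spectrum))
        flip = rng.random(count) < 0.5  # emit half on the complementary strand
        depth = np.maximum(1, rng.poisson(config.depth_mean, size=count))
        if compartment == "germline":
            vaf = np.full(count, 0.5)
        else:
            vaf = rng.uniform(0.15, 0.6, size=count)
        alt_reads = rng.binomial(depth, vaf)
        qual = np.maximum(0.0, rng.normal(config.qual_mean, config.qual_sd, size=count))
        for i in range(count):
            ref, alt = _CLASS_PAIRS[cls_idx[i]]
            if flip[i]:
                ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            out.append(
                VariantCall(
                    chrom=chroms[chrom_idx[i]],
                    pos=int(pos[i]),
                    ref=ref,
                    alt=alt,
                    qual=float(qual[i]),
                    alt_reads=int(alt_reads[i]),
                    total_depth=int(depth[i]),
                    compartment=compartment,
                )
            )
    return out


_HISTOLOGIES = ("ALL", "M", "E", "Ge", "G,O", "C", "Ga", "BL")
_FIELDS = ("Focal", "CSI", "CR", "TBI")


def simulate_clinical_table(
    config: SimulationConfig,
    rng: np.random.Generator,
    n: Optional[int] = None,
) -> List[ClinicalRecord]:
    """Clinical-table fixture: ages/latencies log-normal around the
    configured medians, survival exponential, sporadic missing values."""
    if n is None:
        n = config.n_samples_group_a + config.n_samples_group_b
    if n < 1:
        raise InputError("n must be >= 1")
    records = []
    for i in range(n):
        age = float(np.round(np.exp(rng.normal(np.log(config.age_median_y), 0.7)), 1))
        latency = float(np.round(np.exp(rng.normal(np.log(config.latency_median_y), 0.4)), 1))
        survival = float(
            np.round(rng.exponential(config.survival_median_months / np.log(2)), 1)
        )
        dose = float(np.round(rng.uniform(12, 60), 1))
        rec = ClinicalRecord(
            case_id=f"S{i + 1}",
            age=age,
            histology=_HISTOLOGIES[rng.integers(0, len(_HISTOLOGIES))],
            dose_gy=dose,
            dose_raw=f"{dose:g}",
            field_type=_FIELDS[rng.integers(0, len(_FIELDS))],
            latency_y=latency,
            status="deceased",
            survival_months=survival,
        )
        for attr in ("age", "dose_gy", "latency_y", "survival_months"):
            if rng.random() < config.clinical_missing_prob:
                setattr(rec, attr, None)
                if attr == "dose_gy":
                    rec.dose_raw = None
        if rng.random() < config.clinical_missing_prob:
            rec.status = None
        records.append(rec)
    return records


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Generate the full synthetic cohort.

    Each sample gets one chromothriptic chromosome, one
    progressive-rearrangement control chromosome, one planted circular
    amplicon, and a germline+somatic variant set; the cohort gets one
    clinical table. Per-sample RNG streams make generation order
    irrelevant.
    """
    n_total = config.n_samples_group_a + config.n_samples_group_b
    truth = GroundTruth()
    segments: List[CNSegment] = []
    joins: Dict[str, List[BreakpointJoin]] = {}
    variants: Dict[str, List[VariantCall]] = {}
    chroms = [c for c in config.genome.chromosomes if c not in ("chrX", "chrY")]

    for i in range(n_total):
        group = "A" if i < config.n_samples_group_a else "B"
        sample = f"S{i + 1}"
        rng = sample_rng(config.seed, i)
        ct_chrom = chroms[i % len(chroms)]
        pr_chrom = chroms[(i + 7) % len(chroms)]
        ec_chrom = chroms[(i + 13) % len(chroms)]
        if pr_chrom == ct_chrom:
            pr_chrom = chroms[(i + 8) % len(chroms)]
        if ec_chrom in (ct_chrom, pr_chrom):
            ec_chrom = chroms[(i + 14) % len(chroms)]

        st = SampleTruth(sample=sample, group=group)
        segs, js, _ = simulate_chromothriptic_chromosome(config, ct_chrom, rng, sample)
        segments.extend(segs)
        sample_joins = list(js)
        st.chromothriptic_chroms.append(ct_chrom)

        segs, js, _ = simulate_progressive_rearrangement(config, pr_chrom, rng, sample)
        segments.extend(segs)
        sample_joins.extend(js)
        st.progressive_chroms.append(pr_chrom)

        segs, js, cycle = simulate_eccdna(config, ec_chrom, rng, sample)
        segments.extend(segs)
        sample_joins.extend(js)
        st.cycles.append(cycle)

        vs = simulate_variant_calls(config, sample, group, rng)
        st.germline_count = sum(1 for v in vs if v.compartment == "germline")
        st.somatic_count = sum(1 for v in vs if v.compartment == "somatic")

        joins[sample] = sample_joins
        variants[sample] = vs
        truth.samples[sample] = st

    clinical = simulate_clinical_table(config, sample_rng(config.seed, 10**6), n=n_total)
    for rec, st in zip(clinical, truth.samples.values()):
        rec.case_id = st.sample
    return CohortData(
        segments=segments, joins=joins, variants=variants, clinical=clinical, truth=truth
    )
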