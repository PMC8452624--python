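"""Copy-number segment classification and cohort-level CNV summaries.

Gain/loss thresholds are inclusive at +/-0.2 (a +/-0.25 preset is
available for WGS-derived segmentations). Focality is either the
fraction-of-arm rule (<=25% of the containing arm, default) or a fixed
<=3 Mb rule. Segments spanning the centromere are split per arm before
classification so the arm fraction is well defined.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .genome import GeneLocus, GenomeModel
from .model import CNSegment, InputError

__all__ = [
    "CNVThresholds",
    "SegmentCall",
    "GeneCall",
    "CNVCount",
    "classify_segment",
    "classify_segments",
    "arm_alteration_frequencies",
    "call_gene_cnv",
    "cnv_count_per_sample",
]


@dataclass(frozen=True)
class CNVThresholds:
    gain: float = 0.2
    loss: float = -0.2
    amplification: float = 2.0
    focal_mode: str = "arm25"  # "arm25" | "3mb"
    focal_arm_fraction: float = 0.25
    focal_mb: float = 3.0

    def __post_init__(self) -> None:
        if self.focal_mode not in ("arm25", "3mb"):
            raise InputError(f"unknown focal mode {self.focal_mode!r}")
        if self.loss >= self.gain:
            raise InputError("loss threshold must be below gain threshold")

    @classmethod
    def wgs_preset(cls, **kw) -> "CNVThresholds":
        """+/-0.25 reporting rule used for sequencing-derived segmentations."""
        return cls(gain=0.25, loss=-0.25, **kw)


@dataclass(frozen=True)
class SegmentCall:
    segment: CNSegment
    direction: str  # "gain" | "loss" | "neutral"
    extent: str  # "focal" | "broad" | "not-applicable"
    arm: str
    arm_fraction: float


@dataclass(frozen=True)
class GeneCall:
    gene: GeneLocus
    sample: str
    call: str  # "gain" | "amplification" | "loss" | "neutral"
    seg_mean: Optional[float]
    no_coverage: bool = False


@dataclass(frozen=True)
class CNVCount:
    gains: int
    losses: int

    @property
    def total(self) -> int:
        return self.gains + self.losses


def _direction(seg_mean: float, thresholds: CNVThresholds) -> str:
    if seg_mean >= thresholds.gain:
        return "gain"
    if seg_mean <= thresholds.loss:
        return "loss"
    return "neutral"


def split_at_centromere(seg: CNSegment, genome: GenomeModel) -> List[CNSegment]:
    """Split a centromere-spanning segment into its p and q parts."""
    cen = genome.centromere(seg.chrom)
    if seg.start < cen < seg.end:
        return [replace(seg, end=cen), replace(seg, start=cen)]
    return [seg]


def classify_segment(
    seg: CNSegment,
    genome: GenomeModel,
    thresholds: CNVThresholds = CNVThresholds(),
) -> List[SegmentCall]:
    """Classify one segment; returns two calls if it spans the centromere."""
    if seg.chrom not in genome:
        raise InputError(f"unknown chromosome {seg.chrom!r}")
    if seg.end > genome.length(seg.chrom):
        raise InputError(
            f"segment {seg.chrom}:{seg.start}-{seg.end} exceeds chromosome length"
        )
    calls = []
    for part in split_at_centromere(seg, genome):
        arm = genome.arm_of(part.chrom, part.start)
        arm_fraction = part.length / genome.arm_length(part.chrom, arm)
        direction = _direction(part.seg_mean, thresholds)
        if direction == "neutral":
            extent = "not-applicable"
        elif thresholds.focal_mode == "arm25":
            extent = "focal" if arm_fraction <= thresholds.focal_arm_fraction else "broad"
        else:
            extent = "focal" if part.length <= thresholds.focal_mb * 1e6 else "broad"
        calls.append(
            SegmentCall(
                segment=part,
                direction=direction,
                extent=extent,
                arm=arm,
                arm_fraction=arm_fraction,
            )
        )
    return calls


def classify_segments(
    segments: Iterable[CNSegment],
    genome: GenomeModel,
    thresholds: CNVThresholds = CNVThresholds(),
) -> List[SegmentCall]:
    calls: List[SegmentCall] = []
    for seg in segments:
        calls.extend(classify_segment(seg, genome, thresholds))
    return calls


def arm_alteration_frequencies(calls: Sequence[SegmentCall]) -> pd.DataFrame:
    """Per (chromosome arm, direction) fraction of samples carrying at
    least one broad alteration there. Numerator and denominator are kept.
    """
    if not calls:
        raise InputError("empty cohort")
    samples = sorted({c.segment.sample for c in calls})
    n = len(samples)
    hits: Dict[Tuple[str, str, str], set] = defaultdict(set)
    for c in calls:
        if c.direction != "neutral" and c.extent == "broad":
            hits[(c.segment.chrom, c.arm, c.direction)].add(c.segment.sample)
    rows = []
    for (chrom, arm, direction), who in sorted(hits.items()):
        rows.append(
            {
                "chrom": chrom,
                "arm": arm,
                "direction": direction,
                "n_samples": len(who),
                "n_cohort": n,
                "frequency": len(who) / n,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "arm", "direction", "n_samples", "n_cohort", "frequency"]
    )


def call_gene_cnv(
    segments: Sequence[CNSegment],
    gene: GeneLocus,
    thresholds: CNVThresholds = CNVThresholds(),
) -> GeneCall:
    """Gene-level call from the overlapping segment of maximal |seg_mean|.

    Overlap is any intersection with the gene interval. Amplification
    requires seg_mean >= the amplification threshold; gains sit in
    [gain, amplification). No overlapping segment yields a flagged
    neutral call.
    """
    overlapping = [
        s for s in segments if s.chrom == gene.chrom and s.start < gene.end and s.end > gene.start
    ]
    sample = segments[0].sample if segments else ""
    if not overlapping:
        return GeneCall(gene=gene, sample=sample, call="neutral", seg_mean=None, no_coverage=True)
    best = max(overlapping, key=lambda s: (abs(s.seg_mean), -s.start))
    if best.seg_mean >= thresholds.amplification:
        call = "amplification"
    else:
        call = _direction(best.seg_mean, thresholds)
    return GeneCall(gene=gene, sample=best.sample, call=call, seg_mean=best.seg_mean)


def cnv_count_per_sample(calls: Sequence[SegmentCall]) -> CNVCount:
    """Count of non-neutral segment calls, gains and losses separately."""
    gains = sum(1 for c in calls if c.direction == "gain")
    losses = sum(1 for c in calls if c.direction == "loss")
    return CNVCount(gains=gains, losses=losses)
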