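"""Core domain records shared across pipeline stages.

Coordinates are 0-based half-open for intervals (``CNSegment``) and
0-based point positions for SV breakends (``BreakpointJoin``); small
variants keep the 1-based VCF convention (``VariantCall.pos``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "CNSegment",
    "BreakpointJoin",
    "VariantCall",
    "ClinicalRecord",
    "InputError",
    "DegenerateSimulationError",
    "ORIENTATION_CLASSES",
    "orientation_class",
]


class InputError(ValueError):
    """Raised on malformed or out-of-contract input."""


class DegenerateSimulationError(ValueError):
    """Raised when simulation parameters make the planted signal impossible."""


#: strand pair -> join orientation class
ORIENTATION_CLASSES = {
    ("+", "-"): "del",
    ("-", "+"): "dup",
    ("+", "+"): "inv_head",
    ("-", "-"): "inv_tail",
}


def orientation_class(strand_a: str, strand_b: str) -> str:
    """Map a breakend strand pair to its join orientation class.

    ``(+,-)`` deletion-type, ``(-,+)`` duplication-type, ``(+,+)`` /
    ``(-,-)`` the two inversion types.
    """
    try:
        return ORIENTATION_CLASSES[(strand_a, strand_b)]
    except KeyError:
        raise InputError(f"invalid strand pair ({strand_a!r}, {strand_b!r})") from None


@dataclass(frozen=True)
class CNSegment:
    """A contiguous genomic interval with a mean log2 copy-ratio."""

    sample: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    seg_mean: float
    num_mark: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.start < 0:
            raise InputError(f"segment start {self.start} is negative")
        if not math.isfinite(self.seg_mean):
            raise InputError("seg_mean must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BreakpointJoin:
    """An SV adjacency: two breakends plus a derived orientation class."""

    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    somatic: bool = True
    name: str = "."

    def __post_init__(self) -> None:
        orientation_class(self.strand_a, self.strand_b)  # validates strands
        if self.pos_a < 0 or self.pos_b < 0:
            raise InputError("breakend positions must be non-negative")

    @property
    def orientation(self) -> str:
        return orientation_class(self.strand_a, self.strand_b)

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom_a == self.chrom_b


@dataclass(frozen=True)
class VariantCall:
    """A small variant call with the fields the load filters consume.

    ``qual`` may be ``None`` (VCF ``.``), in which case QUAL-based
    filters exclude the record.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: Optional[float]
    alt_reads: int
    total_depth: int
    compartment: str  # "germline" | "somatic"
    coding: bool = True
    database_match: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in ("germline", "somatic"):
            raise InputError(f"unknown compartment {self.compartment!r}")
        if self.alt_reads > self.total_depth:
            raise InputError("alt_reads exceeds total_depth")

    @property
    def vaf(self) -> Optional[float]:
        if self.total_depth == 0:
            return None
        return self.alt_reads / self.total_depth

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )


@dataclass
class ClinicalRecord:
    """One row of the clinical table; ``None`` marks a missing value."""

    case_id: str
    age: Optional[float] = None
    histology: Optional[str] = None
    dose_gy: Optional[float] = None
    dose_raw: Optional[str] = None
    field_type: Optional[str] = None
    latency_y: Optional[float] = None
    status: Optional[str] = None  # "deceased" | None (unknown)
    survival_months: Optional[float] = None

    def __post_init__(self) -> None:
        for attr in ("age", "latency_y", "survival_months"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise InputError(f"{attr} must be >= 0, got {v}")
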