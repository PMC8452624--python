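"""Germline/somatic mutation loads, substitution spectra, and the
between-group burden comparison.

Filter conventions (all inclusive): germline load counts variants with
QUAL >= 50; somatic load counts variants with >= 4 supporting reads and
ignores QUAL; the exome reporting filter keeps >= 5 supporting reads at
>= 30% VAF, with curated-database matches passed through.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .model import InputError, VariantCall

__all__ = [
    "LoadFilterParams",
    "MutationLoadSummary",
    "GroupComparison",
    "germline_load",
    "somatic_load",
    "wes_report_filter",
    "load_per_mb",
    "substitution_spectrum",
    "SPECTRUM_CLASSES",
    "summarize_sample",
    "compare_groups",
]

#: purine/pyrimidine-collapsed substitution classes (A- or C-reference)
SPECTRUM_CLASSES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class LoadFilterParams:
    germline_min_qual: float = 50.0
    somatic_min_alt_reads: int = 4
    wes_min_alt_reads: int = 5
    wes_min_vaf: float = 0.30
    coding_mb: float = 34.0
    hypermutator_per_mb: float = 10.0  # somatic coding variants/Mb above which a sample is flagged
    exclude_hypermutators: bool = True


@dataclass
class MutationLoadSummary:
    sample: str
    group: str
    germline_load: int
    somatic_load: int
    somatic_per_mb: float
    spectrum: Dict[str, float]
    hypermutator: bool = False


@dataclass
class GroupComparison:
    fold_change: float  # mean(B) / mean(A) of somatic loads
    t_statistic: float
    t_p_value: float
    spectrum_chi2: float
    spectrum_p_value: float
    n_a: int
    n_b: int
    n_excluded_hypermutators: int


def germline_load(variants: Sequence[VariantCall], params: LoadFilterParams = LoadFilterParams()) -> int:
    """Number of germline variants passing the QUAL filter (missing QUAL excluded)."""
    return sum(
        1
        for v in variants
        if v.compartment == "germline" and v.qual is not None and v.qual >= params.germline_min_qual
    )


def somatic_load(variants: Sequence[VariantCall], params: LoadFilterParams = LoadFilterParams()) -> int:
    """Number of somatic variants with sufficient read support; QUAL is ignored."""
    return sum(
        1
        for v in variants
        if v.compartment == "somatic" and v.alt_reads >= params.somatic_min_alt_reads
    )


def wes_report_filter(
    variants: Sequence[VariantCall], params: LoadFilterParams = LoadFilterParams()
) -> List[VariantCall]:
    """Exome reporting subset: alt_reads >= 5 and VAF >= 0.30; records
    flagged as curated-database matches bypass the filter. Depth-0
    records (undefined VAF) are excluded."""
    kept = []
    for v in variants:
        if v.database_match:
            kept.append(v)
            continue
        if v.vaf is None:
            continue
        if v.alt_reads >= params.wes_min_alt_reads and v.vaf >= params.wes_min_vaf:
            kept.append(v)
    return kept


def load_per_mb(load: int, region_mb: float) -> float:
    if region_mb <= 0:
        raise InputError("region_mb must be > 0")
    return load / region_mb


def collapse_substitution(ref: str, alt: str) -> Optional[str]:
    """Map an SNV to its purine-reference class, complementing T/G refs."""
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        return None
    if ref in ("T", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def substitution_spectrum(
    variants: Sequence[VariantCall],
) -> Tuple[Dict[str, float], int]:
    """6-class substitution proportions over the SNVs in ``variants``.

    Returns (proportions, n_skipped_non_snv). Proportions are zero when
    there are no SNVs.
    """
    counts: Counter = Counter()
    skipped = 0
    for v in variants:
        if not v.is_snv:
            skipped += 1
            continue
        cls = collapse_substitution(v.ref, v.alt)
        if cls is None:
            skipped += 1
            continue
        counts[cls] += 1
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in SPECTRUM_CLASSES}, skipped
    return {c: counts[c] / total for c in SPECTRUM_CLASSES}, skipped


def spectrum_counts(variants: Sequence[VariantCall]) -> Dict[str, int]:
    counts: Counter = Counter()
    for v in variants:
        if v.is_snv:
            cls = collapse_substitution(v.ref, v.alt)
            if cls is not None:
                counts[cls] += 1
    return {c: counts[c] for c in SPECTRUM_CLASSES}


def summarize_sample(
    sample: str,
    group: str,
    variants: Sequence[VariantCall],
    params: LoadFilterParams = LoadFilterParams(),
    known_hypermutator: bool = False,
) -> MutationLoadSummary:
    som = somatic_load(variants, params)
    per_mb = load_per_mb(som, params.coding_mb)
    spectrum, _ = substitution_spectrum(
        [v for v in variants if v.compartment == "somatic"]
    )
    return MutationLoadSummary(
        sample=sample,
        group=group,
        germline_load=germline_load(variants, params),
        somatic_load=som,
        somatic_per_mb=per_mb,
        spectrum=spectrum,
        hypermutator=known_hypermutator or per_mb > params.hypermutator_per_mb,
    )


def compare_groups(
    summaries_a: Sequence[MutationLoadSummary],
    summaries_b: Sequence[MutationLoadSummary],
    spectrum_counts_a: Optional[Dict[str, int]] = None,
    spectrum_counts_b: Optional[Dict[str, int]] = None,
    params: LoadFilterParams = LoadFilterParams(),
) -> GroupComparison:
    """Fold change and Student's two-sample two-sided t-test on somatic
    loads, plus a chi-square comparison of pooled substitution spectra.

    Hypermutator-flagged samples are dropped first (when exclusion is
    enabled, the default).
    """
    if params.exclude_hypermutators:
        a = [s for s in summaries_a if not s.hypermutator]
        b = [s for s in summaries_b if not s.hypermutator]
    else:
        a, b = list(summaries_a), list(summaries_b)
    n_excluded = (len(summaries_a) + len(summaries_b)) - (len(a) + len(b))
    if len(a) < 2 or len(b) < 2:
        raise InputError("need >= 2 samples per group after hypermutator exclusion")

    loads_a = np.asarray([s.somatic_load for s in a], dtype=float)
    loads_b = np.asarray([s.somatic_load for s in b], dtype=float)
    if loads_a.mean() == 0:
        raise InputError("zero mean somatic load in group A; fold change undefined")
    fold = float(loads_b.mean() / loads_a.mean())
    t_stat, t_p = sps.ttest_ind(loads_b, loads_a, equal_var=True)

    chi2 = p_chi = float("nan")
    if spectrum_counts_a is not None and spectrum_counts_b is not None:
        rows = []
        cols = [
            c
            for c in SPECTRUM_CLASSES
            if spectrum_counts_a.get(c, 0) + spectrum_counts_b.get(c, 0) > 0
        ]
        if cols:
            rows = [
                [spectrum_counts_a.get(c, 0) for c in cols],
                [spectrum_counts_b.get(c, 0) for c in cols],
            ]
            chi2, p_chi, _, _ = sps.chi2_contingency(np.asarray(rows))
    return GroupComparison(
        fold_change=fold,
        t_statistic=float(t_stat),
        t_p_value=float(t_p),
        spectrum_chi2=float(chi2),
        spectrum_p_value=float(p_chi),
        n_a=len(a),
        n_b=len(b),
        n_excluded_hypermutators=n_excluded,
    )
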