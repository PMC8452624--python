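"""Per-chromosome chromothripsis calling from four statistical hallmarks.

C1 oscillation     two copy-number states dominate and alternate.
C2 clustering      breakpoints are spatially clustered (Monte-Carlo
                   one-sided KS test on inter-breakpoint spacings versus
                   uniform placement).
C3 join randomness the four breakend orientation classes are consistent
                   with equal proportions.
C4 order randomness partner breakend positions carry no rank correlation
                   with reference order.

Note the inverted test logic of C3/C4: chromothripsis predicts
randomness, so those criteria are satisfied when the test does NOT
reject (p >= alpha). A chromosome is called when at least two criteria
are satisfied; exactly two sets a borderline flag (the stand-in for
manual review).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .model import BreakpointJoin, CNSegment, InputError
from .stats import ContingencyResult, fisher_exact

__all__ = [
    "ChromothripsisParams",
    "CriterionResult",
    "ChromothripsisEvaluation",
    "infer_cn_states",
    "criterion_oscillation",
    "criterion_breakpoint_clustering",
    "criterion_join_randomness",
    "criterion_order_randomness",
    "call_chromothripsis",
    "evaluate_cohort",
    "compare_cohort_frequency",
]

CRITERIA = ("C1-oscillation", "C2-clustering", "C3-join-randomness", "C4-order-randomness")


@dataclass(frozen=True)
class ChromothripsisParams:
    alpha: float = 0.05
    min_segments: int = 10
    min_breakpoints: int = 10
    min_joins_orientation: int = 4
    chi_square_min_joins: int = 8  # below this C3 uses the exact multinomial test
    min_joins_order: int = 8
    oscillation_dominance: float = 0.8
    min_switches: int = 6
    n_resamples: int = 1000
    mc_seed: int = 0


@dataclass(frozen=True)
class CriterionResult:
    criterion: str
    statistic: float
    p_value: float  # NaN for the score-based C1
    satisfied: bool
    evaluable: bool
    detail: str = ""

    def __post_init__(self) -> None:
        if self.satisfied and not self.evaluable:
            raise InputError("a non-evaluable criterion cannot be satisfied")


@dataclass(frozen=True)
class ChromothripsisEvaluation:
    sample: str
    chrom: str
    criteria: Tuple[CriterionResult, ...]
    n_satisfied: int
    call: bool
    borderline: bool

    def criterion(self, cid: str) -> CriterionResult:
        for c in self.criteria:
            if c.criterion == cid:
                return c
        raise KeyError(cid)


def _not_evaluable(cid: str, detail: str) -> CriterionResult:
    return CriterionResult(
        criterion=cid,
        statistic=float("nan"),
        p_value=float("nan"),
        satisfied=False,
        evaluable=False,
        detail=detail,
    )


def infer_cn_states(segments: Sequence[CNSegment]) -> List[int]:
    """Integer copy-number states on a diploid baseline: round(2 * 2^seg_mean)."""
    if not segments:
        raise InputError("at least one segment required")
    return [max(0, round(2 * 2**s.seg_mean)) for s in segments]


def criterion_oscillation(
    states: Sequence[int], params: ChromothripsisParams = ChromothripsisParams()
) -> CriterionResult:
    """C1: the two most frequent states cover >= the dominance fraction of
    segments and alternate at least ``min_switches`` times."""
    cid = CRITERIA[0]
    n = len(states)
    if n < params.min_segments:
        return _not_evaluable(cid, f"{n} segments < {params.min_segments}")
    counts: Dict[int, int] = {}
    for s in states:
        counts[s] = counts.get(s, 0) + 1
    top2 = sorted(counts, key=lambda k: (-counts[k], k))[:2]
    coverage = sum(counts[s] for s in top2) / n
    run = [s for s in states if s in top2]
    switches = sum(1 for a, b in zip(run, run[1:]) if a != b)
    satisfied = coverage >= params.oscillation_dominance and switches >= params.min_switches
    return CriterionResult(
        criterion=cid,
        statistic=float(switches),
        p_value=float("nan"),
        satisfied=satisfied,
        evaluable=True,
        detail=f"top2 coverage {coverage:.3f}, switches {switches}",
    )


def _spacing_ks_plus(positions: np.ndarray, chrom_length: int) -> float:
    """One-sided KS statistic of inter-breakpoint spacings against the
    spacing distribution of the same number of uniform points, evaluated
    only below the null's median spacing.

    Under uniform placement of n points on [0, L] a consecutive spacing S
    has P(S <= s) = 1 - (1 - s/L)^n. Clustering yields an excess of SMALL
    spacings, pushing the spacing ECDF above the null at small s; the sup
    of (ECDF - F0) is therefore restricted to s at or below the null
    median spacing, so that regular spacing (no small spacings at all,
    but a step above the null at the mean) scores 0 rather than firing
    the criterion.
    """
    n = len(positions)
    spacings = np.sort(np.diff(np.sort(positions)))
    m = len(spacings)
    s_med = chrom_length * (1.0 - 0.5 ** (1.0 / n))  # null median spacing
    small = spacings <= s_med
    if not np.any(small):
        return 0.0
    f0 = 1.0 - (1.0 - spacings[small] / chrom_length) ** n
    i = np.arange(1, m + 1)[small] / m
    return max(0.0, float(np.max(i - f0)))


def criterion_breakpoint_clustering(
    positions: Sequence[int],
    chrom_length: int,
    params: ChromothripsisParams = ChromothripsisParams(),
    rng: Optional[np.random.Generator] = None,
) -> CriterionResult:
    """C2: Monte-Carlo test for breakpoint clustering, one-sided toward
    clustering. Duplicate positions are collapsed with a warning."""
    cid = CRITERIA[1]
    pos = np.unique(np.asarray(positions, dtype=float))
    if len(pos) < len(positions):
        warnings.warn("duplicate breakpoint positions collapsed", stacklevel=2)
    if len(pos) < params.min_breakpoints:
        return _not_evaluable(cid, f"{len(pos)} breakpoints < {params.min_breakpoints}")
    if rng is None:
        rng = np.random.default_rng(params.mc_seed)
    n = len(pos)
    d_obs = _spacing_ks_plus(pos, chrom_length)
    sims = rng.uniform(0, chrom_length, size=(params.n_resamples, n))
    exceed = sum(1 for row in sims if _spacing_ks_plus(row, chrom_length) >= d_obs)
    p = (1 + exceed) / (params.n_resamples + 1)
    return CriterionResult(
        criterion=cid,
        statistic=d_obs,
        p_value=p,
        satisfied=p < params.alpha,
        evaluable=True,
        detail=f"n={n}, MC resamples {params.n_resamples}",
    )


def _orientation_counts(joins: Sequence[BreakpointJoin]) -> np.ndarray:
    order = ("del", "dup", "inv_head", "inv_tail")
    counts = {k: 0 for k in order}
    for j in joins:
        counts[j.orientation] += 1
    return np.asarray([counts[k] for k in order], dtype=int)


def _exact_multinomial_p(counts: np.ndarray) -> float:
    """Exact multinomial goodness-of-fit p against equal cell
    probabilities: sum of probabilities of all outcomes at most as likely
    as the observed one."""
    n = int(counts.sum())
    k = len(counts)
    dist = sps.multinomial(n, [1 / k] * k)
    p_obs = dist.pmf(counts)
    total = 0.0
    for combo in itertools.product(range(n + 1), repeat=k - 1):
        if sum(combo) > n:
            continue
        vec = list(combo) + [n - sum(combo)]
        p = dist.pmf(vec)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(float(total), 1.0)


def criterion_join_randomness(
    joins: Sequence[BreakpointJoin],
    params: ChromothripsisParams = ChromothripsisParams(),
) -> CriterionResult:
    """C3: the four orientation-class counts fit equal proportions.

    Satisfied when the goodness-of-fit test does NOT reject (p >= alpha).
    Chi-square for >= ``chi_square_min_joins`` joins, exact multinomial
    below that, non-evaluable under ``min_joins_orientation``.
    """
    cid = CRITERIA[2]
    intra = [j for j in joins if j.intrachromosomal]
    n = len(intra)
    if n < params.min_joins_orientation:
        return _not_evaluable(cid, f"{n} joins < {params.min_joins_orientation}")
    counts = _orientation_counts(intra)
    if n >= params.chi_square_min_joins:
        stat, p = sps.chisquare(counts)
        detail = "chi-square"
    else:
        p = _exact_multinomial_p(counts)
        expected = n / 4
        stat = float(np.sum((counts - expected) ** 2 / expected))
        detail = "exact multinomial"
    return CriterionResult(
        criterion=cid,
        statistic=float(stat),
        p_value=float(p),
        satisfied=p >= params.alpha,
        evaluable=True,
        detail=f"{detail}, counts {counts.tolist()}",
    )


def criterion_order_randomness(
    joins: Sequence[BreakpointJoin],
    params: ChromothripsisParams = ChromothripsisParams(),
) -> CriterionResult:
    """C4: no rank correlation between the reference order of each
    join's first breakend and its partner's position. Satisfied on
    non-rejection.

    The A/B breakends are used as given (the derived-chromosome exit and
    entry of the adjacency) rather than min/max per join: the min and
    max of an independent uniform pair are positively correlated by
    construction (rho = 0.5), which would break the null calibration.
    """
    cid = CRITERIA[3]
    intra = [j for j in joins if j.intrachromosomal]
    if len(intra) < params.min_joins_order:
        return _not_evaluable(cid, f"{len(intra)} joins < {params.min_joins_order}")
    left = np.asarray([j.pos_a for j in intra], dtype=float)
    partner = np.asarray([j.pos_b for j in intra], dtype=float)
    if np.all(left == left[0]) or np.all(partner == partner[0]):
        return _not_evaluable(cid, "degenerate positions")
    rho, p = sps.spearmanr(left, partner)
    return CriterionResult(
        criterion=cid,
        statistic=float(rho),
        p_value=float(p),
        satisfied=p >= params.alpha,
        evaluable=True,
        detail=f"n={len(intra)}",
    )


def call_chromothripsis(
    segments: Sequence[CNSegment],
    joins: Sequence[BreakpointJoin],
    chrom_length: int,
    params: ChromothripsisParams = ChromothripsisParams(),
    sample: str = "",
    chrom: str = "",
) -> ChromothripsisEvaluation:
    """Run the four criteria on one sample-chromosome and combine with
    the >=2-of-4 rule. Non-evaluable criteria count as not satisfied."""
    if not sample and segments:
        sample = segments[0].sample
    if not chrom:
        if segments:
            chrom = segments[0].chrom
        elif joins:
            chrom = joins[0].chrom_a

    if segments:
        c1 = criterion_oscillation(infer_cn_states(segments), params)
    else:
        c1 = _not_evaluable(CRITERIA[0], "no segments")

    # breakpoint set for C2: join breakends plus interior segment
    # boundaries (chromosome ends are tiling artifacts, not breakpoints)
    intra = [j for j in joins if j.intrachromosomal]
    breakends = {p for j in intra for p in (j.pos_a, j.pos_b)}
    breakends.update(b for s in segments for b in (s.start, s.end))
    breakends -= {0, chrom_length}
    positions = sorted(breakends)
    if positions:
        c2 = criterion_breakpoint_clustering(positions, chrom_length, params)
    else:
        c2 = _not_evaluable(CRITERIA[1], "no breakpoints")
    c3 = criterion_join_randomness(joins, params)
    c4 = criterion_order_randomness(joins, params)

    criteria = (c1, c2, c3, c4)
    n_sat = sum(c.satisfied for c in criteria)
    return ChromothripsisEvaluation(
        sample=sample,
        chrom=chrom,
        criteria=criteria,
        n_satisfied=n_sat,
        call=n_sat >= 2,
        borderline=n_sat == 2,
    )


def evaluate_cohort(
    segments: Sequence[CNSegment],
    joins: Sequence[BreakpointJoin],
    chrom_lengths: Dict[str, int],
    params: ChromothripsisParams = ChromothripsisParams(),
    samples: Optional[Sequence[str]] = None,
) -> List[ChromothripsisEvaluation]:
    """Group inputs by (sample, chromosome) and evaluate each pair.

    ``joins`` must be provided per sample via their ``name`` field holding
    the sample id; interchromosomal joins are ignored.
    """
    keys = set()
    seg_by: Dict[Tuple[str, str], List[CNSegment]] = {}
    for s in segments:
        seg_by.setdefault((s.sample, s.chrom), []).append(s)
        keys.add((s.sample, s.chrom))
    join_by: Dict[Tuple[str, str], List[BreakpointJoin]] = {}
    for j in joins:
        if not j.intrachromosomal:
            continue
        join_by.setdefault((j.name, j.chrom_a), []).append(j)
        keys.add((j.name, j.chrom_a))
    if samples is not None:
        keys = {k for k in keys if k[0] in set(samples)}
    out = []
    for sample, chrom in sorted(keys):
        if chrom not in chrom_lengths:
            raise InputError(f"unknown chromosome {chrom!r}")
        segs = sorted(seg_by.get((sample, chrom), []), key=lambda s: s.start)
        out.append(
            call_chromothripsis(
                segs,
                join_by.get((sample, chrom), []),
                chrom_lengths[chrom],
                params,
                sample=sample,
                chrom=chrom,
            )
        )
    return out


def compare_cohort_frequency(
    calls_a: Sequence[bool], calls_b: Sequence[bool]
) -> ContingencyResult:
    """One-sided Fisher exact comparison of positive-call frequency,
    direction: greater in cohort A."""
    if not len(calls_a) or not len(calls_b):
        raise InputError("both cohorts must be non-empty")
    a = sum(bool(x) for x in calls_a)
    c = sum(bool(x) for x in calls_b)
    table = ((a, len(calls_a) - a), (c, len(calls_b) - c))
    return fisher_exact(table, sidedness="greater")
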