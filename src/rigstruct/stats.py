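"""Patient-level statistics: medians, Fisher exact tests, odds ratios,
Kaplan-Meier estimation, and the two-group log-rank test.

The Fisher test is computed directly from the hypergeometric distribution
(two-sided rule: sum of the probabilities of all fixed-margin tables whose
probability does not exceed the observed table's).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .model import InputError

__all__ = [
    "ContingencyResult",
    "KMEstimate",
    "median_and_range",
    "fisher_exact",
    "odds_ratio_ci",
    "km_estimate",
    "logrank",
    "mann_whitney",
]

_REL_TOL = 1 + 1e-9  # float guard for the "probability <= observed" rule


@dataclass
class ContingencyResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    sidedness: str
    p_value: float
    odds_ratio: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    ci_level: float = 0.95
    degenerate: bool = False
    undefined_or: bool = False


@dataclass
class KMEstimate:
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float  # NaN when S never reaches 0.5
    median_ci: Tuple[float, float]

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def median_and_range(
    values: Sequence[Optional[float]],
) -> Tuple[float, float, float, int]:
    """Median, min, max, and n over the non-missing values.

    Missing is ``None`` or NaN. Even-n median is the mean of the central
    pair. All-missing input is an error.
    """
    clean = [float(v) for v in values if v is not None and not math.isnan(float(v))]
    if not clean:
        raise InputError("no non-missing values")
    arr = np.sort(np.asarray(clean))
    return float(np.median(arr)), float(arr[0]), float(arr[-1]), len(arr)


def _validate_table(table) -> Tuple[int, int, int, int]:
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if int(x) != x or x < 0:
            raise InputError("table entries must be non-negative integers")
    return int(a), int(b), int(c), int(d)


def fisher_exact(table, sidedness: str = "two-sided") -> ContingencyResult:
    """Fisher's exact test on a 2x2 table.

    sidedness: "two-sided", "greater" (upper tail of the top-left cell,
    i.e. enrichment in row 1 / column 1), or "less".

    A zero margin makes every fixed-margin table identical; p is then 1
    and the result is flagged degenerate.
    """
    a, b, c, d = _validate_table(table)
    if sidedness not in ("two-sided", "greater", "less"):
        raise InputError(f"unknown sidedness {sidedness!r}")
    res = _or_result(a, b, c, d, sidedness)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 in (0, n) or c1 in (0, n):
        res.p_value = 1.0
        res.degenerate = True
        return res

    # support of the top-left cell given fixed margins
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)

    if sidedness == "two-sided":
        p = float(pmf[pmf <= p_obs * _REL_TOL].sum())
    elif sidedness == "greater":
        p = float(pmf[support >= a].sum())
    else:
        p = float(pmf[support <= a].sum())
    res.p_value = min(p, 1.0)
    return res


def _or_result(a: int, b: int, c: int, d: int, sidedness: str) -> ContingencyResult:
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        odds = float("nan")
        undefined = True
    elif b * c == 0:
        odds = float("inf")
        undefined = False
    else:
        odds = (a * d) / (b * c)
        undefined = False
    return ContingencyResult(
        table=((a, b), (c, d)),
        sidedness=sidedness,
        p_value=float("nan"),
        odds_ratio=odds,
        undefined_or=undefined,
    )


def odds_ratio_ci(table, level: float = 0.95) -> ContingencyResult:
    """Odds ratio ad/bc with a log-normal CI.

    When any cell is zero the Haldane-Anscombe 0.5 correction is applied
    to the CI computation (the point estimate is left uncorrected). Two
    zero cells on one diagonal leave the OR undefined.
    """
    a, b, c, d = _validate_table(table)
    res = _or_result(a, b, c, d, "two-sided")
    res.ci_level = level
    res.p_value = fisher_exact(table).p_value
    if res.undefined_or:
        return res
    cells = [a, b, c, d]
    if 0 in cells:
        cells = [x + 0.5 for x in cells]
    aa, bb, cc, dd = cells
    log_or = math.log((aa * dd) / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = sps.norm.ppf(0.5 + level / 2)
    res.ci_low = math.exp(log_or - z * se)
    res.ci_high = math.exp(log_or + z * se)
    return res


def km_estimate(
    times: Sequence[float],
    event_flags: Sequence[bool],
    ci_level: float = 0.95,
) -> KMEstimate:
    """Product-limit survival estimate with Greenwood log(-log) intervals.

    The median is the smallest event time with S(t) <= 0.5 (NaN when the
    curve never reaches 0.5). Its CI inverts the pointwise survival CI
    (Brookmeyer-Crowley style): the lower bound is the first time the
    upper survival band drops to 0.5, the upper bound the first time the
    lower band does.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise InputError("times and event_flags must be 1-d and equal length")
    if np.any(t < 0):
        raise InputError("times must be >= 0")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]

    event_times = np.unique(t[e])
    n_total = len(t)
    surv, lo_band, hi_band, at_risk, d_counts = [], [], [], [], []
    s = 1.0
    var_sum = 0.0  # Greenwood sum d/(n(n-d))
    z = sps.norm.ppf(0.5 + ci_level / 2)
    for et in event_times:
        n_i = int(np.sum(t >= et))
        d_i = int(np.sum((t == et) & e))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            var_sum += d_i / (n_i * (n_i - d_i))
        if 0.0 < s < 1.0:
            se_theta = math.sqrt(var_sum) / abs(math.log(s))
            lo = s ** math.exp(z * se_theta)
            hi = s ** math.exp(-z * se_theta)
        else:
            lo = hi = s
        surv.append(s)
        lo_band.append(lo)
        hi_band.append(hi)
        at_risk.append(n_i)
        d_counts.append(d_i)

    surv_arr = np.asarray(surv)
    median = float("nan")
    if len(event_times) and np.any(surv_arr <= 0.5):
        median = float(event_times[np.argmax(surv_arr <= 0.5)])
    med_lo = med_hi = float("nan")
    if len(event_times):
        hi_arr = np.asarray(hi_band)
        lo_arr = np.asarray(lo_band)
        if np.any(hi_arr <= 0.5):
            med_lo = float(event_times[np.argmax(hi_arr <= 0.5)])
        if np.any(lo_arr <= 0.5):
            med_hi = float(event_times[np.argmax(lo_arr <= 0.5)])
    return KMEstimate(
        times=event_times,
        survival=surv_arr,
        ci_low=np.asarray(lo_band),
        ci_high=np.asarray(hi_band),
        n_at_risk=np.asarray(at_risk),
        n_events=np.asarray(d_counts),
        median=median,
        median_ci=(med_lo, med_hi),
    )


def logrank(
    group_a: Sequence[Tuple[float, bool]],
    group_b: Sequence[Tuple[float, bool]],
) -> Tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    if not len(group_a) or not len(group_b):
        raise InputError("both groups must be non-empty")
    t_a = np.asarray([t for t, _ in group_a], dtype=float)
    e_a = np.asarray([bool(f) for _, f in group_a])
    t_b = np.asarray([t for t, _ in group_b], dtype=float)
    e_b = np.asarray([bool(f) for _, f in group_b])
    all_event_times = np.unique(np.concatenate([t_a[e_a], t_b[e_b]]))
    if not len(all_event_times):
        raise InputError("at least one event is required")

    obs_minus_exp = 0.0
    var = 0.0
    for et in all_event_times:
        n1 = int(np.sum(t_a >= et))
        n2 = int(np.sum(t_b >= et))
        d1 = int(np.sum((t_a == et) & e_a))
        d2 = int(np.sum((t_b == et) & e_b))
        n, d = n1 + n2, d1 + d2
        if n == 0 or d == 0:
            continue
        exp1 = d * n1 / n
        obs_minus_exp += d1 - exp1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = obs_minus_exp**2 / var
    return float(stat), float(sps.chi2.sf(stat, df=1))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Thin Wilcoxon-Mann-Whitney wrapper; returns (U, two-sided p)."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
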