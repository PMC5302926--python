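"""Rate and group-difference statistics for cohort summaries.

Positive-rate comparisons use Pearson's chi-square (no continuity
correction by default); reference-Ct group comparisons use the
Mann-Whitney U test (normal approximation, tie-corrected variance) and
Welch's unequal-variance t test.  All p values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedRateError, ValidationError, ZeroExpectedCountError
from .gating_and_calls import Call

__all__ = [
    "TwoByTwoTable",
    "GroupComparison",
    "positive_rate",
    "chi_square_2x2",
    "mann_whitney",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts for a 2x2 contingency table (rows = groups, columns = outcome)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if value < 0 or value != int(value):
                raise ValidationError(f"cell {name} must be a non-negative integer, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group location comparison on the Ct scale.

    ``delta_ct`` is ``median_b - median_a``: positive means group b has the
    higher Ct (i.e. the lower template input).
    """

    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    delta_ct: float
    u_statistic: float
    t_statistic: float
    p_mw: float
    p_t: float


def positive_rate(calls: Iterable[Call]) -> float:
    """Percentage of POSITIVE calls, at full precision (round for display)."""
    calls = list(calls)
    if not calls:
        raise UndefinedRateError("positive rate is undefined for an empty set of calls")
    return 100.0 * sum(c is Call.POSITIVE for c in calls) / len(calls)


def chi_square_2x2(table: TwoByTwoTable, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and upper-tail p on 1 df.

    Yates continuity correction is available behind ``continuity`` but off
    by default.  Raises :class:`ZeroExpectedCountError` when any expected
    count is zero (use an exact test instead).
    """
    observed = table.as_array()
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    total = observed.sum()
    if total == 0:
        raise ZeroExpectedCountError("empty table")
    expected = row @ col / total
    if np.any(expected == 0):
        raise ZeroExpectedCountError(
            "a zero expected count makes the chi-square approximation invalid; "
            "use an exact test"
        )
    diff = np.abs(observed - expected)
    if continuity:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(statistic, df=1))
    return statistic, p


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U (normal approximation with tie-corrected
    variance, midranks for ties) plus Welch's t, medians, means, and delta.

    The U statistic reported is the number of (a, b) pairs with a > b,
    counting ties as 1/2.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must contain at least one value")

    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    rank_sum_a = float(ranks[:n_a].sum())
    u_a = rank_sum_a - n_a * (n_a + 1) / 2.0

    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    mean_u = n_a * n_b / 2.0
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_u > 0:
        z = (u_a - mean_u) / np.sqrt(var_u)
        p_mw = float(2.0 * sps.norm.sf(abs(z)))
    else:
        p_mw = 1.0  # all pooled values identical

    if n_a > 1 and n_b > 1 and (np.std(a) > 0 or np.std(b) > 0):
        t_res = sps.ttest_ind(a, b, equal_var=False)
        t_stat, p_t = float(t_res.statistic), float(t_res.pvalue)
    else:
        t_stat, p_t = float("nan"), float("nan")

    median_a, median_b = float(np.median(a)), float(np.median(b))
    return GroupComparison(
        median_a=median_a,
        median_b=median_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        delta_ct=median_b - median_a,
        u_statistic=float(u_a),
        t_statistic=t_stat,
        p_mw=min(p_mw, 1.0),
        p_t=p_t,
    )
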