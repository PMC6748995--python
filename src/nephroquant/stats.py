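"""Group summaries and t-test comparisons of per-experiment ratios.

Conditions are compared on the means of per-experiment ratios with a
two-sided t-test: the independent two-sample pooled-variance Student test by
default (df = nA + nB - 2), Welch's unequal-variance variant by flag, or the
paired test (df = n - 1) for matched designs. Comparisons accept either the
raw per-experiment values or (mean, SD, n) summary statistics. Significance
is flagged at alpha = 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSummary", "GroupComparison", "summarize", "compare"]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD (n-1) and count of per-experiment ratios."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Two-condition comparison on the means of per-experiment ratios."""

    condition_a: str
    condition_b: str
    summary_a: GroupSummary
    summary_b: GroupSummary
    variant: str  # "independent" | "welch" | "paired"
    t: float
    df: float
    p: float
    fold_change: float  # mean_b / mean_a

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def summarize(values: Sequence[float]) -> GroupSummary:
    """Arithmetic mean, sample SD (divisor n-1) and n of a ratio series.

    A single value has no dispersion estimate; its SD is reported as 0 with
    a warning (documented convention).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    if x.size == 1:
        warnings.warn("single value: SD undefined, reported as 0", stacklevel=2)
        return GroupSummary(mean=float(x[0]), sd=0.0, n=1)
    return GroupSummary(
        mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size)
    )


def _two_sided_p(t: float, df: float) -> float:
    if math.isinf(t):
        return 0.0
    return float(2.0 * sps.t.sf(abs(t), df))


def _as_summary(group) -> GroupSummary:
    if isinstance(group, GroupSummary):
        return group
    if isinstance(group, tuple) and len(group) == 3:
        return GroupSummary(float(group[0]), float(group[1]), int(group[2]))
    return summarize(group)


def compare(
    group_a,
    group_b,
    variant: str = "independent",
    condition_a: str = "A",
    condition_b: str = "B",
) -> GroupComparison:
    """Compare two groups of per-experiment ratios.

    ``group_a``/``group_b`` are sequences of raw values, ``GroupSummary``
    objects, or ``(mean, sd, n)`` tuples (summary input is accepted for the
    independent and Welch variants; the paired test needs raw values).
    Degenerate dispersion follows fixed conventions: zero pooled variance
    with equal means gives t = 0, p = 1; with unequal means the t statistic
    is infinite and p = 0, with a warning.
    """
    if variant == "paired":
        a = np.asarray(list(group_a), dtype=float)
        b = np.asarray(list(group_b), dtype=float)
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        if a.size < 2:
            raise ValueError("paired test requires n >= 2")
        d = b - a
        sd_d = float(d.std(ddof=1))
        df = float(a.size - 1)
        if sd_d == 0:
            t = 0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
            if t != 0:
                warnings.warn(
                    "zero variance of paired differences with nonzero mean; "
                    "t is infinite, p -> 0",
                    stacklevel=2,
                )
        else:
            t = float(d.mean() / (sd_d / math.sqrt(a.size)))
        sa, sb = summarize_quiet(a), summarize_quiet(b)
    elif variant in ("independent", "welch"):
        sa, sb = _as_summary(group_a), _as_summary(group_b)
        if sa.n < 2 or sb.n < 2:
            raise ValueError("independent test requires n >= 2 per group")
        diff = sb.mean - sa.mean
        if variant == "independent":
            df = float(sa.n + sb.n - 2)
            pooled_var = (
                (sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2
            ) / df
            se = math.sqrt(pooled_var * (1.0 / sa.n + 1.0 / sb.n))
        else:
            va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
            se = math.sqrt(va + vb)
            df = (
                (va + vb) ** 2
                / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
                if va + vb > 0
                else float(sa.n + sb.n - 2)
            )
        if se == 0:
            t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
            if t != 0:
                warnings.warn(
                    "zero variance with unequal means; t is infinite, p -> 0",
                    stacklevel=2,
                )
        else:
            t = float(diff / se)
    else:
        raise ValueError(f"unknown test variant {variant!r}")

    p = 1.0 if t == 0 else _two_sided_p(t, df)
    fold = sb.mean / sa.mean if sa.mean != 0 else math.inf
    return GroupComparison(
        condition_a=condition_a,
        condition_b=condition_b,
        summary_a=sa,
        summary_b=sb,
        variant=variant,
        t=t,
        df=df,
        p=p,
        fold_change=float(fold),
    )


def summarize_quiet(values) -> GroupSummary:
    """summarize() without the single-value warning (internal use)."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 1:
        return GroupSummary(mean=float(x[0]), sd=0.0, n=1)
    return summarize(x)
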