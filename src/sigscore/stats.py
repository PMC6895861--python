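"""Inferential layer: Pearson correlation, Fisher's exact mutual-exclusivity
test, and two-group (Welch) score comparisons.

No multiple-testing correction is applied anywhere; every report lists raw
p-values and says so.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, inf, nan

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "FisherResult",
    "ContingencyTable2x2",
    "GroupComparisonResult",
    "MutualExclusivityResult",
    "pearson_correlation",
    "fisher_exact_two_sided",
    "mutual_exclusivity",
    "compare_groups_welch",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float

    def to_dict(self) -> dict:
        return {"r": self.r, "n": self.n, "p": self.p}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = marker A high/low, columns = marker B high/low."""

    a: int  # A high, B high
    b: int  # A high, B low
    c: int  # A low,  B high
    d: int  # A low,  B low

    def __post_init__(self) -> None:
        for name, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a non-negative integer, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_list(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # inf when b*c == 0 with a*d > 0; nan when 0/0
    p: float

    def to_dict(self) -> dict:
        odds = self.odds_ratio
        return {
            "odds_ratio": None if np.isnan(odds) else ("inf" if np.isinf(odds) else odds),
            "p": self.p,
        }


@dataclass(frozen=True)
class GroupComparisonResult:
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    p: float

    def to_dict(self) -> dict:
        return {
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "t": self.t,
            "p": self.p,
        }


@dataclass(frozen=True)
class MutualExclusivityResult:
    table: ContingencyTable2x2
    fisher: FisherResult
    co_occurrence: int
    exclusive: bool  # no sample is high for both markers


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-reference p-value.

    p is computed from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom. Inputs must have equal length >= 3 and be non-constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=int(n), p=float(p))


def fisher_exact_two_sided(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p-value sums, over all tables sharing the observed margins,
    the hypergeometric probabilities that do not exceed the observed table's
    probability — computed in exact integer arithmetic, so ties in probability
    are handled without floating-point ambiguity. The odds ratio is the sample
    (a*d)/(b*c), with inf for b*c == 0 (a*d > 0) and nan for 0/0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = table.total
    # hypergeometric numerators share the denominator C(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    num_sum = sum(
        w for x in range(lo, hi + 1) if (w := comb(r1, x) * comb(r2, c1 - x)) <= num_obs
    )
    p = num_sum / comb(n, c1)
    if b * c == 0:
        odds = nan if a * d == 0 else inf
    else:
        odds = (a * d) / (b * c)
    return FisherResult(odds_ratio=odds, p=float(min(p, 1.0)))


def mutual_exclusivity(labels_a: pd.Series, labels_b: pd.Series) -> MutualExclusivityResult:
    """Test whether two high/low markers co-occur less than expected.

    Builds the 2x2 table of A-high/low x B-high/low over the shared sample
    universe, reports the A-high AND B-high count, and attaches the two-sided
    Fisher result. ``exclusive`` is True when the co-occurrence cell is 0.
    """
    labels_a = pd.Series(labels_a)
    labels_b = pd.Series(labels_b)
    if not labels_a.index.equals(labels_b.index):
        if set(labels_a.index) != set(labels_b.index):
            raise ValueError("label vectors cover different sample universes")
        labels_b = labels_b.loc[labels_a.index]
    for name, lab in (("A", labels_a), ("B", labels_b)):
        bad = set(lab.unique()) - {"high", "low"}
        if bad:
            raise ValueError(f"labels {name} contain values other than high/low: {bad}")
    ah = labels_a == "high"
    bh = labels_b == "high"
    table = ContingencyTable2x2(
        a=int((ah & bh).sum()),
        b=int((ah & ~bh).sum()),
        c=int((~ah & bh).sum()),
        d=int((~ah & ~bh).sum()),
    )
    fisher = fisher_exact_two_sided(table)
    return MutualExclusivityResult(
        table=table,
        fisher=fisher,
        co_occurrence=table.a,
        exclusive=table.a == 0,
    )


def compare_groups_welch(values, labels) -> GroupComparisonResult:
    """Welch (unequal-variance) two-sample t-test on a binary grouping.

    ``labels`` must take exactly two values with >= 2 samples each; group A is
    the lexicographically smaller label.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    va = values[labels == groups[0]]
    vb = values[labels == groups[1]]
    if va.size < 2 or vb.size < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {va.size} and {vb.size})"
        )
    if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
        # scipy yields nan for two zero-variance groups; resolve by means
        if va.mean() == vb.mean():
            t, p = 0.0, 1.0
        else:
            t = inf if va.mean() > vb.mean() else -inf
            p = float(np.finfo(float).tiny)
    else:
        t, p = sps.ttest_ind(va, vb, equal_var=False)
    return GroupComparisonResult(
        mean_a=float(va.mean()),
        mean_b=float(vb.mean()),
        n_a=int(va.size),
        n_b=int(vb.size),
        t=float(t),
        p=float(p),
    )
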