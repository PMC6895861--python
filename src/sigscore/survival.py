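"""Kaplan-Meier estimation, log-rank testing, and expression-based
stratification rules (geometric-mean split, score-sign quadrants)."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "SurvivalCurve",
    "LogrankResult",
    "km_estimate",
    "logrank_test",
    "geometric_mean_split",
    "quadrant_stratify",
]

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit estimate over the observed event-time grid.

    ``median`` is the smallest event time t with S(t) <= 0.5, or ``inf``
    ("not reached") when the curve never drops that far.
    """

    times: np.ndarray  # event times (deaths observed), ascending
    survival: np.ndarray  # S(t) at each event time
    at_risk: np.ndarray  # number at risk just before each event time
    median: float

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p": self.p}


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no survival records")
    if times.shape != events.shape:
        raise ValueError("times and events must align")
    if not np.isfinite(times).all() or (times <= 0).any():
        raise ValueError("survival times must be finite and > 0")
    return times, events


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Parameters are per-sample follow-up times (days) and event indicators
    (True = death observed, False = censored). The returned grid contains the
    distinct times at which a death occurred.
    """
    times, events = _check_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    death_rows = tbl[tbl["observed"] > 0]
    grid = death_rows.index.to_numpy(dtype=float)
    if grid.size:
        surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
        at_risk = death_rows["at_risk"].to_numpy(dtype=int)
        below = np.nonzero(surv <= 0.5)[0]
        median = float(grid[below[0]]) if below.size else math.inf
    else:
        surv = np.empty(0)
        at_risk = np.empty(0, dtype=int)
        median = math.inf
    return SurvivalCurve(times=grid, survival=surv, at_risk=at_risk, median=median)


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group log-rank test (observed - expected over pooled event times),
    two-sided p from a 1-df chi-square."""
    times_a, events_a = _check_times_events(times_a, events_a)
    times_b, events_b = _check_times_events(times_b, events_b)
    if int(events_a.sum()) + int(events_b.sum()) == 0:
        raise ValueError("log-rank test undefined with zero events overall")
    res = _lifelines_logrank(times_a, times_b, event_observed_A=events_a,
                             event_observed_B=events_b)
    return LogrankResult(statistic=float(res.test_statistic), p=float(res.p_value))


def geometric_mean_split(
    expr: pd.DataFrame, gene: str, pseudocount: float = 0.0
) -> tuple[pd.Series, dict[str, int]]:
    """Dichotomize a cohort around one gene's geometric mean expression.

    gm = exp(mean(log(x + pseudocount))); samples strictly above gm are
    "high", strictly below are "low", and exact ties go to "high" (logged).
    With the default pseudocount of 0, zero values are an error (microarray
    intensities are positive); set a small epsilon for RNA-seq zeros.
    """
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} not in the expression matrix")
    values = expr.loc[gene].to_numpy(dtype=float) + pseudocount
    if (values <= 0).any():
        raise ValueError(
            f"gene {gene!r} has non-positive values; set a pseudocount > 0"
        )
    gm = float(np.exp(np.mean(np.log(values))))
    ties = int((values == gm).sum())
    if ties:
        logger.warning(
            "%d sample(s) exactly at the geometric mean %.6g labelled 'high'",
            ties,
            gm,
        )
    labels = pd.Series(
        np.where(values >= gm, "high", "low"), index=expr.columns, name=f"{gene}_gm"
    )
    sizes = {"high": int((labels == "high").sum()), "low": int((labels == "low").sum())}
    return labels, sizes


def quadrant_stratify(
    score_a: pd.Series,
    score_b: pd.Series,
    thresholds: tuple[float, float] = (0.0, 0.0),
) -> tuple[pd.Series, pd.Index, pd.Index]:
    """Sign-quadrant labels from two scores, plus the (+,+) vs (-,-) contrast.

    A score at or above its threshold counts as "+". Returns the per-sample
    quadrant labels ("++", "+-", "-+", "--") and the double-positive and
    double-negative sample index sets for a downstream log-rank comparison.
    """
    score_a = pd.Series(score_a)
    score_b = pd.Series(score_b)
    if not score_a.index.equals(score_b.index):
        raise ValueError("scores must cover the same samples in the same order")
    va = score_a.to_numpy(dtype=float)
    vb = score_b.to_numpy(dtype=float)
    if not (np.isfinite(va).all() and np.isfinite(vb).all()):
        raise ValueError("scores must be finite")
    ta, tb = thresholds
    pa = np.where(va >= ta, "+", "-")
    pb = np.where(vb >= tb, "+", "-")
    labels = pd.Series(np.char.add(pa, pb), index=score_a.index, name="quadrant")
    return labels, labels.index[labels == "++"], labels.index[labels == "--"]
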