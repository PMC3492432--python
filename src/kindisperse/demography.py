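"""Tenure survival analysis and sex-bias count tests.

Kaplan-Meier product-limit curves of group tenure (natal or breeding
context) with right-censoring, log-rank comparison of the sexes, and
count tests (chi-square with Yates' continuity correction, Fisher's exact
test) for whether one sex immigrates or emigrates more often than expected
from its share of the population.  The expected event count for a sex is
the total number of events multiplied by that sex's proportion of animals.

The median tenure is the smallest observed time at which the survival
function drops to 0.5 or below; when fewer than half of the animals
experienced the event the median is undefined (None).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CountTestResult",
    "kaplan_meier",
    "logrank_test",
    "sex_bias_count_test",
]


@dataclass
class SurvivalCurve:
    """A product-limit survival estimate over months of tenure."""

    times: np.ndarray          # event/censoring times in ascending order
    survival: np.ndarray       # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    median: float | None       # months; None when S never reaches 0.5
    n: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "at_risk": self.at_risk,
            "events": self.events, "censored": self.censored,
            "survival": self.survival,
        })


def _filter(tenures: pd.DataFrame, context: str | None, sex: str | None) -> pd.DataFrame:
    df = tenures
    if context is not None:
        df = df[df["context"] == context]
    if sex is not None:
        df = df[df["sex"] == sex]
    return df


def kaplan_meier(tenures: pd.DataFrame, context: str | None = None,
                 sex: str | None = None) -> SurvivalCurve:
    """Kaplan-Meier estimate for one stratum of the tenure table.

    Censored records leave the risk set without contributing events; ties
    between events and censorings at the same time are resolved by
    processing the events first (the censored animal is still at risk for
    the event).
    """
    df = _filter(tenures, context, sex)
    if df.empty:
        raise ValueError("empty stratum")
    if (df["duration"] <= 0).any():
        raise ValueError("durations must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(df["duration"], event_observed=df["event_observed"].astype(bool))
    table = kmf.event_table
    table = table[table.index > 0]  # drop lifelines' t=0 bookkeeping row
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    median = kmf.median_survival_time_
    return SurvivalCurve(
        times=times, survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
        median=None if np.isinf(median) else float(median),
        n=len(df),
    )


@dataclass
class CountTestResult:
    """Outcome of a two-group count comparison."""

    observed: dict[str, float]
    expected: dict[str, float]
    statistic: float
    df: int
    p: float
    method: str
    statistic_uncorrected: float | None = None


def logrank_test(tenures: pd.DataFrame, context: str | None = None,
                 by: str = "sex") -> CountTestResult:
    """Log-rank comparison of tenure between the two levels of ``by``."""
    df = _filter(tenures, context, None)
    levels = sorted(df[by].unique())
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly two strata, got {levels}")
    g0 = df[df[by] == levels[0]]
    g1 = df[df[by] == levels[1]]
    if g0.empty or g1.empty:
        raise ValueError("a stratum has zero subjects")
    res = _ll_logrank(g0["duration"], g1["duration"],
                      event_observed_A=g0["event_observed"].astype(bool),
                      event_observed_B=g1["event_observed"].astype(bool))
    return CountTestResult(
        observed={levels[0]: int(g0["event_observed"].sum()),
                  levels[1]: int(g1["event_observed"].sum())},
        expected={}, statistic=float(res.test_statistic), df=1,
        p=float(res.p_value), method="log_rank",
    )


def sex_bias_count_test(events_male: int, events_female: int,
                        n_male: int, n_female: int,
                        method: str = "chi_square_yates") -> CountTestResult:
    """Do males (or females) show more events than their population share?

    Expected counts: total events times each sex's proportion of the
    population.  ``chi_square_yates`` runs the 1-df goodness-of-fit test
    with the |O-E|-0.5 continuity correction against those expectations;
    ``fisher_exact`` tests the 2x2 sex-by-outcome table (two-sided, by the
    point-probability rule).
    """
    if n_male <= 0 or n_female <= 0:
        raise ValueError("population counts must be positive")
    total_events = events_male + events_female
    prop_male = n_male / (n_male + n_female)
    expected = {"male": total_events * prop_male,
                "female": total_events * (1 - prop_male)}
    observed = {"male": float(events_male), "female": float(events_female)}
    if method == "chi_square_yates":
        if min(expected.values()) == 0:
            raise ValueError("expected count of zero")
        stat = sum((max(abs(observed[s] - expected[s]) - 0.5, 0.0)) ** 2
                   / expected[s] for s in observed)
        uncorr = sum((observed[s] - expected[s]) ** 2 / expected[s]
                     for s in observed)
        return CountTestResult(observed=observed, expected=expected,
                               statistic=float(stat), df=1,
                               p=float(stats.chi2.sf(stat, 1)),
                               method=method,
                               statistic_uncorrected=float(uncorr))
    if method == "fisher_exact":
        if events_male > n_male or events_female > n_female:
            raise ValueError("more events than animals")
        table = [[events_male, n_male - events_male],
                 [events_female, n_female - events_female]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return CountTestResult(observed=observed, expected=expected,
                               statistic=float(odds), df=1, p=float(p),
                               method=method)
    raise ValueError(f"unknown method {method!r}")
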