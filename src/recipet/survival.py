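"""Survival statistics: Kaplan-Meier, log-rank, univariate Cox, C-index.

The estimators themselves are standard and are delegated to lifelines
(Kaplan-Meier product-limit, unstratified 1-df log-rank, Cox partial
likelihood with Efron tie handling and Wald confidence intervals); this
module fixes the input contract (times in months from the follow-up scan,
event = 1 for death, 0 for censoring), the error behaviour, and the
"median not reached" convention used when reporting.

Harrell's concordance index is implemented directly from its pairwise
definition — a patient pair is comparable when the shorter observed time
ended in death; the index is the fraction of comparable pairs in which
the higher-risk patient failed first, with risk ties counting one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CoxFit",
    "UndefinedStatisticError",
    "CoxDiagnosticError",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "concordance_index",
]

MEDIAN_NOT_REACHED = math.inf


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for these data (e.g. no events)."""


class CoxDiagnosticError(RuntimeError):
    """The Cox partial likelihood could not be maximised (separation, constancy)."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time (months), death indicator, covariate."""

    time: float
    event: int
    covariate: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time <= 0:
            raise ValueError("survival time must be finite and positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate at the observed event times."""

    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    median: float  # months; MEDIAN_NOT_REACHED (inf) when S never drops to 0.5

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)


@dataclass(frozen=True)
class CoxFit:
    log_hr: float
    hr: float
    ci95: tuple[float, float]
    wald_p: float
    c_index: float
    n: int
    n_events: int


def _to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "covariate": [r.covariate for r in records],
        }
    )


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier estimate; the median is the smallest event time with
    S(t) <= 0.5, or ``MEDIAN_NOT_REACHED`` (inf)."""
    if len(records) == 0:
        raise ValueError("at least one record is required")
    df = _to_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    event_times = sorted(df.loc[df["event"] == 1, "time"].unique())
    surv = [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    times = np.asarray(df["time"])
    at_risk = [int((times >= t).sum()) for t in event_times]
    median = float(kmf.median_survival_time_)
    return KMCurve(tuple(event_times), tuple(surv), tuple(at_risk), median)


def km_table(curve: KMCurve) -> pd.DataFrame:
    """KM curve as a tidy frame (time, survival, at_risk) for CSV export."""
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
        }
    )


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Unstratified 1-df log-rank test; returns (chi-square, p)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a) and not any(r.event for r in group_b):
        raise UndefinedStatisticError("log-rank statistic undefined with no events")
    res = _ll_logrank(
        [r.time for r in group_a],
        [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(
    records: Sequence[SurvivalRecord],
    ties: str = "efron",
) -> CoxFit:
    """Univariate Cox proportional-hazards fit of the record covariate.

    Efron tie handling by default (``ties="breslow"`` available); the 95%
    confidence interval and p-value are Wald-based. The reported C-index
    is Harrell's concordance of the fitted risk with the outcomes.
    """
    df = _to_frame(records)
    if df["covariate"].nunique() <= 1:
        raise CoxDiagnosticError("covariate is constant; hazard ratio not identifiable")
    binary = set(df["covariate"].unique()) <= {0.0, 1.0}
    if binary:
        events_per_level = df.groupby("covariate")["event"].sum()
        if (events_per_level == 0).any():
            raise CoxDiagnosticError(
                "no events in one covariate level (monotone likelihood / separation)"
            )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise CoxDiagnosticError(f"Cox fit failed to converge: {err}") from err
    log_hr = float(cph.params_["covariate"])
    se = float(cph.standard_errors_["covariate"])
    if not math.isfinite(log_hr) or not math.isfinite(se) or se > 50:
        raise CoxDiagnosticError("Cox fit degenerate (monotone likelihood suspected)")
    lo, hi = math.exp(log_hr - 1.96 * se), math.exp(log_hr + 1.96 * se)
    c = concordance_index(records, [r.covariate * log_hr for r in records])
    return CoxFit(
        log_hr=log_hr,
        hr=math.exp(log_hr),
        ci95=(lo, hi),
        wald_p=float(cph.summary.loc["covariate", "p"]),
        c_index=c,
        n=len(records),
        n_events=int(df["event"].sum()),
    )


def concordance_index(
    records: Sequence[SurvivalRecord], risk: Sequence[float]
) -> float:
    """Harrell's C from the pairwise definition (risk ties count 0.5)."""
    if len(records) != len(risk):
        raise ValueError("records and risk scores must have equal length")
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=int)
    risk = np.asarray(risk, dtype=float)
    n = len(times)
    comparable = 0
    score = 0.0
    for i in range(n):
        if events[i] != 1:
            continue
        # subject i died at times[i]; compare with everyone observed longer
        longer = (times > times[i]) | ((times == times[i]) & (events == 0))
        comparable += int(longer.sum())
        score += float((risk[i] > risk[longer]).sum())
        score += 0.5 * float((risk[i] == risk[longer]).sum())
    if comparable == 0:
        raise UndefinedStatisticError("no comparable pairs for the concordance index")
    return score / comparable
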