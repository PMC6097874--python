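"""Lifespan analysis: censoring rules, Kaplan-Meier curves, log-rank tests.

Assays start with day-1 adults scored for survival on alternate days; worms
that go missing, bag (internally hatched progeny) or show physical damage
are censored at their last observed day.  Survival curves use the
product-limit estimator and group comparisons use the Mantel-Cox log-rank
test (both via ``lifelines``).  The headline "mean lifespan" is the
arithmetic mean over uncensored death days, matching the convention in
which reported n counts deaths only; the KM restricted mean is available as
a secondary summary.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import AggregationError, EstimationError, ValidationError

CENSOR_REASONS = ("missing", "bagged", "damaged", "none")


@dataclass(frozen=True)
class LifespanRecord:
    worm_id: str
    group: str
    last_day_alive: int  # adult day on which the worm was last scored alive/dead
    status: str  # "died" | "censored"
    censor_reason: str = "none"

    def __post_init__(self):
        if self.last_day_alive < 1:
            raise ValidationError(f"{self.worm_id}: day before adult day 1")
        if self.status not in ("died", "censored"):
            raise ValidationError(f"{self.worm_id}: bad status {self.status!r}")
        if self.censor_reason not in CENSOR_REASONS:
            raise ValidationError(f"{self.worm_id}: bad censor reason {self.censor_reason!r}")
        if (self.status == "died") != (self.censor_reason == "none"):
            raise ValidationError(
                f"{self.worm_id}: censor_reason must be 'none' iff status is 'died'"
            )


@dataclass(frozen=True)
class KMCurve:
    times: np.ndarray  # event days (including 0)
    survival: np.ndarray  # non-increasing, survival[0] = 1
    at_risk: np.ndarray


@dataclass(frozen=True)
class LifespanSummary:
    mean_days: float
    sem: float
    n_deaths: int
    n_censored: int


def apply_censoring(raw: pd.DataFrame) -> list[LifespanRecord]:
    """Convert a raw scoring table into :class:`LifespanRecord` objects.

    ``raw`` columns: ``worm_id, group, last_day_alive`` plus boolean flags
    ``missing, bagged, damaged``.  A worm with any flag set is censored at
    its last observed day (reason = first true flag in that order);
    otherwise it died on ``last_day_alive`` (the scoring day on which it was
    first found dead).
    """
    records = []
    for r in raw.itertuples():
        reason = "none"
        for flag in ("missing", "bagged", "damaged"):
            if bool(getattr(r, flag, False)):
                reason = flag
                break
        records.append(
            LifespanRecord(
                worm_id=str(r.worm_id),
                group=str(r.group),
                last_day_alive=int(r.last_day_alive),
                status="died" if reason == "none" else "censored",
                censor_reason=reason,
            )
        )
    return records


def _times_events(records: list[LifespanRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.last_day_alive for r in records], dtype=float)
    events = np.array([r.status == "died" for r in records], dtype=bool)
    return times, events


def km_estimate(records: list[LifespanRecord]) -> KMCurve:
    """Product-limit survival estimate; censored worms leave the risk set after their last day."""
    if not records:
        raise AggregationError("no lifespan records")
    times, events = _times_events(records)
    if not events.any():
        raise EstimationError("cannot estimate survival with zero deaths")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
    )
    return KMCurve(times=timeline, survival=surv, at_risk=at_risk)


def mean_lifespan(records: list[LifespanRecord]) -> LifespanSummary:
    """Arithmetic mean +- SEM over uncensored death days."""
    deaths = np.array([r.last_day_alive for r in records if r.status == "died"], dtype=float)
    n_cens = sum(1 for r in records if r.status == "censored")
    if len(deaths) < 2:
        raise EstimationError("mean lifespan needs at least two deaths")
    return LifespanSummary(
        mean_days=float(deaths.mean()),
        sem=float(deaths.std(ddof=1) / np.sqrt(len(deaths))),
        n_deaths=len(deaths),
        n_censored=n_cens,
    )


def km_restricted_mean(records: list[LifespanRecord]) -> float:
    """Area under the KM curve (restricted to the last observed event time)."""
    curve = km_estimate(records)
    return float(np.trapezoid(curve.survival, curve.times))


def logrank(group_a: list[LifespanRecord], group_b: list[LifespanRecord]) -> tuple[float, float]:
    """Two-group Mantel-Cox log-rank test; returns (chi2, p) on 1 df."""
    for name, grp in (("a", group_a), ("b", group_b)):
        if not any(r.status == "died" for r in grp):
            raise EstimationError(f"group {name} has no deaths; log-rank undefined")
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def percent_change(mean_ref: float, mean_test: float) -> float:
    """Signed percent change of a test mean relative to a reference mean."""
    if mean_ref <= 0:
        raise ValidationError("reference mean must be positive")
    return 100.0 * (mean_test - mean_ref) / mean_ref
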