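"""Distant-recurrence-free survival (DRFS) analysis.

Kaplan–Meier product-limit curves and the (unweighted) log-rank test,
grouped by systemic-therapy category, for the discordant cases a triage
rule mislabels.  DRFS treats distant metastasis as the event; deaths from
causes other than breast cancer censor the observation at the death time
(a composite-event mode counting any death as an event is available).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .records import CaseRecord, DeathCause, Therapy

__all__ = [
    "SurvivalObservation",
    "SurvivalCurve",
    "LogrankResult",
    "DRFSGroupSummary",
    "DRFSReport",
    "km_estimate",
    "logrank_test",
    "drfs_report",
]


@dataclass(frozen=True)
class SurvivalObservation:
    """One subject: follow-up time in months, event flag, optional group label."""

    time: float
    event: bool
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"time must be finite and > 0, got {self.time}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with at-risk/event bookkeeping.

    ``times`` are the distinct event times in increasing order; at each,
    ``at_risk`` subjects were under observation, ``events`` failed, and
    ``survival`` is the running product-limit estimate just after that
    time.  Ties between events and censorings at the same time are
    resolved events-first (the standard convention).  ``censor_times``
    lists every censored observation time.
    """

    times: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]
    survival: tuple[float, ...]
    censor_times: tuple[float, ...] = ()
    n: int = 0

    def survival_at(self, t: float) -> float:
        """S(t): the estimate at time t (right-continuous step function)."""
        s = 1.0
        for time, est in zip(self.times, self.survival):
            if time <= t:
                s = est
            else:
                break
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )

    def to_dict(self) -> dict:
        return {
            "times": list(self.times),
            "at_risk": list(self.at_risk),
            "events": list(self.events),
            "survival": list(self.survival),
            "censor_times": list(self.censor_times),
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurvivalCurve":
        return cls(
            times=tuple(d["times"]),
            at_risk=tuple(int(v) for v in d["at_risk"]),
            events=tuple(int(v) for v in d["events"]),
            survival=tuple(d["survival"]),
            censor_times=tuple(d["censor_times"]),
            n=int(d["n"]),
        )


def km_estimate(observations: Sequence[SurvivalObservation]) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator.

    Censored times do not drop the curve; at tied times events are
    processed before censorings.  Requires at least one observation.
    """
    if len(observations) == 0:
        raise ValueError("at least one observation is required")
    times = np.array([o.time for o in observations], dtype=float)
    events = np.array([o.event for o in observations], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    event_rows = tbl[tbl["observed"] > 0]
    ts = tuple(float(t) for t in event_rows.index)
    surv = tuple(float(kmf.survival_function_at_times(t).iloc[0]) for t in ts)
    return SurvivalCurve(
        times=ts,
        at_risk=tuple(int(v) for v in event_rows["at_risk"]),
        events=tuple(int(v) for v in event_rows["observed"]),
        survival=surv,
        censor_times=tuple(sorted(float(t) for t, e in zip(times, events) if not e)),
        n=len(observations),
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: Optional[float]
    df: int
    p_value: Optional[float]
    applicable: bool = True
    note: str = ""


def logrank_test(groups: Mapping[str, Sequence[SurvivalObservation]]) -> LogrankResult:
    """Unweighted log-rank test across two or more groups.

    Chi-square reference with ``len(groups) - 1`` degrees of freedom,
    two-sided p.  With zero events overall the statistic is undefined and
    the result is flagged not-applicable.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if any(len(groups[g]) == 0 for g in names):
        raise ValueError("log-rank test needs nonempty groups")
    durations, flags, labels = [], [], []
    for g in names:
        for o in groups[g]:
            durations.append(o.time)
            flags.append(bool(o.event))
            labels.append(g)
    df = len(names) - 1
    if not any(flags):
        return LogrankResult(None, df, None, applicable=False, note="no events observed")
    res = multivariate_logrank_test(
        np.asarray(durations, float), np.asarray(labels), np.asarray(flags, bool)
    )
    return LogrankResult(float(res.test_statistic), df, float(res.p_value))


@dataclass(frozen=True)
class DRFSGroupSummary:
    therapy: str
    n: int
    n_events: int
    followup_mean: float
    followup_iqr: tuple[float, float]
    curve: SurvivalCurve


@dataclass(frozen=True)
class DRFSReport:
    """Per-therapy-group DRFS curves, follow-up summaries and log-rank tests."""

    groups: tuple[DRFSGroupSummary, ...]
    global_test: Optional[LogrankResult]
    pairwise_tests: Mapping[tuple[str, str], LogrankResult]
    excluded_case_ids: tuple[object, ...] = ()

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)


def _drfs_observation(case: CaseRecord, composite_events: bool) -> SurvivalObservation:
    event = bool(case.distant_recurrence)
    if composite_events and case.death not in (None, DeathCause.NONE):
        event = True
    # non-breast-cancer death without recurrence censors at the death time,
    # which is the recorded end of follow-up
    therapy = case.therapy.value if case.therapy is not None else "unknown"
    return SurvivalObservation(time=float(case.followup_months), event=event, group=therapy)


def drfs_report(
    cases: Iterable[CaseRecord],
    composite_events: bool = False,
    min_group_size: int = 1,
) -> DRFSReport:
    """DRFS analysis of a case set (typically the discordant cases).

    Cases lacking follow-up time are excluded (their identifiers are
    reported).  Groups are the therapy categories present; the global
    log-rank covers all groups with at least ``min_group_size`` cases, and
    pairwise tests cover every group pair.
    """
    by_group: dict[str, list[SurvivalObservation]] = {}
    excluded: list[object] = []
    for case in cases:
        if case.followup_months is None or case.followup_months <= 0:
            excluded.append(case.case_id)
            continue
        obs = _drfs_observation(case, composite_events)
        by_group.setdefault(obs.group, []).append(obs)
    summaries = []
    for therapy in sorted(by_group):
        obs = by_group[therapy]
        if len(obs) < min_group_size:
            continue
        t = np.array([o.time for o in obs])
        summaries.append(
            DRFSGroupSummary(
                therapy=therapy,
                n=len(obs),
                n_events=int(sum(o.event for o in obs)),
                followup_mean=float(t.mean()),
                followup_iqr=(float(np.percentile(t, 25)), float(np.percentile(t, 75))),
                curve=km_estimate(obs),
            )
        )
    kept = {s.therapy: by_group[s.therapy] for s in summaries}
    global_test = None
    if len(kept) >= 2:
        if any(o.event for obs in kept.values() for o in obs):
            global_test = logrank_test(kept)
        else:
            global_test = LogrankResult(None, len(kept) - 1, None, applicable=False,
                                        note="no events observed")
    pairwise: dict[tuple[str, str], LogrankResult] = {}
    names = sorted(kept)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if any(o.event for o in kept[a]) or any(o.event for o in kept[b]):
                pairwise[(a, b)] = logrank_test({a: kept[a], b: kept[b]})
            else:
                pairwise[(a, b)] = LogrankResult(None, 1, None, applicable=False,
                                                 note="no events observed")
    return DRFSReport(
        groups=tuple(summaries),
        global_test=global_test,
        pairwise_tests=pairwise,
        excluded_case_ids=tuple(excluded),
    )
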