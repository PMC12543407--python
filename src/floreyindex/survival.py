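"""Onset events on the disease-index scale, Kaplan-Meier estimation and
threshold extraction.

A participant's MCI (or AD) onset event is placed at the index value of the
first visit carrying a qualifying diagnosis; participants who never qualify
are right-censored at their last visit. The onset threshold is the smallest
index at which the event-free survival estimate drops to 0.5 or below.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Cohort, ParticipantSeries, Stage, stage_from_cdrsb
from .trajectory import AlignmentModel

ENDPOINTS = ("MCI", "AD")


class NoEventsError(ValueError):
    """No onset events for the requested endpoint."""


class ThresholdUndefinedError(ValueError):
    """The survival curve never reaches the requested onset probability."""


@dataclass(frozen=True)
class OnsetEvent:
    participant_id: str
    endpoint: str
    fdi_time: float
    observed: bool  # True = event, False = right-censored
    stratum: str | None = None


@dataclass
class ExtractionReport:
    n_events: int
    n_censored: int
    n_prevalent_excluded: int
    n_skipped_no_labels: int


def _visit_stage(visit, use_staging_fallback: bool) -> Stage | None:
    if visit.diagnosis is not None:
        return visit.diagnosis
    if use_staging_fallback:
        return stage_from_cdrsb(visit.cdr_sb)
    return None


def _qualifies(stage: Stage | None, endpoint: str, count_direct_converters: bool) -> bool:
    if stage is None:
        return False
    if endpoint == "AD":
        return stage is Stage.AD
    # MCI endpoint: AD implies MCI onset has already occurred (possibly
    # unobserved between visits) unless direct converters are excluded.
    if count_direct_converters:
        return stage in (Stage.MCI, Stage.AD)
    return stage is Stage.MCI


def extract_onset_events(
    cohort: Cohort,
    alignment: AlignmentModel,
    endpoint: str,
    use_staging_fallback: bool = True,
    count_direct_converters: bool = True,
) -> tuple[list[OnsetEvent], ExtractionReport]:
    """Convert aligned trajectories into onset/censoring times on the index.

    Participants already at or past the endpoint at their first visit
    (prevalent cases) are excluded and counted; participants with no usable
    stage label at any visit are skipped with a warning.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    events: list[OnsetEvent] = []
    n_prev = n_skip = n_ev = n_cen = 0
    for s in cohort:
        shift = alignment.shift_of(s.participant_id).shift
        stages = [_visit_stage(v, use_staging_fallback) for v in s.visits]
        if all(st is None for st in stages):
            n_skip += 1
            continue
        qualifying = [
            i for i, st in enumerate(stages)
            if _qualifies(st, endpoint, count_direct_converters)
        ]
        if qualifying and qualifying[0] == 0:
            n_prev += 1
            continue
        if qualifying:
            v = s.visits[qualifying[0]]
            events.append(OnsetEvent(s.participant_id, endpoint, v.age + shift, True))
            n_ev += 1
        else:
            events.append(
                OnsetEvent(s.participant_id, endpoint, s.visits[-1].age + shift, False)
            )
            n_cen += 1
    if n_skip:
        warnings.warn(
            f"{n_skip} participants had no stage label at any visit and were skipped",
            stacklevel=2,
        )
    return events, ExtractionReport(n_ev, n_cen, n_prev, n_skip)


@dataclass
class SurvivalCurve:
    """Kaplan-Meier event-free survival on the index scale.

    ``grid`` holds the ordered distinct event times; ``survival`` the
    product-limit estimate just after each, with 95% log-log confidence
    limits and the number at risk just before each event time.
    """

    endpoint: str
    grid: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    n_events: int
    n_censored: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fdi": self.grid,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "n_at_risk": self.n_at_risk,
            }
        )


def km_estimate(events: Sequence[OnsetEvent], alpha: float = 0.05) -> SurvivalCurve:
    """Product-limit survival estimate with right censoring.

    Ties follow the standard convention (events precede censorings at equal
    times); confidence limits use the log-log (exponential Greenwood)
    transform, the default in standard survival tooling.
    """
    if not events:
        raise NoEventsError("no observations supplied")
    durations = np.array([e.fdi_time for e in events], dtype=float)
    observed = np.array([e.observed for e in events], dtype=bool)
    if not observed.any():
        raise NoEventsError(f"no events for endpoint {events[0].endpoint}")

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, event_observed=observed)

    grid = np.unique(durations[observed])
    sf = kmf.survival_function_.iloc[:, 0]
    surv = sf.reindex(grid, method="ffill").to_numpy(dtype=float)
    ci = kmf.confidence_interval_survival_function_
    ci_lo = ci.iloc[:, 0].reindex(grid, method="ffill").to_numpy(dtype=float)
    ci_hi = ci.iloc[:, 1].reindex(grid, method="ffill").to_numpy(dtype=float)
    n_at_risk = np.array([(durations >= t).sum() for t in grid])
    return SurvivalCurve(
        endpoint=events[0].endpoint,
        grid=grid,
        survival=surv,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        n_at_risk=n_at_risk,
        n_events=int(observed.sum()),
        n_censored=int((~observed).sum()),
    )


def threshold_from_curve(curve: SurvivalCurve, p: float = 0.5) -> float:
    """Smallest index at which onset probability reaches ``p``.

    The KM estimate is a step function, so the threshold is the first grid
    time with S <= 1 - p; no interpolation or extrapolation is performed.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    target = 1.0 - p
    hit = np.nonzero(curve.survival <= target + 1e-12)[0]
    if len(hit) == 0:
        raise ThresholdUndefinedError(
            f"survival never reaches {target:g} (min S = {curve.survival.min():.3f})"
        )
    return float(curve.grid[hit[0]])


@dataclass
class ThresholdEntry:
    theta: float | None
    n_events: int | None = None
    n_censored: int | None = None
    note: str | None = None


@dataclass
class ThresholdTable:
    """Onset thresholds keyed by (endpoint, covariate, level).

    The overall (unstratified) entry for an endpoint uses covariate=None,
    level=None. Boolean comorbidity strata use levels "disease" and
    "disease-free"; sex uses "F"/"M".
    """

    entries: dict[tuple[str, str | None, str | None], ThresholdEntry] = field(
        default_factory=dict
    )

    def set(self, endpoint: str, covariate: str | None, level: str | None,
            entry: ThresholdEntry) -> None:
        self.entries[(endpoint, covariate, level)] = entry

    def get(self, endpoint: str, covariate: str | None = None,
            level: str | None = None) -> ThresholdEntry | None:
        return self.entries.get((endpoint, covariate, level))

    def theta(self, endpoint: str, covariate: str | None = None,
              level: str | None = None) -> float | None:
        e = self.get(endpoint, covariate, level)
        return None if e is None else e.theta

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "endpoint": ep,
                "covariate": cov,
                "level": lev,
                "theta": e.theta,
                "n_events": e.n_events,
                "n_censored": e.n_censored,
                "note": e.note,
            }
            for (ep, cov, lev), e in sorted(
                self.entries.items(), key=lambda kv: tuple(str(x) for x in kv[0])
            )
        ]
        return pd.DataFrame(rows)


def _stratum_level(value) -> str:
    if isinstance(value, bool):
        return "disease" if value else "disease-free"
    return str(value)


def stratified_thresholds(
    cohort: Cohort,
    alignment: AlignmentModel,
    endpoint: str,
    stratify_by: str,
    min_per_stratum: int = 20,
    p: float = 0.5,
    use_staging_fallback: bool = True,
    count_direct_converters: bool = True,
) -> ThresholdTable:
    """One threshold per level of a covariate (disease vs disease-free, F vs M).

    Strata with fewer participants than ``min_per_stratum``, or whose survival
    curve never reaches the onset probability, get an undefined entry with a
    note instead of an extrapolated number.
    """
    strata: dict[str, list[ParticipantSeries]] = {}
    known = False
    for s in cohort:
        if stratify_by in s.covariates:
            known = True
            strata.setdefault(_stratum_level(s.covariates[stratify_by]), []).append(s)
    if not known:
        raise ValueError(f"covariate {stratify_by!r} not present in cohort")

    table = ThresholdTable()
    for level, members in sorted(strata.items()):
        if len(members) < min_per_stratum:
            warnings.warn(
                f"stratum {stratify_by}={level} has only {len(members)} "
                f"participants (< {min_per_stratum}); threshold undefined",
                stacklevel=2,
            )
            table.set(endpoint, stratify_by, level,
                      ThresholdEntry(None, note="small sample"))
            continue
        sub = Cohort(members, provenance=f"{stratify_by}={level}")
        events, _ = extract_onset_events(
            sub, alignment, endpoint,
            use_staging_fallback=use_staging_fallback,
            count_direct_converters=count_direct_converters,
        )
        try:
            curve = km_estimate(events)
            theta = threshold_from_curve(curve, p)
        except (NoEventsError, ThresholdUndefinedError) as exc:
            table.set(endpoint, stratify_by, level,
                      ThresholdEntry(None, note=str(exc)))
            continue
        table.set(
            endpoint, stratify_by, level,
            ThresholdEntry(theta, curve.n_events, curve.n_censored),
        )
    return table
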