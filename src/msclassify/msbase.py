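"""Longitudinal detection of conversion to secondary progressive MS.

Implements a confirmed-EDSS-progression rule adapted from the MSBase
registry definition. A patient converts at the first relapse-free visit
where, relative to a roving baseline (the lowest EDSS seen so far at a
relapse-free visit):

* the EDSS has increased by at least 1.0 point from a baseline below 6, or
  by at least 0.5 point from a baseline of 6 or more;
* the EDSS has reached at least 4.0;
* the increase is confirmed at a later relapse-free visit at least three
  months (91 days) afterwards, with every intervening relapse-free visit
  remaining at or above the progressed level.

A visit is "relapse-free" when no recorded relapse falls within
``relapse_window_days`` of it on either side. The pyramidal functional
system criterion (FS score >= 2 at event and confirmation) is off by
default, for registries that do not record FS sub-scores; enabling it
against a cohort without FS data makes every patient unconvertible and
emits a loud warning.

The conversion date is the event date, not the confirmation date, so the
detector can date SP onset earlier than a retrospective clinical call.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

from .data_model import Cohort, Relapse, Visit


@dataclass(frozen=True)
class MSBaseConfig:
    min_increase_below6: float = 1.0
    min_increase_at6plus: float = 0.5
    edss_floor: float = 4.0
    confirmation_days: int = 91
    relapse_window_days: int = 30
    require_pyramidal_fs: bool = False
    fs_threshold: int = 2
    #: "roving" (reset to any lower relapse-free EDSS) or "first" (fixed
    #: first relapse-free visit)
    baseline_mode: str = "roving"

    def __post_init__(self):
        if min(self.min_increase_below6, self.min_increase_at6plus, self.edss_floor) <= 0:
            raise ValueError("EDSS thresholds must be positive")
        if self.confirmation_days < 1:
            raise ValueError("confirmation_days must be >= 1")
        if self.baseline_mode not in ("roving", "first"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")


@dataclass(frozen=True)
class ProgressionCall:
    converted: bool
    conversion_date: dt.date | None = None
    baseline_visit: Visit | None = None
    event_visit: Visit | None = None
    confirming_visit: Visit | None = None
    flag: str | None = None


def _relapse_free(visit: Visit, relapse_dates: list[dt.date], window: int) -> bool:
    return all(abs((visit.visit_date - d).days) > window for d in relapse_dates)


def _fs_ok(visit: Visit, config: MSBaseConfig) -> bool:
    if not config.require_pyramidal_fs:
        return True
    return visit.pyramidal_fs is not None and visit.pyramidal_fs >= config.fs_threshold


def detect_conversion(
    visits: list[Visit],
    relapses: list[Relapse] | None = None,
    config: MSBaseConfig | None = None,
) -> ProgressionCall:
    """Scan a patient's visit history for confirmed SP conversion.

    *visits* must be chronologically sorted; the earliest qualifying and
    confirmed event wins. Returns a non-conversion call for an empty
    history.
    """
    config = config or MSBaseConfig()
    if any(b.visit_date < a.visit_date for a, b in zip(visits, visits[1:])):
        raise ValueError("visits must be sorted by date")
    if not visits:
        return ProgressionCall(converted=False, flag="no visits")

    relapse_dates = sorted(r.relapse_date for r in (relapses or []))
    free = [
        v
        for v in visits
        if _relapse_free(v, relapse_dates, config.relapse_window_days)
    ]
    if config.require_pyramidal_fs and all(v.pyramidal_fs is None for v in visits):
        warnings.warn(
            "pyramidal FS criterion is enabled but no visit carries an FS "
            "score: no patient can convert",
            stacklevel=2,
        )

    baseline: Visit | None = None
    for i, v in enumerate(free):
        if baseline is None:
            baseline = v
            continue
        required = (
            config.min_increase_below6
            if baseline.edss < 6.0
            else config.min_increase_at6plus
        )
        progressed_level = baseline.edss + required
        if v.edss >= progressed_level and v.edss >= config.edss_floor and _fs_ok(v, config):
            confirmed = _confirm(free[i + 1 :], v, progressed_level, config)
            if confirmed is not None:
                return ProgressionCall(
                    converted=True,
                    conversion_date=v.visit_date,
                    baseline_visit=baseline,
                    event_visit=v,
                    confirming_visit=confirmed,
                )
        if config.baseline_mode == "roving" and v.edss < baseline.edss:
            baseline = v
    return ProgressionCall(converted=False)


def _confirm(
    later: list[Visit], event: Visit, progressed_level: float, config: MSBaseConfig
) -> Visit | None:
    """First later relapse-free visit >= confirmation_days after the event
    with EDSS sustained at the progressed level throughout."""
    for v in later:
        if v.edss < progressed_level:
            return None  # progression not sustained
        if (v.visit_date - event.visit_date).days >= config.confirmation_days and _fs_ok(
            v, config
        ):
            return v
    return None


def classify_cohort_msbase(
    cohort: Cohort, config: MSBaseConfig | None = None
) -> dict[str, ProgressionCall]:
    """Per-patient SP/RR call from longitudinal history.

    Patients with fewer than two visits cannot show confirmed progression
    and are called non-converted with a ``"no longitudinal data"`` flag.
    """
    config = config or MSBaseConfig()
    calls: dict[str, ProgressionCall] = {}
    for p in cohort.patients:
        visits = cohort.visits_of(p.patient_id)
        if len(visits) < 2:
            calls[p.patient_id] = ProgressionCall(converted=False, flag="no longitudinal data")
            continue
        calls[p.patient_id] = detect_conversion(
            visits, cohort.relapses_of(p.patient_id), config
        )
    return calls


def labels_from_calls(calls: dict[str, ProgressionCall]) -> dict[str, str]:
    return {pid: ("SP" if c.converted else "RR") for pid, c in calls.items()}
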