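"""Diagnostic-accuracy metrics, misclassification profiling and
Kaplan-Meier time-to-SP comparison.

Conventions follow the classification study this package reproduces: the
relapsing-remitting (RR) class is the positive class by default, so
sensitivity is the probability of calling an RR patient RR. Binomial 95%
confidence intervals use the Wilson score method by default (Wald
available for comparison). Survival estimation is the product-limit
estimator with Greenwood-based confidence bands; RR-labelled patients are
right-censored at their last visit.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from statsmodels.stats.proportion import proportion_confint

from .data_model import Cohort, CohortError, age_at, latest_assessment, years_between
from . import published_tree
from .msbase import MSBaseConfig, classify_cohort_msbase


@dataclass(frozen=True)
class MetricValue:
    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    reason: str | None = None  # set when undefined (zero denominator)


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str
    accuracy: MetricValue = field(init=False)
    sensitivity: MetricValue = field(init=False)
    specificity: MetricValue = field(init=False)
    ppv: MetricValue = field(init=False)
    npv: MetricValue = field(init=False)

    ci_method: str = "wilson"

    def __post_init__(self):
        self.accuracy = _proportion(self.tp + self.tn, self.tp + self.fp + self.fn + self.tn, self.ci_method)
        self.sensitivity = _proportion(self.tp, self.tp + self.fn, self.ci_method)
        self.specificity = _proportion(self.tn, self.tn + self.fp, self.ci_method)
        self.ppv = _proportion(self.tp, self.tp + self.fp, self.ci_method)
        self.npv = _proportion(self.tn, self.tn + self.fn, self.ci_method)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            m: MetricValue = getattr(self, name)
            rows.append({"metric": name, "value": m.value, "ci_low": m.ci_low,
                         "ci_high": m.ci_high, "note": m.reason})
        return pd.DataFrame(rows)


def _proportion(k: int, n: int, ci_method: str) -> MetricValue:
    if n == 0:
        return MetricValue(value=None, reason="undefined: zero denominator")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson" if ci_method == "wilson" else "normal")
    return MetricValue(value=k / n, ci_low=float(lo), ci_high=float(hi))


def confusion_metrics(
    predicted,
    reference,
    positive_class: str = "RR",
    ci_method: str = "wilson",
) -> ConfusionMetrics:
    """Accuracy, sensitivity, specificity, PPV and NPV with 95% CIs.

    *predicted* and *reference* are aligned label sequences. The positive
    class defaults to RR, matching the reporting convention of the
    registry study.
    """
    pred = list(predicted)
    ref = list(reference)
    if len(pred) != len(ref):
        raise CohortError("predicted and reference labels must be aligned")
    if not pred:
        raise CohortError("empty label vectors")
    if ci_method not in ("wilson", "wald"):
        raise CohortError(f"unknown ci_method {ci_method!r}")
    tp = sum(p == positive_class and r == positive_class for p, r in zip(pred, ref))
    fp = sum(p == positive_class and r != positive_class for p, r in zip(pred, ref))
    fn = sum(p != positive_class and r == positive_class for p, r in zip(pred, ref))
    tn = sum(p != positive_class and r != positive_class for p, r in zip(pred, ref))
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn, positive_class=positive_class, ci_method=ci_method)


# ---------------------------------------------------------------------------
# Misclassification profiling


def misclassification_profile(cohort: Cohort, predicted: dict[str, str]) -> pd.DataFrame:
    """Characteristics of concordant and discordant patients, one row per
    (reference, predicted) cell.

    Columns mirror the registry-style cohort tables: age at the most
    recent visit (mean, SD), % female, onset age (mean, SD), disease
    duration (median [IQR]) and last EDSS (median [IQR]). Empty cells are
    omitted.
    """
    records = []
    for p in cohort.patients:
        if p.patient_id not in predicted:
            continue
        visits = cohort.visits_of(p.patient_id)
        if not visits:
            continue
        last = latest_assessment(visits)
        records.append(
            {
                "reference": p.assigned_phenotype,
                "predicted": predicted[p.patient_id],
                "age_last_visit": age_at(p, last.visit_date),
                "female": p.sex == "female",
                "onset_age": age_at(p, p.onset_date),
                "disease_duration": years_between(p.onset_date, last.visit_date),
                "last_edss": last.edss,
            }
        )
    df = pd.DataFrame(records)
    rows = []
    for (ref, pred), grp in df.groupby(["reference", "predicted"], sort=True):
        rows.append(
            {
                "reference": ref,
                "predicted": pred,
                "concordant": ref == pred,
                "n": len(grp),
                "age_last_visit_mean": grp.age_last_visit.mean(),
                "age_last_visit_sd": grp.age_last_visit.std(),
                "female_pct": 100 * grp.female.mean(),
                "onset_age_mean": grp.onset_age.mean(),
                "onset_age_sd": grp.onset_age.std(),
                "duration_median": grp.disease_duration.median(),
                "duration_iqr_low": grp.disease_duration.quantile(0.25),
                "duration_iqr_high": grp.disease_duration.quantile(0.75),
                "edss_median": grp.last_edss.median(),
                "edss_iqr_low": grp.last_edss.quantile(0.25),
                "edss_iqr_high": grp.last_edss.quantile(0.75),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    median: float  # inf when not reached
    median_ci: tuple[float, float]
    n_events: int
    n_censored: int

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "ci_low": self.ci_low, "ci_high": self.ci_high}
        )


def km_curve(times, events) -> KMCurve:
    """Product-limit survival estimate with 95% confidence band.

    *times* are event/censoring times in years; *events* is True where the
    endpoint (SP conversion) was observed. The median is the smallest time
    with survival <= 0.5, infinite when never reached.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise CohortError("no observations")
    if (times < 0).any():
        raise CohortError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(kmf.confidence_interval_)
    lo = float(med_ci.iloc[0, 0])
    hi = float(med_ci.iloc[0, 1])
    return KMCurve(
        times=surv.index.to_numpy(),
        survival=surv.to_numpy(),
        ci_low=ci.iloc[:, 0].to_numpy(),
        ci_high=ci.iloc[:, 1].to_numpy(),
        median=median,
        median_ci=(lo, hi),
        n_events=int(events.sum()),
        n_censored=int((~events).sum()),
    )


# ---------------------------------------------------------------------------
# Time-to-SP comparison across labelling methods


def _clinical_event(cohort: Cohort, pid: str) -> tuple[dt.date | None, dt.date]:
    p = cohort.patient(pid)
    last = latest_assessment(cohort.visits_of(pid)).visit_date
    return (p.sp_date if p.assigned_phenotype == "SP" else None), last


def _tree_event(cohort: Cohort, pid: str) -> tuple[dt.date | None, dt.date]:
    """Earliest visit at which the published tree classifies the patient SP.

    The tree gives a cross-sectional status, not a transition date; the
    first SP-classified assessment is used as its event date.
    """
    p = cohort.patient(pid)
    visits = cohort.visits_of(pid)
    for v in visits:
        if published_tree.classify(v.edss, age_at(p, v.visit_date)).label == "SP":
            return v.visit_date, visits[-1].visit_date
    return None, visits[-1].visit_date


def compare_time_to_sp(
    cohort: Cohort,
    msbase_config: MSBaseConfig | None = None,
    labellers: tuple[str, ...] = ("clinical", "published_tree", "msbase"),
) -> tuple[dict[tuple[str, str], KMCurve], pd.DataFrame]:
    """Kaplan-Meier time to SP per labelling method, from birth and from
    symptom onset.

    Returns the curves keyed by (labeller, origin) and a summary table of
    medians with 95% CIs. Patients without an event under a labeller are
    censored at their last visit.
    """
    eligible = [p.patient_id for p in cohort.patients if cohort.visits_of(p.patient_id)]
    events_by_labeller: dict[str, dict[str, tuple[dt.date | None, dt.date]]] = {}
    for name in labellers:
        if name == "clinical":
            events_by_labeller[name] = {pid: _clinical_event(cohort, pid) for pid in eligible}
        elif name == "published_tree":
            events_by_labeller[name] = {pid: _tree_event(cohort, pid) for pid in eligible}
        elif name == "msbase":
            calls = classify_cohort_msbase(cohort, msbase_config)
            events_by_labeller[name] = {
                pid: (
                    calls[pid].conversion_date if calls[pid].converted else None,
                    cohort.visits_of(pid)[-1].visit_date,
                )
                for pid in eligible
            }
        else:
            raise CohortError(f"unknown labeller {name!r}")

    curves: dict[tuple[str, str], KMCurve] = {}
    rows = []
    for name, ev in events_by_labeller.items():
        for origin in ("birth", "onset"):
            times, flags = [], []
            for pid, (event_date, censor_date) in ev.items():
                p = cohort.patient(pid)
                start = p.birth_date if origin == "birth" else p.onset_date
                end = event_date if event_date is not None else censor_date
                times.append(max(years_between(start, end), 0.0))
                flags.append(event_date is not None)
            curve = km_curve(times, flags)
            curves[(name, origin)] = curve
            rows.append(
                {
                    "labeller": name,
                    "origin": origin,
                    "n": len(times),
                    "n_events": curve.n_events,
                    "median_years": curve.median,
                    "median_ci_low": curve.median_ci[0],
                    "median_ci_high": curve.median_ci[1],
                }
            )
    return curves, pd.DataFrame(rows)
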