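"""Synthetic longitudinal MS cohort generator.

No individual-level registry data can be redistributed, so every other
module is exercised against cohorts drawn from a simple generative model
calibrated to published Swedish-registry marginals:

* onset age ~ Normal(32.4, 10.2) truncated to [5, 70] years;
* 71.4% female;
* disease duration at the last visit ~ log-normal with median 14 years
  (IQR roughly 7-23);
* latent time from onset to SP transition ~ log-normal with median 25
  years; a patient is SP when that time falls within follow-up, and the
  neurologist-style label and transition date are taken from it;
* visits roughly annually from onset to the last visit;
* relapses in the RR phase as a Poisson process whose rate (0.35/year at
  onset) decays with disease duration;
* EDSS as a mean-reverting random walk in the RR phase and a ratcheted
  upward drift (0.35 points/year) after SP transition, snapped to the
  valid 0.5 grid; a recent relapse transiently inflates the observed
  score by one point.

The model matches the configured marginals, not any joint structure of
real registries; see the methods note for what that does and does not
validate.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    DAYS_PER_YEAR,
    Cohort,
    CohortError,
    Patient,
    Relapse,
    Visit,
    _shift_years,
    age_at,
    latest_assessment,
    years_between,
)


class ConfigError(CohortError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 1000
    female_fraction: float = 0.714
    onset_age_mean: float = 32.4
    onset_age_sd: float = 10.2
    onset_age_bounds: tuple[float, float] = (5.0, 70.0)
    duration_median: float = 14.0
    duration_log_sd: float = 0.88
    visit_interval_mean: float = 1.0
    relapse_rate_rr: float = 0.35
    relapse_rate_halflife: float = 15.0  # years of disease duration
    sp_median_years: float = 25.0
    sp_log_sd: float = 0.5
    #: RR-phase disability is modelled as fluctuation around a stable
    #: per-patient set point established early in the disease: a mild
    #: majority (set point ~N(1.5, 0.8) truncated to [0, 3.5]) and a
    #: severe tail (uniform on [3.5, 6.5]) of patients with substantial
    #: but non-progressive disability.
    severe_rr_fraction: float = 0.12
    rr_setpoint_mild: tuple[float, float] = (1.5, 0.8)
    rr_setpoint_mild_bounds: tuple[float, float] = (0.0, 3.5)
    rr_setpoint_severe_bounds: tuple[float, float] = (3.5, 6.5)
    #: RR fluctuation: stationary SD around the set point and the
    #: mean-reversion rate (1/years); excursions decorrelate within about
    #: a year so stable RR disability rarely mimics confirmed progression
    edss_rr_reversion: float = 1.0
    edss_rr_sd: float = 0.3
    edss_sp_drift: float = 0.35  # points/year
    edss_sp_sd: float = 0.3
    relapse_bump_days: int = 60
    label_noise: float = 0.0
    reference_date: dt.date = dt.date(2019, 2, 1)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ("female_fraction", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {v}")
        for name in (
            "onset_age_sd", "duration_log_sd", "visit_interval_mean",
            "relapse_rate_rr", "sp_log_sd", "edss_rr_sd", "edss_sp_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.sp_median_years <= 0:
            raise ConfigError("sp_median_years must be positive (may be inf)")


def _truncated_normal(rng, mean, sd, low, high) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return x
    raise ConfigError("truncated normal bounds too tight for the given mean/sd")


def _snap_edss(x: float) -> float:
    v = min(max(round(x * 2) / 2, 0.0), 10.0)
    if v == 0.5:  # no 0.5 step on the scale
        v = 1.0 if x >= 0.5 else 0.0
    return v


def generate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Draw a full synthetic cohort; deterministic for a fixed seed."""
    cohort, _ = generate_cohort_with_truth(config)
    return cohort


def generate_cohort_with_truth(
    config: SimulationConfig | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """As :func:`generate_cohort`, also returning the latent ground truth
    (unperturbed phenotype, transition time) per patient."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    width = max(6, len(str(cfg.n_patients)))

    patients: list[Patient] = []
    visits: list[Visit] = []
    relapses: list[Relapse] = []
    truth_rows = []

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:0{width}d}"
        sex = "female" if rng.random() < cfg.female_fraction else "male"
        onset_age = _truncated_normal(
            rng, cfg.onset_age_mean, cfg.onset_age_sd, *cfg.onset_age_bounds
        )
        duration = float(
            np.clip(
                rng.lognormal(math.log(cfg.duration_median), cfg.duration_log_sd),
                0.5,
                60.0,
            )
        )
        onset_date = _shift_years(cfg.reference_date, -duration)
        birth_date = _shift_years(onset_date, -onset_age)

        if math.isinf(cfg.sp_median_years):
            t_sp = math.inf
        else:
            t_sp = float(rng.lognormal(math.log(cfg.sp_median_years), cfg.sp_log_sd))
        is_sp = t_sp <= duration

        # visit schedule: roughly annual, always ending at the last visit
        times = []
        t = float(rng.uniform(0.05, cfg.visit_interval_mean))
        while t < duration - 0.02:
            times.append(t)
            t += float(np.clip(rng.exponential(cfg.visit_interval_mean), 0.25, 2.5))
        times.append(duration)

        # relapses: thinned Poisson in the RR phase only
        rr_end = min(t_sp, duration)
        relapse_times = []
        t = 0.0
        while cfg.relapse_rate_rr > 0:
            t += float(rng.exponential(1.0 / cfg.relapse_rate_rr))
            if t >= rr_end:
                break
            if rng.random() < math.exp(-t / cfg.relapse_rate_halflife):
                relapse_times.append(t)

        # latent EDSS: fluctuation around a per-patient RR set point,
        # then a ratcheted upward drift after SP transition
        if rng.random() < cfg.severe_rr_fraction:
            setpoint = float(rng.uniform(*cfg.rr_setpoint_severe_bounds))
        else:
            setpoint = _truncated_normal(
                rng, *cfg.rr_setpoint_mild, *cfg.rr_setpoint_mild_bounds
            )
        x = setpoint + float(rng.normal(0, cfg.edss_rr_sd))
        prev_t = 0.0
        edss_obs = []
        for vt in times:
            step = vt - prev_t
            while step > 1e-9:
                dt_phase = step
                if prev_t < t_sp <= prev_t + step:
                    dt_phase = t_sp - prev_t  # finish the RR part first
                if prev_t < t_sp:
                    # exact Ornstein-Uhlenbeck transition (stable for any step)
                    decay = math.exp(-cfg.edss_rr_reversion * dt_phase)
                    x = (
                        setpoint
                        + (x - setpoint) * decay
                        + cfg.edss_rr_sd * math.sqrt(1 - decay * decay) * rng.normal()
                    )
                else:
                    inc = (
                        cfg.edss_sp_drift * dt_phase
                        + cfg.edss_sp_sd * math.sqrt(dt_phase) * rng.normal()
                    )
                    x = max(x, x + inc)  # progressive phase ratchets upward
                x = min(max(x, 0.0), 10.0)
                prev_t += dt_phase
                step -= dt_phase
            bump = any(
                0 <= (vt - rt) * DAYS_PER_YEAR <= cfg.relapse_bump_days
                for rt in relapse_times
            )
            edss_obs.append(_snap_edss(x + (1.0 if bump else 0.0)))

        # neurologist-style label, optionally perturbed
        label, sp_date = ("SP", _shift_years(onset_date, t_sp)) if is_sp else ("RR", None)
        if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
            if label == "SP":
                label, sp_date = "RR", None
            else:
                label = "SP"
                sp_date = _shift_years(onset_date, duration * float(rng.uniform(0.3, 0.9)))

        patients.append(
            Patient(
                patient_id=pid,
                sex=sex,
                birth_date=birth_date,
                onset_date=onset_date,
                assigned_phenotype=label,
                sp_date=sp_date,
            )
        )
        seen_days = set()
        for vt, e in zip(times, edss_obs):
            date = _shift_years(onset_date, vt)
            if date in seen_days:
                continue
            seen_days.add(date)
            visits.append(Visit(pid, date, e))
        for rt in relapse_times:
            relapses.append(Relapse(pid, _shift_years(onset_date, rt)))
        truth_rows.append(
            {
                "patient_id": pid,
                "true_phenotype": "SP" if is_sp else "RR",
                "latent_onset_to_sp_years": t_sp,
                "onset_age": onset_age,
                "disease_duration": duration,
            }
        )

    cohort = Cohort(patients=patients, visits=visits, relapses=relapses)
    return cohort, pd.DataFrame(truth_rows)


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Registry-table style summary, one row per phenotype stratum plus
    one for the whole cohort.

    Strata without patients appear with n = 0 and missing statistics.
    """
    if not cohort.patients:
        raise CohortError("empty cohort")
    per_patient = []
    for p in cohort.patients:
        vs = cohort.visits_of(p.patient_id)
        last = latest_assessment(vs) if vs else None
        per_patient.append(
            {
                "stratum": p.assigned_phenotype,
                "age_last_visit": age_at(p, last.visit_date) if last else np.nan,
                "female": p.sex == "female",
                "onset_age": age_at(p, p.onset_date),
                "duration": years_between(p.onset_date, last.visit_date) if last else np.nan,
                "last_edss": last.edss if last else np.nan,
            }
        )
    df = pd.DataFrame(per_patient)
    rows = []
    for name in ("RR", "SP", "All"):
        grp = df if name == "All" else df[df.stratum == name]
        if grp.empty:
            rows.append({"stratum": name, "n": 0})
            continue
        rows.append(
            {
                "stratum": name,
                "n": len(grp),
                "age_last_visit_mean": grp.age_last_visit.mean(),
                "age_last_visit_sd": grp.age_last_visit.std(),
                "female_pct": 100 * grp.female.mean(),
                "onset_age_mean": grp.onset_age.mean(),
                "onset_age_sd": grp.onset_age.std(),
                "duration_median": grp.duration.median(),
                "duration_iqr_low": grp.duration.quantile(0.25),
                "duration_iqr_high": grp.duration.quantile(0.75),
                "edss_median": grp.last_edss.median(),
                "edss_iqr_low": grp.last_edss.quantile(0.25),
                "edss_iqr_high": grp.last_edss.quantile(0.75),
            }
        )
    return pd.DataFrame(rows)
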