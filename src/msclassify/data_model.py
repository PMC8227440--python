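"""Domain types, validation and CSV I/O for registry-style MS cohorts.

The package works from three long-format tables:

``patients.csv``
    ``patient_id,sex,birth_date,onset_date,assigned_phenotype,sp_date``
``visits.csv``
    ``patient_id,visit_date,edss`` (one EDSS assessment per row)
``relapses.csv``
    ``patient_id,relapse_date``

Dates are ISO-8601. The neurologist-assigned phenotype (``RR`` or ``SP``)
and, for SP patients, the transition date are the reference labels against
which algorithmic classifiers are evaluated. Registries often record only
the *year* of SP transition; a bare year is accepted and canonicalised to
July 1 of that year (mid-year convention) and flagged as imputed.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: The EDSS is an ordinal scale in 0.5 steps from 0 to 10, except that the
#: step between 0 and 1 does not exist (there is no 0.5 score).
VALID_EDSS: tuple[float, ...] = (0.0,) + tuple(x / 2 for x in range(2, 21))

PHENOTYPES = ("RR", "SP")
SEXES = ("female", "male")


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """A required column is missing from an input table."""


class RowError(CohortError):
    """A row holds an unparseable or invalid value; carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(f"row {row}: {message}" if row is not None else message)
        self.row = row


class ReferentialError(CohortError):
    """A visit or relapse references an unknown patient."""


class MissingDataError(CohortError):
    """An operation needs data (e.g. visits) that the patient lacks."""


@dataclass(frozen=True)
class ValidationConfig:
    """Knobs for input validation.

    allow_half_point_edss
        Accept any multiple of 0.5 in [0, 10], including the nonexistent
        0.5 step, for registries that record interpolated scores.
    duplicate_visit_policy
        How to collapse several EDSS rows for one patient on one day:
        ``"max"`` (default, conservative toward progression) or ``"min"``.
    """

    allow_half_point_edss: bool = False
    duplicate_visit_policy: str = "max"

    def __post_init__(self):
        if self.duplicate_visit_policy not in ("max", "min"):
            raise ValueError(f"unknown duplicate_visit_policy {self.duplicate_visit_policy!r}")


def validate_edss(value: float, config: ValidationConfig | None = None) -> float:
    """Check *value* against the EDSS grid; return it as a float.

    Raises :class:`RowError` for off-grid values and, unless
    ``allow_half_point_edss`` is set, for the nonexistent 0.5 score.
    """
    config = config or ValidationConfig()
    v = float(value)
    if not (0.0 <= v <= 10.0) or round(v * 2) != v * 2:
        raise RowError(f"EDSS {value!r} is not a 0.5-step value in [0, 10]")
    if v == 0.5 and not config.allow_half_point_edss:
        raise RowError("EDSS 0.5 does not exist on the scale (no step between 0 and 1)")
    return v


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str
    birth_date: dt.date
    onset_date: dt.date
    assigned_phenotype: str
    sp_date: dt.date | None = None
    sp_date_imputed: bool = False

    def __post_init__(self):
        if self.sex not in SEXES:
            raise RowError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.assigned_phenotype not in PHENOTYPES:
            raise RowError(f"phenotype must be one of {PHENOTYPES}, got {self.assigned_phenotype!r}")
        if self.onset_date < self.birth_date:
            raise RowError(f"patient {self.patient_id}: onset before birth")
        if (self.assigned_phenotype == "SP") != (self.sp_date is not None):
            raise RowError(
                f"patient {self.patient_id}: sp_date must be present iff phenotype is SP"
            )
        if self.sp_date is not None and self.sp_date < self.onset_date:
            raise RowError(f"patient {self.patient_id}: sp_date before onset")


@dataclass(frozen=True)
class Visit:
    patient_id: str
    visit_date: dt.date
    edss: float
    pyramidal_fs: int | None = None


@dataclass(frozen=True)
class Relapse:
    patient_id: str
    relapse_date: dt.date


@dataclass
class Cohort:
    """Validated container: patients plus per-patient sorted visit history."""

    patients: list[Patient]
    visits: list[Visit]
    relapses: list[Relapse] = field(default_factory=list)

    _by_id: dict[str, Patient] = field(init=False, repr=False)
    _visits_by_id: dict[str, list[Visit]] = field(init=False, repr=False)
    _relapses_by_id: dict[str, list[Relapse]] = field(init=False, repr=False)

    def __post_init__(self):
        self._by_id = {p.patient_id: p for p in self.patients}
        if len(self._by_id) != len(self.patients):
            raise RowError("duplicate patient_id in patient table")
        self._visits_by_id = {pid: [] for pid in self._by_id}
        self._relapses_by_id = {pid: [] for pid in self._by_id}
        for v in self.visits:
            if v.patient_id not in self._by_id:
                raise ReferentialError(f"visit references unknown patient {v.patient_id!r}")
            if v.visit_date < self._by_id[v.patient_id].birth_date:
                raise RowError(f"patient {v.patient_id}: visit before birth")
            self._visits_by_id[v.patient_id].append(v)
        for r in self.relapses:
            if r.patient_id not in self._by_id:
                raise ReferentialError(f"relapse references unknown patient {r.patient_id!r}")
            if r.relapse_date < self._by_id[r.patient_id].onset_date:
                raise RowError(f"patient {r.patient_id}: relapse before symptom onset")
            self._relapses_by_id[r.patient_id].append(r)
        for pid, vs in self._visits_by_id.items():
            vs.sort(key=lambda v: v.visit_date)
            for a, b in zip(vs, vs[1:]):
                if a.visit_date == b.visit_date:
                    raise RowError(f"patient {pid}: duplicate visit date {a.visit_date}")
        for rs in self._relapses_by_id.values():
            rs.sort(key=lambda r: r.relapse_date)
        self.visits = [v for pid in self._by_id for v in self._visits_by_id[pid]]
        self.relapses = [r for pid in self._by_id for r in self._relapses_by_id[pid]]

    def __len__(self) -> int:
        return len(self.patients)

    def patient(self, patient_id: str) -> Patient:
        return self._by_id[patient_id]

    def visits_of(self, patient_id: str) -> list[Visit]:
        return self._visits_by_id[patient_id]

    def relapses_of(self, patient_id: str) -> list[Relapse]:
        return self._relapses_by_id[patient_id]


def age_at(patient: Patient, date: dt.date) -> float:
    """Age of *patient* on *date* in years, using a 365.25-day year."""
    if date < patient.birth_date:
        raise RowError(f"date {date} precedes birth date {patient.birth_date}")
    return (date - patient.birth_date).days / DAYS_PER_YEAR


def years_between(start: dt.date, end: dt.date) -> float:
    return (end - start).days / DAYS_PER_YEAR


def latest_assessment(visits: list[Visit]) -> Visit:
    """The visit with the maximal date (the 'most recent EDSS')."""
    if not visits:
        raise MissingDataError("patient has no visits")
    return max(visits, key=lambda v: v.visit_date)


# ---------------------------------------------------------------------------
# CSV I/O

_PATIENT_COLS = ["patient_id", "sex", "birth_date", "onset_date", "assigned_phenotype", "sp_date"]
_VISIT_COLS = ["patient_id", "visit_date", "edss"]
_RELAPSE_COLS = ["patient_id", "relapse_date"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _parse_date(raw, row: int, what: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(raw).strip())
    except ValueError:
        raise RowError(f"unparseable {what} {raw!r}", row=row) from None


def _parse_sp_date(raw, row: int) -> tuple[dt.date | None, bool]:
    """ISO date, bare year (mid-year imputed), or blank."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return None, False
    s = str(raw).strip()
    if s.isdigit() and len(s) == 4:
        return dt.date(int(s), 7, 1), True
    return _parse_date(s, row, "sp_date"), False


def read_cohort(
    patients_path,
    visits_path,
    relapses_path=None,
    config: ValidationConfig | None = None,
) -> Cohort:
    """Read and validate the three CSV tables into a :class:`Cohort`.

    Per-patient visits are sorted by date; several rows for one patient on
    one day are collapsed to a single visit (max EDSS by default). Errors
    name the offending column or row.
    """
    config = config or ValidationConfig()

    pdf = pd.read_csv(patients_path, dtype=str)
    _require_columns(pdf, _PATIENT_COLS[:5], patients_path)
    patients = []
    n_imputed = 0
    for i, rec in enumerate(pdf.to_dict("records"), start=2):
        sp_date, imputed = _parse_sp_date(rec.get("sp_date"), i)
        n_imputed += imputed
        try:
            patients.append(
                Patient(
                    patient_id=str(rec["patient_id"]).strip(),
                    sex=str(rec["sex"]).strip(),
                    birth_date=_parse_date(rec["birth_date"], i, "birth_date"),
                    onset_date=_parse_date(rec["onset_date"], i, "onset_date"),
                    assigned_phenotype=str(rec["assigned_phenotype"]).strip(),
                    sp_date=sp_date,
                    sp_date_imputed=imputed,
                )
            )
        except RowError as e:
            raise RowError(str(e), row=i) from None
    if n_imputed:
        logger.info("imputed %d bare-year SP dates to July 1 (mid-year convention)", n_imputed)

    vdf = pd.read_csv(visits_path, dtype=str)
    _require_columns(vdf, _VISIT_COLS, visits_path)
    has_fs = "pyramidal_fs" in vdf.columns
    visits: dict[tuple[str, dt.date], Visit] = {}
    for i, rec in enumerate(vdf.to_dict("records"), start=2):
        pid = str(rec["patient_id"]).strip()
        date = _parse_date(rec["visit_date"], i, "visit_date")
        try:
            edss = validate_edss(float(rec["edss"]), config)
        except (TypeError, ValueError) as e:
            if isinstance(e, RowError):
                raise RowError(str(e), row=i) from None
            raise RowError(f"unparseable EDSS {rec['edss']!r}", row=i) from None
        fs = None
        if has_fs and str(rec.get("pyramidal_fs", "")).strip() not in ("", "nan"):
            fs = int(float(rec["pyramidal_fs"]))
        key = (pid, date)
        new = Visit(pid, date, edss, pyramidal_fs=fs)
        if key in visits:
            keep = max if config.duplicate_visit_policy == "max" else min
            new = keep(visits[key], new, key=lambda v: v.edss)
        visits[key] = new

    relapses: list[Relapse] = []
    if relapses_path is not None:
        rdf = pd.read_csv(relapses_path, dtype=str)
        _require_columns(rdf, _RELAPSE_COLS, relapses_path)
        for i, rec in enumerate(rdf.to_dict("records"), start=2):
            relapses.append(
                Relapse(str(rec["patient_id"]).strip(), _parse_date(rec["relapse_date"], i, "relapse_date"))
            )

    return Cohort(patients=patients, visits=list(visits.values()), relapses=relapses)


def write_cohort(cohort: Cohort, patients_path, visits_path, relapses_path=None) -> None:
    """Write a cohort back to the three canonical CSV tables.

    Output is canonically sorted so that ``write(read(x))`` is
    byte-reproducible for validated input.
    """
    prec = []
    for p in sorted(cohort.patients, key=lambda p: p.patient_id):
        prec.append(
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "birth_date": p.birth_date.isoformat(),
                "onset_date": p.onset_date.isoformat(),
                "assigned_phenotype": p.assigned_phenotype,
                "sp_date": p.sp_date.isoformat() if p.sp_date else "",
            }
        )
    pd.DataFrame(prec, columns=_PATIENT_COLS).to_csv(patients_path, index=False)

    vrec = [
        {
            "patient_id": v.patient_id,
            "visit_date": v.visit_date.isoformat(),
            "edss": f"{v.edss:.1f}",
        }
        for v in sorted(cohort.visits, key=lambda v: (v.patient_id, v.visit_date))
    ]
    pd.DataFrame(vrec, columns=_VISIT_COLS).to_csv(visits_path, index=False)

    if relapses_path is not None:
        rrec = [
            {"patient_id": r.patient_id, "relapse_date": r.relapse_date.isoformat()}
            for r in sorted(cohort.relapses, key=lambda r: (r.patient_id, r.relapse_date))
        ]
        pd.DataFrame(rrec, columns=_RELAPSE_COLS).to_csv(relapses_path, index=False)


def _shift_years(date: dt.date, years: float) -> dt.date:
    return date + dt.timedelta(days=round(years * DAYS_PER_YEAR))
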