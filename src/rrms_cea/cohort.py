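"""Cohort data model, file I/O, inclusion screening and annual-cost aggregation.

The unit of analysis is a retrospective cohort of relapsing-remitting multiple
sclerosis (RRMS) patients, each on exactly one disease-modifying-therapy (DMT)
class: orally administered agents (``ORAL``), interferon beta-1a (``IFN``) or
monoclonal antibodies (``MAB``).  Each patient carries three binary clinical
outcome flags over the observation year (clinical relapse, disability
progression, new MRI lesion), whose logical OR is the composite outcome, plus
an annual direct medical cost in USD.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "CLASSES",
    "AGENTS",
    "AGENT_CLASS",
    "DURATION_BANDS",
    "DURATION_MIDPOINT",
    "SEXES",
    "AGE_BANDS",
    "CohortError",
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "PatientRecord",
    "CohortTable",
    "ScreeningRecord",
    "UnitCostTable",
    "read_cohort",
    "write_cohort",
    "apply_inclusion_criteria",
    "derive_composite",
    "compute_annual_cost",
    "age_band",
    "duration_midpoint",
]

CLASSES = ("ORAL", "IFN", "MAB")
SEXES = ("male", "female")

#: agent -> treatment class; membership must be consistent on every record
AGENT_CLASS = {
    "dimethyl_fumarate": "ORAL",
    "teriflunomide": "ORAL",
    "fingolimod": "ORAL",
    "rebif": "IFN",
    "natalizumab": "MAB",
    "rituximab": "MAB",
}
AGENTS = tuple(AGENT_CLASS)

#: therapy-duration band label -> midpoint in years, used for modelling;
#: the label itself is what files carry and reports print
DURATION_MIDPOINT = {"1-2yr": 1.5, "2-3yr": 2.5, "3-4yr": 3.5}
DURATION_BANDS = tuple(DURATION_MIDPOINT)

#: reporting age bands, closed on the left: [16,25], [26,35], [36,45], >45
AGE_BANDS = ("16-25yr", "26-35yr", "36-45yr", ">45yr")

CSV_COLUMNS = [
    "patient_id",
    "sex",
    "age_years",
    "treatment_class",
    "agent",
    "duration_band",
    "relapse",
    "progression",
    "mri_lesion",
    "annual_cost_usd",
]


class CohortError(ValueError):
    """Base error for cohort construction and I/O."""


class SchemaError(CohortError):
    """A required column is absent or unmappable."""


class ValidationError(CohortError):
    """A row violates a field-level or cross-field invariant."""


class ConfigError(CohortError):
    """Unit-cost configuration is incomplete or invalid."""


def age_band(age_years: int) -> str:
    """Reporting band for an integer age; bands are closed on the left."""
    if age_years <= 25:
        return "16-25yr"
    if age_years <= 35:
        return "26-35yr"
    if age_years <= 45:
        return "36-45yr"
    return ">45yr"


def duration_midpoint(band: str) -> float:
    """Midpoint in years of a therapy-duration band (modelling scale)."""
    try:
        return DURATION_MIDPOINT[band]
    except KeyError:
        raise ValidationError(f"unknown duration band {band!r}") from None


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates, therapy assignment, outcomes and annual cost."""

    patient_id: str
    sex: str
    age_years: int
    treatment_class: str
    agent: str
    duration_band: str
    relapse: int
    progression: int
    mri_lesion: int
    annual_cost_usd: float
    resource_counts: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        pid = self.patient_id
        if not pid:
            raise ValidationError("patient_id must be a non-empty token")
        if self.sex not in SEXES:
            raise ValidationError(f"patient {pid}: invalid sex {self.sex!r}")
        if not isinstance(self.age_years, int) or self.age_years < 16:
            raise ValidationError(
                f"patient {pid}: age_years must be an integer >= 16, got {self.age_years!r}"
            )
        if self.treatment_class not in CLASSES:
            raise ValidationError(
                f"patient {pid}: invalid treatment_class {self.treatment_class!r}"
            )
        if self.agent not in AGENT_CLASS:
            raise ValidationError(f"patient {pid}: invalid agent {self.agent!r}")
        if AGENT_CLASS[self.agent] != self.treatment_class:
            raise ValidationError(
                f"patient {pid}: agent {self.agent!r} is not a "
                f"{self.treatment_class} agent (it belongs to {AGENT_CLASS[self.agent]})"
            )
        if self.duration_band not in DURATION_MIDPOINT:
            raise ValidationError(
                f"patient {pid}: invalid duration_band {self.duration_band!r}"
            )
        for flag_name in ("relapse", "progression", "mri_lesion"):
            flag = getattr(self, flag_name)
            if flag not in (0, 1):
                raise ValidationError(
                    f"patient {pid}: outcome flag {flag_name} must be 0/1, got {flag!r}"
                )
        cost = self.annual_cost_usd
        if not math.isfinite(cost) or cost < 0:
            raise ValidationError(
                f"patient {pid}: annual_cost_usd must be finite and >= 0, got {cost!r}"
            )
        if self.resource_counts is not None:
            for name, count in self.resource_counts.items():
                if not math.isfinite(count) or count < 0:
                    raise ValidationError(
                        f"patient {pid}: resource count {name!r} must be >= 0"
                    )

    @property
    def composite(self) -> int:
        return derive_composite(self)

    @property
    def duration_midpoint_years(self) -> float:
        return duration_midpoint(self.duration_band)

    @property
    def age_band(self) -> str:
        return age_band(self.age_years)


def derive_composite(record: PatientRecord) -> int:
    """Composite outcome: 1 iff any of relapse / progression / MRI lesion is 1.

    Always re-derived from the component flags; a ``composite`` column in a
    file is never trusted.
    """
    for flag_name in ("relapse", "progression", "mri_lesion"):
        if getattr(record, flag_name) not in (0, 1):
            raise ValidationError(
                f"patient {record.patient_id}: missing/invalid flag {flag_name}"
            )
    return int(record.relapse or record.progression or record.mri_lesion)


@dataclass
class CohortTable:
    """Validated, ordered collection of :class:`PatientRecord`.

    ``provenance`` records where the table came from: the deterministic study
    fixture, the stochastic simulator, or a user-supplied file.
    """

    records: list[PatientRecord]
    provenance: str = "user"

    def __post_init__(self) -> None:
        if not self.records:
            raise CohortError("no records: a cohort must be nonempty")
        if self.provenance not in ("fixture", "simulated", "user"):
            raise CohortError(f"invalid provenance {self.provenance!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise ValidationError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.records == other.records

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; one row per patient, plus derived analysis columns.

        Derived columns (``composite``, ``effective``, ``duration_mid``,
        ``female``) are appended for convenience and are never written to file.
        """
        rows = []
        for rec in self.records:
            row = {c: getattr(rec, c) for c in CSV_COLUMNS}
            row["composite"] = rec.composite
            row["effective"] = 1 - rec.composite
            row["duration_mid"] = rec.duration_midpoint_years
            row["female"] = int(rec.sex == "female")
            if rec.resource_counts:
                for name, count in rec.resource_counts.items():
                    row[f"rc_{name}"] = count
            rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, classes: Iterable[str]) -> "CohortTable":
        wanted = set(classes)
        kept = [r for r in self.records if r.treatment_class in wanted]
        if not kept:
            raise CohortError(f"no records in classes {sorted(wanted)}")
        return CohortTable(kept, provenance=self.provenance)


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Parameters
    ----------
    path
        CSV file with a header row; comma-separated, UTF-8, ``.`` decimals.
    schema
        Optional map of file column name -> canonical field name, for files
        whose headers differ from the canonical ones.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CohortError(f"no records in {path}") from None
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise CohortError(f"no records in {path}")
    rc_cols = sorted(c for c in df.columns if c.startswith("rc_"))
    records = []
    for _, row in df.iterrows():
        counts = None
        if rc_cols:
            counts = {
                c[3:]: float(row[c]) for c in rc_cols if pd.notna(row[c])
            }
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                sex=str(row["sex"]),
                age_years=int(row["age_years"]),
                treatment_class=str(row["treatment_class"]),
                agent=str(row["agent"]),
                duration_band=str(row["duration_band"]),
                relapse=int(row["relapse"]),
                progression=int(row["progression"]),
                mri_lesion=int(row["mri_lesion"]),
                annual_cost_usd=float(row["annual_cost_usd"]),
                resource_counts=counts or None,
            )
        )
    return CohortTable(records, provenance="user")


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV such that :func:`read_cohort` round-trips it."""
    path = Path(path)
    rc_names = sorted(
        {name for r in cohort.records if r.resource_counts for name in r.resource_counts}
    )
    rows = []
    for rec in cohort.records:
        row = {c: getattr(rec, c) for c in CSV_COLUMNS}
        for name in rc_names:
            counts = rec.resource_counts or {}
            row[f"rc_{name}"] = counts.get(name, "")
        rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS + [f"rc_{n}" for n in rc_names]).to_csv(
        path, index=False
    )


@dataclass(frozen=True)
class ScreeningRecord:
    """Pre-inclusion chart-review record for one candidate patient."""

    patient_id: str
    diagnosis_date: _dt.date
    ms_type: str  # RRMS / SPMS / PPMS / other
    age_years: int
    months_observed: int
    other_chronic_conditions: int
    has_missing_data: int

    def __post_init__(self) -> None:
        if self.months_observed < 0:
            raise ValidationError(
                f"patient {self.patient_id}: months_observed must be >= 0"
            )


#: EMR system launch; diagnoses predating it cannot be fully observed
EMR_CUTOVER = _dt.date(2015, 5, 1)

# inclusion rules in priority order: (reason, predicate that must hold)
_INCLUSION_RULES = [
    ("not RRMS", lambda s: s.ms_type == "RRMS"),
    ("diagnosed before 2015-05-01", lambda s: s.diagnosis_date >= EMR_CUTOVER),
    ("younger than 18 years", lambda s: s.age_years >= 18),
    ("observed less than 12 months", lambda s: s.months_observed >= 12),
    ("other chronic conditions", lambda s: s.other_chronic_conditions == 0),
    ("missing data", lambda s: s.has_missing_data == 0),
]


def apply_inclusion_criteria(
    screening: Iterable[ScreeningRecord],
) -> tuple[list[str], list[tuple[str, str]]]:
    """Screen candidate patients against the study's inclusion criteria.

    A patient is included iff they have RRMS, were diagnosed on/after the EMR
    cut-over (2015-05-01), are adults (>= 18 years), were observed for at
    least 12 months, and have neither other chronic conditions nor missing
    data.  The exclusion log pairs each excluded id with the first failing
    rule, in the order above.
    """
    included: list[str] = []
    excluded: list[tuple[str, str]] = []
    for rec in screening:
        for reason, ok in _INCLUSION_RULES:
            if not ok(rec):
                excluded.append((rec.patient_id, reason))
                break
        else:
            included.append(rec.patient_id)
    return included, excluded


@dataclass(frozen=True)
class UnitCostTable:
    """Resource name -> unit cost in USD, from the payer's cost schedule."""

    costs: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, cost in self.costs.items():
            if not math.isfinite(cost) or cost < 0:
                raise ConfigError(f"unit cost for {name!r} must be finite and >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UnitCostTable":
        """Load a flat ``resource: cost`` mapping from a YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a flat mapping of resource -> cost")
        return cls({str(k): float(v) for k, v in raw.items()})

    def __getitem__(self, name: str) -> float:
        try:
            return self.costs[name]
        except KeyError:
            raise ConfigError(f"no unit cost configured for resource {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.costs


def compute_annual_cost(
    resource_counts: Mapping[str, float],
    unit_costs: UnitCostTable,
    drug_cost: float,
) -> float:
    """Annual total cost: drug acquisition plus priced resource utilisation.

    Returns ``drug_cost + sum(count * unit_cost)`` over the resources used.
    Every named resource must have a configured unit cost.
    """
    if not math.isfinite(drug_cost) or drug_cost < 0:
        raise ConfigError(f"drug_cost must be finite and >= 0, got {drug_cost!r}")
    total = float(drug_cost)
    for name, count in resource_counts.items():
        if name not in unit_costs:
            raise ConfigError(f"no unit cost configured for resource {name!r}")
        if not math.isfinite(count) or count < 0:
            raise ConfigError(f"resource count for {name!r} must be finite and >= 0")
        total += count * unit_costs[name]
    return total
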