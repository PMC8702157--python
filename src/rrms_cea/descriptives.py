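"""Descriptive cohort statistics: baseline frequencies, outcome rates, arm summaries."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .cohort import (
    AGENTS,
    AGE_BANDS,
    CLASSES,
    DURATION_BANDS,
    CohortError,
    CohortTable,
    age_band,
)

__all__ = [
    "ArmSummary",
    "round_half_up",
    "summarize_baseline",
    "outcome_rates",
    "arm_summaries",
]

OUTCOMES = ("relapse", "progression", "mri_lesion", "composite")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm effectiveness and cost summary (means and n-1 sample SDs).

    Effectiveness of a patient is the absence of the composite outcome;
    the arm's effectiveness mean and SD are reported on the percent scale.
    """

    treatment_class: str
    n: int
    effectiveness_mean: float  # percent
    effectiveness_sd: float  # percent
    cost_mean: float  # USD/yr
    cost_sd: float  # USD/yr

    def __post_init__(self) -> None:
        if not 0.0 <= self.effectiveness_mean <= 100.0:
            raise ValueError("effectiveness_mean outside [0, 100]")
        if self.effectiveness_sd < 0 or self.cost_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def _block(series: pd.Series, levels) -> pd.DataFrame:
    n = len(series)
    counts = series.value_counts()
    rows = [
        {
            "level": lvl,
            "count": int(counts.get(lvl, 0)),
            "percent": round_half_up(100.0 * counts.get(lvl, 0) / n),
        }
        for lvl in levels
    ]
    return pd.DataFrame(rows)


def summarize_baseline(cohort: CohortTable) -> pd.DataFrame:
    """Baseline characteristic frequencies and percentages (2 dp, half-up).

    Blocks: sex, reporting age band, agent, treatment class, therapy-duration
    band.  Within each block the percentages sum to 100 up to rounding.
    """
    df = cohort.to_frame()
    bands = df["age_years"].map(age_band)
    blocks = {
        "sex": _block(df["sex"], ("male", "female")),
        "age_band": _block(bands, AGE_BANDS),
        "agent": _block(df["agent"], AGENTS),
        "treatment_class": _block(df["treatment_class"], CLASSES),
        "duration_band": _block(df["duration_band"], DURATION_BANDS),
    }
    out = []
    for name, tbl in blocks.items():
        tbl = tbl.copy()
        tbl.insert(0, "block", name)
        out.append(tbl)
    return pd.concat(out, ignore_index=True)


def outcome_rates(cohort: CohortTable, by_class: bool = False) -> pd.DataFrame:
    """Event counts and percent rates per outcome, overall or per arm."""
    df = cohort.to_frame()
    groups = [("all", df)]
    if by_class:
        groups = [(cls, df[df["treatment_class"] == cls]) for cls in CLASSES]
    rows = []
    for label, sub in groups:
        n = len(sub)
        if n == 0:
            raise CohortError(f"no patients in group {label!r}")
        for outcome in OUTCOMES:
            k = int(sub[outcome].sum())
            rows.append(
                {
                    "group": label,
                    "outcome": outcome,
                    "n": n,
                    "events": k,
                    "percent": round_half_up(100.0 * k / n),
                }
            )
    return pd.DataFrame(rows)


def arm_summaries(cohort: CohortTable) -> list[ArmSummary]:
    """Effectiveness-rate and cost summaries per treatment arm.

    The per-patient effectiveness indicator is ``1 - composite``; the arm mean
    and its n-1 sample SD are scaled by 100 to the percent convention used in
    reporting.  Requires at least two patients per arm for the SD.
    """
    df = cohort.to_frame()
    out = []
    for cls in CLASSES:
        sub = df[df["treatment_class"] == cls]
        if len(sub) == 0:
            continue
        if len(sub) < 2:
            raise CohortError(f"arm {cls} has fewer than 2 patients")
        eff = sub["effective"].to_numpy(dtype=float)
        cost = sub["annual_cost_usd"].to_numpy(dtype=float)
        out.append(
            ArmSummary(
                treatment_class=cls,
                n=len(sub),
                effectiveness_mean=100.0 * float(eff.mean()),
                effectiveness_sd=100.0 * float(eff.std(ddof=1)),
                cost_mean=float(cost.mean()),
                cost_sd=float(cost.std(ddof=1)),
            )
        )
    return out
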