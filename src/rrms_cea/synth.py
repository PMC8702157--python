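"""Deterministic study-cohort fixture and stochastic cohort simulator.

The patient-level data behind the published cohort are not deposited, so this
module provides two stand-ins:

``make_study_fixture``
    A deterministic 146-patient cohort whose marginal structure reproduces the
    published baseline table and per-arm summaries exactly: arm sizes 40
    (oral) / 66 (interferon) / 40 (monoclonal antibodies), sex, age-band and
    duration-band margins, per-arm composite-outcome counts, and per-arm mean
    annual costs.  Joint covariate-outcome structure is NOT reproduced (it is
    unrecoverable from the printed margins); covariates are allocated evenly
    within arm, independent of outcome.

``simulate_cohort``
    A seeded generative model with known ground truth (arm event
    probabilities, cost moments, covariate margins) for recovery testing of
    the estimation machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import (
    CLASSES,
    DURATION_BANDS,
    CohortTable,
    PatientRecord,
    ScreeningRecord,
)

__all__ = [
    "SimulationParams",
    "make_study_fixture",
    "make_screening_fixture",
    "simulate_cohort",
    "FIXTURE_ARM_COSTS",
]

# --------------------------------------------------------------------------
# deterministic fixture
# --------------------------------------------------------------------------

#: per-arm constant annual cost (USD/yr) equal to the published arm means
FIXTURE_ARM_COSTS = {"ORAL": 11044.66, "IFN": 15381.31, "MAB": 16762.54}

# agents per arm in id order: (agent, count)
_FIXTURE_AGENTS = {
    "ORAL": [("dimethyl_fumarate", 2), ("teriflunomide", 15), ("fingolimod", 23)],
    "IFN": [("rebif", 66)],
    "MAB": [("natalizumab", 28), ("rituximab", 12)],
}

_FIXTURE_ARM_SIZES = {"ORAL": 40, "IFN": 66, "MAB": 40}

# patients experiencing the composite outcome per arm (arm size minus the
# composite-free count implied by the published effectiveness rates)
_FIXTURE_COMPOSITE = {"ORAL": 21, "IFN": 40, "MAB": 7}

# global component-flag totals: MRI lesions, clinical relapses, progressions
_FIXTURE_COMPONENT_TOTALS = {"mri_lesion": 52, "relapse": 31, "progression": 23}

# per-arm covariate compositions; ORAL and MAB are identical by construction
# (both arms have 40 patients) so their covariate multisets coincide, and the
# global margins are 95/51 (sex), 42/62/27/15 (age bands), 77/31/38 (duration)
_FIXTURE_SEX = {"ORAL": {"female": 26, "male": 14},
                "IFN": {"female": 43, "male": 23},
                "MAB": {"female": 26, "male": 14}}
_FIXTURE_AGE_BANDS = {"ORAL": {"16-25yr": 12, "26-35yr": 17, "36-45yr": 7, ">45yr": 4},
                      "IFN": {"16-25yr": 18, "26-35yr": 28, "36-45yr": 13, ">45yr": 7},
                      "MAB": {"16-25yr": 12, "26-35yr": 17, "36-45yr": 7, ">45yr": 4}}
_FIXTURE_DURATION = {"ORAL": {"1-2yr": 21, "2-3yr": 9, "3-4yr": 10},
                     "IFN": {"1-2yr": 35, "2-3yr": 13, "3-4yr": 18},
                     "MAB": {"1-2yr": 21, "2-3yr": 9, "3-4yr": 10}}

# integer ages cycled within each reporting band
_BAND_AGE_CYCLE = {
    "16-25yr": (19, 23, 21, 25, 17),
    "26-35yr": (28, 33, 30, 35, 26),
    "36-45yr": (38, 43, 40, 45, 36),
    ">45yr": (47, 52, 49, 55, 46),
}


def _spread(counts: Mapping[str, int], n: int) -> list[str]:
    """Deterministic even interleaving of category labels over n positions.

    Largest-remainder scheduling: at each position the category furthest
    behind its ideal quota is emitted (ties broken by insertion order), so
    every category's occurrences are spread evenly and counts are exact.
    """
    if sum(counts.values()) != n:
        raise ValueError("category counts must sum to n")
    labels = list(counts)
    assigned = {k: 0 for k in labels}
    out = []
    for i in range(1, n + 1):
        lbl = max(labels, key=lambda k: (counts[k] * i / n - assigned[k], -labels.index(k)))
        assigned[lbl] += 1
        out.append(lbl)
    return out


def make_study_fixture() -> CohortTable:
    """Deterministic 146-patient cohort matching the published margins.

    Repeated calls return identical tables.  Within each arm covariates are
    allocated by even interleaving, independent of outcome; composite-outcome
    patients are likewise spread evenly over arm positions.  Component flags
    (MRI lesion / relapse / progression) are distributed over the composite
    patients by cycling arms ORAL -> IFN -> MAB: the 52 MRI flags fill first,
    then the 31 relapse flags (continuing, then wrapping), then the 23
    progression flags, so every composite patient carries at least one flag
    and no composite-free patient carries any.
    """
    arms: dict[str, list[dict]] = {}
    pid = 0
    for cls in CLASSES:
        n = _FIXTURE_ARM_SIZES[cls]
        agents: list[str] = []
        for agent, cnt in _FIXTURE_AGENTS[cls]:
            agents.extend([agent] * cnt)
        sexes = _spread(_FIXTURE_SEX[cls], n)
        bands = _spread(_FIXTURE_AGE_BANDS[cls], n)
        durations = _spread(_FIXTURE_DURATION[cls], n)
        composite = _spread(
            {"yes": _FIXTURE_COMPOSITE[cls], "no": n - _FIXTURE_COMPOSITE[cls]}, n
        )
        band_seen: dict[str, int] = {}
        rows = []
        for i in range(n):
            pid += 1
            band = bands[i]
            k = band_seen.get(band, 0)
            band_seen[band] = k + 1
            rows.append(
                {
                    "patient_id": f"P{pid:03d}",
                    "sex": sexes[i],
                    "age_years": _BAND_AGE_CYCLE[band][k % 5],
                    "treatment_class": cls,
                    "agent": agents[i],
                    "duration_band": durations[i],
                    "composite": composite[i] == "yes",
                    "relapse": 0,
                    "progression": 0,
                    "mri_lesion": 0,
                    "annual_cost_usd": FIXTURE_ARM_COSTS[cls],
                }
            )
        arms[cls] = rows

    # cyclic arm order over composite patients for component-flag allocation
    per_arm = {cls: [r for r in arms[cls] if r["composite"]] for cls in CLASSES}
    sequence: list[dict] = []
    idx = {cls: 0 for cls in CLASSES}
    while any(idx[c] < len(per_arm[c]) for c in CLASSES):
        for cls in CLASSES:
            if idx[cls] < len(per_arm[cls]):
                sequence.append(per_arm[cls][idx[cls]])
                idx[cls] += 1
    assert len(sequence) == sum(_FIXTURE_COMPOSITE.values())

    pos = 0
    for flag, total in _FIXTURE_COMPONENT_TOTALS.items():
        placed = 0
        while placed < total:
            row = sequence[pos % len(sequence)]
            pos += 1
            if row[flag]:  # wrapped onto a patient already carrying this flag
                continue
            row[flag] = 1
            placed += 1

    records = []
    for cls in CLASSES:
        for row in arms[cls]:
            assert (row["relapse"] or row["progression"] or row["mri_lesion"]) == row[
                "composite"
            ]
            row.pop("composite")
            records.append(PatientRecord(**row))
    return CohortTable(records, provenance="fixture")


# screening fixture: 199 chart-review records of which exactly 53 fail one or
# more criteria, reproducing the published 146/199 inclusion flow
_SCREEN_FAILURES = [
    ("SPMS", 12), ("PPMS", 8),            # not RRMS
    ("pre_emr", 12),                      # diagnosed before the EMR cut-over
    ("minor", 6),                         # younger than 18
    ("short_followup", 8),                # observed < 12 months
    ("comorbid", 4),                      # other chronic conditions
    ("missing", 3),                       # missing observations
]


def make_screening_fixture() -> list[ScreeningRecord]:
    """Deterministic 199-record screening table; exactly 146 pass screening."""
    import datetime as dt

    records = []
    for i in range(146):
        records.append(
            ScreeningRecord(
                patient_id=f"S{i + 1:03d}",
                diagnosis_date=dt.date(2016, 1 + i % 12, 1 + i % 28),
                ms_type="RRMS",
                age_years=18 + i % 40,
                months_observed=12 + i % 48,
                other_chronic_conditions=0,
                has_missing_data=0,
            )
        )
    i = 146
    for kind, count in _SCREEN_FAILURES:
        for _ in range(count):
            i += 1
            rec = dict(
                patient_id=f"S{i:03d}",
                diagnosis_date=dt.date(2017, 1 + i % 12, 1 + i % 28),
                ms_type="RRMS",
                age_years=20 + i % 35,
                months_observed=24,
                other_chronic_conditions=0,
                has_missing_data=0,
            )
            if kind in ("SPMS", "PPMS"):
                rec["ms_type"] = kind
            elif kind == "pre_emr":
                rec["diagnosis_date"] = dt.date(2014, 1 + i % 12, 1 + i % 28)
            elif kind == "minor":
                rec["age_years"] = 16 + i % 2
            elif kind == "short_followup":
                rec["months_observed"] = i % 12
            elif kind == "comorbid":
                rec["other_chronic_conditions"] = 1
            else:
                rec["has_missing_data"] = 1
            records.append(ScreeningRecord(**rec))
    assert len(records) == 199
    return records


# --------------------------------------------------------------------------
# stochastic simulator
# --------------------------------------------------------------------------

def _default_arm(value_map):
    return field(default_factory=lambda: dict(value_map))


@dataclass
class SimulationParams:
    """Generative ground truth for simulated cohorts.

    Defaults reproduce the study conditions: arm sizes 40/66/40, per-arm
    composite-event probabilities implied by the published effectiveness
    rates (52.5% / 60.61% / 17.5%), per-arm cost means and SDs from the
    published cost summaries, and the published covariate margins.
    ``component_split`` gives, per class, the conditional probability of each
    component flag (relapse, progression, MRI lesion) given the composite;
    the default uses the global component mix (31/68, 23/68, 52/68).
    """

    arm_sizes: dict = _default_arm({"ORAL": 40, "IFN": 66, "MAB": 40})
    event_prob: dict = _default_arm(
        {"ORAL": 21 / 40, "IFN": 40 / 66, "MAB": 7 / 40}
    )
    component_split: dict = _default_arm(
        {cls: {"relapse": 31 / 68, "progression": 23 / 68, "mri_lesion": 52 / 68}
         for cls in CLASSES}
    )
    cost_mean: dict = _default_arm(
        {"ORAL": 11044.66, "IFN": 15381.31, "MAB": 16762.54}
    )
    cost_sd: dict = _default_arm({"ORAL": 2128.26, "IFN": 279.23, "MAB": 5939.96})
    sex_prob: float = 95 / 146  # probability female
    age_dist: tuple = (31.3, 8.5)  # mean, sd in years; truncated to [16, 70]
    duration_probs: tuple = (77 / 146, 31 / 146, 38 / 146)
    seed: int = 0

    def validate(self) -> None:
        for cls, n in self.arm_sizes.items():
            if cls not in CLASSES or n < 1:
                raise ValueError(f"invalid arm size {cls}={n}")
        for cls, p in self.event_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"event_prob[{cls}]={p} outside [0, 1]")
        for cls, split in self.component_split.items():
            for name, p in split.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"component_split[{cls}][{name}]={p} outside [0, 1]")
            if max(split.values()) <= 0:
                raise ValueError(f"component_split[{cls}] must have a positive entry")
        for cls, sd in self.cost_sd.items():
            if sd < 0:
                raise ValueError(f"cost_sd[{cls}]={sd} must be >= 0")
        for cls, m in self.cost_mean.items():
            if m < 0:
                raise ValueError(f"cost_mean[{cls}]={m} must be >= 0")
        if not 0.0 <= self.sex_prob <= 1.0:
            raise ValueError("sex_prob outside [0, 1]")
        if abs(sum(self.duration_probs) - 1.0) > 1e-12:
            raise ValueError("duration_probs must sum to 1")
        if any(p < 0 for p in self.duration_probs):
            raise ValueError("duration_probs must be nonnegative")


def _lognormal_costs(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and SD (constant if sd=0)."""
    if sd == 0 or mean == 0:
        return np.full(n, float(mean))
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def _truncated_ages(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Integer ages from a normal truncated to [16, 70], by rejection."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[(draw >= 16) & (draw <= 70)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return np.rint(out).astype(int).clip(16, 70)


# within-class agent mix used when drawing agents (fixture proportions)
_AGENT_MIX = {
    "ORAL": (("dimethyl_fumarate", 2 / 40), ("teriflunomide", 15 / 40), ("fingolimod", 23 / 40)),
    "IFN": (("rebif", 1.0),),
    "MAB": (("natalizumab", 28 / 40), ("rituximab", 12 / 40)),
}


def simulate_cohort(params: SimulationParams) -> CohortTable:
    """Draw a cohort from the generative model; reproducible from the seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    records = []
    pid = 0
    for cls in CLASSES:
        if cls not in params.arm_sizes:
            continue
        n = params.arm_sizes[cls]
        sexes = rng.random(n) < params.sex_prob
        ages = _truncated_ages(rng, params.age_dist[0], params.age_dist[1], n)
        durations = rng.choice(DURATION_BANDS, size=n, p=params.duration_probs)
        agents_lbl, agents_p = zip(*_AGENT_MIX[cls])
        agents = rng.choice(agents_lbl, size=n, p=agents_p)
        events = rng.random(n) < params.event_prob[cls]
        split = params.component_split[cls]
        costs = _lognormal_costs(rng, params.cost_mean[cls], params.cost_sd[cls], n)
        for i in range(n):
            flags = {"relapse": 0, "progression": 0, "mri_lesion": 0}
            if events[i]:
                for name in flags:
                    flags[name] = int(rng.random() < split[name])
                if not any(flags.values()):
                    # composite consistency: at least one component must fire
                    flags[max(split, key=split.get)] = 1
            pid += 1
            records.append(
                PatientRecord(
                    patient_id=f"S{pid:04d}",
                    sex="female" if sexes[i] else "male",
                    age_years=int(ages[i]),
                    treatment_class=cls,
                    agent=str(agents[i]),
                    duration_band=str(durations[i]),
                    annual_cost_usd=float(costs[i]),
                    **flags,
                )
            )
    return CohortTable(records, provenance="simulated")
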