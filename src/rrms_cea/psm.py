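"""Propensity-score-matched incremental cost-effectiveness analysis.

Pipeline for one pairwise class comparison (treat vs comparator):

1. a logistic propensity model of treatment assignment on age, sex and
   therapy-duration midpoint;
2. 1:1 greedy nearest-neighbour matching without replacement on the logit of
   the propensity score, within a caliper expressed as a multiple of the
   pooled logit-score SD;
3. incremental annual cost (delta C) and incremental effectiveness (delta E,
   the difference in the proportion free of the composite outcome) over the
   matched sets, and their ratio, the incremental cost-effectiveness ratio
   (ICER, USD per composite event prevented);
4. a non-parametric bootstrap that resamples patients with replacement
   within each arm, re-estimates the propensity model and re-matches on every
   replicate, yielding percentile confidence intervals and the fraction of
   replicates in each cost-effectiveness-plane quadrant (the dominance
   "confidence level" is the SE-quadrant fraction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm
from .cohort import CLASSES, CohortError, CohortTable

__all__ = [
    "MatchingError",
    "PropensityMatch",
    "CEReplicate",
    "IcerResult",
    "CEAResult",
    "estimate_propensity",
    "match_nearest",
    "delta_cost_effect",
    "icer",
    "bootstrap_cea",
    "quadrant_report",
]

QUADRANTS = ("NE", "SE", "SW", "NW")

_QUADRANT_LABELS = {
    "NE": "more effective and more costly",
    "SE": "dominant (more effective and less costly)",
    "SW": "less effective and less costly",
    "NW": "dominated (less effective and more costly)",
}


class MatchingError(CohortError):
    """Matching produced no usable pairs."""


@dataclass
class PropensityMatch:
    """Result of matching one treated arm against one comparator arm."""

    treat: str
    comparator: str
    scores: dict[str, float]
    pairs: list[tuple[str, str]]
    caliper: float
    n_unmatched: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t, c in self.pairs:
            if t in seen or c in seen:
                raise ValueError("a patient appears in more than one pair")
            seen.update((t, c))


@dataclass(frozen=True)
class CEReplicate:
    """One (delta cost, delta effect) draw: treated minus comparator."""

    delta_cost: float
    delta_effect: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_cost) and math.isfinite(self.delta_effect)):
            raise ValueError("increments must be finite")
        if not -1.0 <= self.delta_effect <= 1.0:
            raise ValueError("delta_effect must lie in [-1, 1]")


@dataclass(frozen=True)
class IcerResult:
    """ICER value (USD per composite event prevented) and CE-plane quadrant."""

    value: float | None  # None when delta_effect == 0 (undefined ratio)
    quadrant: str
    defined: bool


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.log(p / (1.0 - p))


def _propensity_design(covariates: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Intercept plus the non-constant covariate columns.

    Constant columns carry no assignment information and would make the
    design rank-deficient; with no varying covariate the model degrades to
    intercept-only (every score equals the treated fraction).
    """
    keep = [j for j in range(covariates.shape[1]) if covariates[:, j].std() > 0]
    X = np.column_stack(
        [np.ones(len(covariates))] + [covariates[:, j] for j in keep]
    )
    return X, ["intercept"] + [glm.ADJUSTERS[j] for j in keep]


def estimate_propensity(
    cohort: CohortTable, treat: str, comparator: str
) -> dict[str, float]:
    """Fitted probabilities of receiving ``treat`` (vs ``comparator``).

    Logistic model of the treatment indicator on age (years), sex (female=1)
    and therapy-duration band midpoint, restricted to the two arms.
    """
    for cls in (treat, comparator):
        if cls not in CLASSES:
            raise CohortError(f"unknown treatment class {cls!r}")
    if treat == comparator:
        raise CohortError("treat and comparator must differ")
    df = cohort.subset([treat, comparator]).to_frame()
    for cls in (treat, comparator):
        if not (df["treatment_class"] == cls).any():
            raise CohortError(f"arm {cls} is empty")
    y = (df["treatment_class"] == treat).to_numpy(dtype=float)
    X, cols = _propensity_design(df[list(glm.ADJUSTERS)].to_numpy(dtype=float))
    try:
        fit = glm.fit_logistic(X, y, columns=cols)
    except glm.SeparationError as exc:
        raise glm.SeparationError(
            f"propensity model separated ({exc}); covariates perfectly predict "
            "the arm, so no overlap exists to match on"
        ) from exc
    eta = X @ fit.coefficients
    probs = 1.0 / (1.0 + np.exp(-eta))
    return dict(zip(df["patient_id"], probs.astype(float)))


def _greedy_match(
    logit_t: np.ndarray,
    logit_c: np.ndarray,
    ids_t: np.ndarray,
    ids_c: np.ndarray,
    caliper: float,
) -> list[tuple[int, int]]:
    """Greedy 1:1 nearest-neighbour matching on precomputed logit scores.

    Treated units are visited in descending score order (ties by ascending
    id); each takes its nearest unmatched comparator within the caliper, ties
    broken by the smaller comparator id.  Returns index pairs into the two
    input arrays.
    """
    order = np.lexsort((ids_t, -logit_t))
    comp_order = np.lexsort((ids_c,))  # visit candidates in ascending id
    lc = logit_c[comp_order]
    available = np.ones(len(ids_c), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for ti in order:
        if not available.any():
            break
        dist = np.abs(lc - logit_t[ti])
        dist[~available] = np.inf
        best = np.argmin(dist)  # first minimum = smallest id among ties
        if available[best] and dist[best] <= caliper:
            available[best] = False
            pairs.append((int(ti), int(comp_order[best])))
    return pairs


def match_nearest(
    scores: dict[str, float],
    treated_ids: list[str],
    comparator_ids: list[str],
    caliper_sd: float | None = 0.2,
    treat: str = "treat",
    comparator: str = "comparator",
) -> PropensityMatch:
    """1:1 greedy nearest-neighbour matching without replacement.

    The caliper is ``caliper_sd`` times the n-1 SD of the pooled logit
    scores; pass ``None`` (or ``inf``) for caliper-free matching.  The
    procedure is deterministic: treated units are processed in descending
    score order and score ties are resolved by smaller patient id.
    """
    for pid in list(treated_ids) + list(comparator_ids):
        if pid not in scores:
            raise MatchingError(f"no propensity score for patient {pid!r}")
    lt = _logit(np.array([scores[i] for i in treated_ids], dtype=float))
    lc = _logit(np.array([scores[i] for i in comparator_ids], dtype=float))
    pooled = np.concatenate([lt, lc])
    pooled_sd = float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0
    if caliper_sd is None or math.isinf(caliper_sd):
        caliper = math.inf
    else:
        if caliper_sd < 0:
            raise MatchingError("caliper_sd must be >= 0")
        caliper = caliper_sd * pooled_sd
    idx_pairs = _greedy_match(
        lt, lc, np.asarray(treated_ids), np.asarray(comparator_ids), caliper
    )
    pairs = [(treated_ids[ti], comparator_ids[ci]) for ti, ci in idx_pairs]
    if not pairs:
        raise MatchingError(
            f"zero pairs formed between {treat} and {comparator} at caliper {caliper:g}"
        )
    n_unmatched = (len(treated_ids) - len(pairs)) + (len(comparator_ids) - len(pairs))
    match = PropensityMatch(
        treat=treat,
        comparator=comparator,
        scores=dict(scores),
        pairs=pairs,
        caliper=caliper,
        n_unmatched=n_unmatched,
    )
    return match


def delta_cost_effect(cohort: CohortTable, match: PropensityMatch) -> CEReplicate:
    """Incremental cost and effectiveness over the matched sets.

    delta C is the matched-treated mean annual cost minus the
    matched-comparator mean; delta E is the difference in the proportion
    free of the composite outcome (treated minus comparator).
    """
    if not match.pairs:
        raise MatchingError("no matched pairs")
    by_id = {r.patient_id: r for r in cohort.records}
    t_ids = [t for t, _ in match.pairs]
    c_ids = [c for _, c in match.pairs]
    t_cost = float(np.mean([by_id[i].annual_cost_usd for i in t_ids]))
    c_cost = float(np.mean([by_id[i].annual_cost_usd for i in c_ids]))
    t_eff = float(np.mean([1 - by_id[i].composite for i in t_ids]))
    c_eff = float(np.mean([1 - by_id[i].composite for i in c_ids]))
    return CEReplicate(delta_cost=t_cost - c_cost, delta_effect=t_eff - c_eff)


def icer(rep: CEReplicate) -> IcerResult:
    """ICER and CE-plane quadrant of one incremental pair.

    Quadrant convention: delta E >= 0 counts as "more effective" and
    delta C <= 0 as "cost-saving"; SE is both (dominance), NE effective but
    costlier, SW cheaper but less effective, NW costlier and less effective.
    A zero delta E leaves the ratio undefined but still assigns a quadrant.
    """
    effective = rep.delta_effect >= 0.0
    saving = rep.delta_cost <= 0.0
    quadrant = {(True, True): "SE", (True, False): "NE",
                (False, True): "SW", (False, False): "NW"}[(effective, saving)]
    if rep.delta_effect == 0.0:
        return IcerResult(value=None, quadrant=quadrant, defined=False)
    return IcerResult(
        value=rep.delta_cost / rep.delta_effect, quadrant=quadrant, defined=True
    )


@dataclass
class CEAResult:
    """Summary of a matched-bootstrap cost-effectiveness comparison."""

    treat: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    icer_defined: bool
    quadrant: str
    ci_delta_cost: tuple[float, float]
    ci_delta_effect: tuple[float, float]
    quadrant_probs: dict[str, float]
    B: int
    seed: int
    n_failures: int
    caliper_sd: float | None
    resample_mode: str
    replicates: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if abs(sum(self.quadrant_probs.values()) - 1.0) > 1e-12:
            raise ValueError("quadrant probabilities must sum to 1")
        for lo, hi in (self.ci_delta_cost, self.ci_delta_effect):
            if lo > hi:
                raise ValueError("confidence limits must be ordered")

    def to_dict(self) -> dict:
        return {
            "treat": self.treat,
            "comparator": self.comparator,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "delta_effect_pct": 100.0 * self.delta_effect,
            "icer": self.icer,
            "icer_defined": self.icer_defined,
            "quadrant": self.quadrant,
            "ci_delta_cost": list(self.ci_delta_cost),
            "ci_delta_effect": list(self.ci_delta_effect),
            "ci_delta_effect_pct": [100.0 * v for v in self.ci_delta_effect],
            "quadrant_probs": {q: self.quadrant_probs[q] for q in QUADRANTS},
            "B": self.B,
            "seed": self.seed,
            "n_failures": self.n_failures,
            "caliper_sd": self.caliper_sd,
            "resample_mode": self.resample_mode,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _arm_arrays(cohort: CohortTable, cls: str):
    df = cohort.subset([cls]).to_frame()
    return {
        "X": df[list(glm.ADJUSTERS)].to_numpy(dtype=float),
        "cost": df["annual_cost_usd"].to_numpy(dtype=float),
        "eff": df["effective"].to_numpy(dtype=float),
        "ids": df["patient_id"].to_numpy(dtype=object),
    }


def _replicate_rematch(
    rng: np.random.Generator, at: dict, ac: dict, caliper_sd: float | None
) -> tuple[float, float]:
    """One bootstrap replicate: resample within arms, refit, rematch."""
    nt, nc = len(at["cost"]), len(ac["cost"])
    it = rng.integers(0, nt, nt)
    ic = rng.integers(0, nc, nc)
    Xt, Xc = at["X"][it], ac["X"][ic]
    X, cols = _propensity_design(np.vstack([Xt, Xc]))
    y = np.concatenate([np.ones(nt), np.zeros(nc)])
    fit = glm.fit_logistic(X, y, columns=cols)
    eta = X @ fit.coefficients
    logits = eta  # the logit of the fitted probability is the linear predictor
    lt, lc = logits[:nt], logits[nt:]
    if caliper_sd is None or math.isinf(caliper_sd):
        caliper = math.inf
    else:
        caliper = caliper_sd * float(np.concatenate([lt, lc]).std(ddof=1))
    # resampled rows are distinct pseudo-patients; position is the tie-break id
    pairs = _greedy_match(lt, lc, np.arange(nt), np.arange(nc), caliper)
    if not pairs:
        raise MatchingError("zero pairs in replicate")
    ti = np.array([p[0] for p in pairs])
    ci = np.array([p[1] for p in pairs])
    dc = float(at["cost"][it][ti].mean() - ac["cost"][ic][ci].mean())
    de = float(at["eff"][it][ti].mean() - ac["eff"][ic][ci].mean())
    return dc, de


def bootstrap_cea(
    cohort: CohortTable,
    treat: str,
    comparator: str,
    B: int = 10_000,
    seed: int = 0,
    caliper_sd: float | None = 0.2,
    resample_mode: str = "rematch",
) -> CEAResult:
    """Non-parametric bootstrap of the matched incremental cost and effect.

    Each replicate resamples patients with replacement within each arm (arm
    sizes preserved).  In ``rematch`` mode (default) the propensity model is
    re-estimated and matching redone on every replicate, so matching
    uncertainty is propagated; in ``pairs`` mode the original matched pairs
    are resampled instead.  Percentile 2.5/97.5 intervals and CE-plane
    quadrant fractions summarise the replicate cloud; the point estimate
    comes from the original (un-resampled) matched data.  Replicates where
    matching or the propensity fit fails are redrawn and counted; more than
    10% failures aborts.  Identical seed and inputs give identical results.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if resample_mode not in ("rematch", "pairs"):
        raise ValueError(f"unknown resample_mode {resample_mode!r}")
    two = cohort.subset([treat, comparator])
    at = _arm_arrays(two, treat)
    ac = _arm_arrays(two, comparator)
    if len(at["cost"]) < 2 or len(ac["cost"]) < 2:
        raise CohortError("both arms need at least 2 patients")

    scores = estimate_propensity(two, treat, comparator)
    point_match = match_nearest(
        scores,
        list(at["ids"]),
        list(ac["ids"]),
        caliper_sd=caliper_sd,
        treat=treat,
        comparator=comparator,
    )
    point = delta_cost_effect(two, point_match)
    point_icer = icer(point)

    dcs = np.empty(B)
    des = np.empty(B)
    failures = 0
    if resample_mode == "pairs":
        by_id = {r.patient_id: r for r in two.records}
        pair_dc = np.array(
            [by_id[t].annual_cost_usd - by_id[c].annual_cost_usd for t, c in point_match.pairs]
        )
        pair_de = np.array(
            [(1 - by_id[t].composite) - (1 - by_id[c].composite) for t, c in point_match.pairs]
        )
        m = len(point_match.pairs)
        for r in range(B):
            rng = np.random.default_rng([seed, r])
            idx = rng.integers(0, m, m)
            dcs[r] = pair_dc[idx].mean()
            des[r] = pair_de[idx].mean()
    else:
        for r in range(B):
            rng = np.random.default_rng([seed, r])
            for attempt in range(50):
                try:
                    dcs[r], des[r] = _replicate_rematch(rng, at, ac, caliper_sd)
                    break
                except (MatchingError, glm.GlmError):
                    failures += 1
            else:
                raise MatchingError(
                    f"replicate {r} failed 50 consecutive redraws; "
                    "matching is infeasible on resampled data"
                )
        if failures > 0.1 * B:
            raise MatchingError(
                f"{failures} failed replicates out of {B} (> 10%); "
                "widen the caliper or check arm overlap"
            )

    effective = des >= 0.0
    saving = dcs <= 0.0
    quadrant_probs = {
        "NE": float(np.mean(effective & ~saving)),
        "SE": float(np.mean(effective & saving)),
        "SW": float(np.mean(~effective & saving)),
        "NW": float(np.mean(~effective & ~saving)),
    }
    replicates = pd.DataFrame(
        {"replicate": np.arange(B), "delta_cost": dcs, "delta_effect": des}
    )
    return CEAResult(
        treat=treat,
        comparator=comparator,
        delta_cost=point.delta_cost,
        delta_effect=point.delta_effect,
        icer=point_icer.value,
        icer_defined=point_icer.defined,
        quadrant=point_icer.quadrant,
        ci_delta_cost=(float(np.percentile(dcs, 2.5)), float(np.percentile(dcs, 97.5))),
        ci_delta_effect=(float(np.percentile(des, 2.5)), float(np.percentile(des, 97.5))),
        quadrant_probs=quadrant_probs,
        B=B,
        seed=seed,
        n_failures=failures,
        caliper_sd=caliper_sd,
        resample_mode=resample_mode,
        replicates=replicates,
    )


def quadrant_report(result: CEAResult) -> str:
    """Human-readable dominance summary of a CEA result.

    Names the modal quadrant with its bootstrap confidence level when it is
    unique; lists all quadrants otherwise.  Fractions print to 2 dp on the
    percent scale.
    """
    probs = result.quadrant_probs
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"quadrant probabilities sum to {total!r}, not 1")
    lines = [f"{result.treat} vs {result.comparator}"]
    de_pct = 100.0 * result.delta_effect
    lines.append(
        f"  incremental cost  : {result.delta_cost:,.2f} USD/yr "
        f"(95% CI {result.ci_delta_cost[0]:,.2f} to {result.ci_delta_cost[1]:,.2f})"
    )
    lines.append(
        f"  incremental effect: {de_pct:.2f} percentage points "
        f"(95% CI {100 * result.ci_delta_effect[0]:.2f} to {100 * result.ci_delta_effect[1]:.2f})"
    )
    if result.icer_defined:
        lines.append(f"  ICER              : {result.icer:,.2f} USD per composite event prevented")
    else:
        lines.append("  ICER              : undefined (zero incremental effectiveness)")
    best = max(probs.values())
    modal = [q for q in QUADRANTS if probs[q] == best]
    if len(modal) == 1:
        q = modal[0]
        lines.append(
            f"  conclusion        : {_QUADRANT_LABELS[q]} with {100 * probs[q]:.2f}% "
            f"confidence ({result.B} bootstrap replicates)"
        )
    else:
        lines.append("  conclusion        : no dominant quadrant")
    for q in QUADRANTS:
        lines.append(f"    {q}: {100 * probs[q]:.2f}%")
    return "\n".join(lines)
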