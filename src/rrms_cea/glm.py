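"""Maximum-likelihood logistic regression with Wald inference.

Fits Bernoulli GLMs by iteratively reweighted least squares (IRLS, i.e.
Newton-Raphson on the log-likelihood) with step-halving, and derives adjusted
odds ratios with Wald confidence intervals and p-values.  Also provides the
one-vs-rest treatment-class odds-ratio analyses (one model per class per
outcome, each adjusted for age, sex and duration of therapy) and an a-priori
sample-size estimate for detecting a target odds ratio.

Perfect or quasi-perfect separation is detected (coefficients diverging on
the standardised-covariate scale) and raised as an explicit error rather than
silently penalised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CLASSES, CohortTable

__all__ = [
    "GlmError",
    "SeparationError",
    "LogisticFit",
    "OddsRatioResult",
    "SampleSizeSpec",
    "fit_logistic",
    "wald_or",
    "class_or_analysis",
    "min_sample_size",
]

#: divergence threshold for |beta_j| * sd(x_j) on standardised covariates
_SEPARATION_NORM = 15.0


class GlmError(ValueError):
    """Design/response problem that prevents a well-defined fit."""


class SeparationError(GlmError):
    """The MLE does not exist (perfect or quasi-perfect separation)."""


@dataclass
class LogisticFit:
    """A converged (or explicitly non-converged) logistic fit.

    ``coefficients`` are on the log-odds scale, ``covariance`` is the inverse
    observed information at the optimum.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    iterations: int
    columns: list[str] = field(default_factory=list)
    ll_trace: list[float] = field(default_factory=list, repr=False)

    def se(self, index: int) -> float:
        return math.sqrt(self.covariance[index, index])


@dataclass(frozen=True)
class OddsRatioResult:
    """Adjusted odds ratio for one exposure with Wald CI and p-value."""

    exposure: str
    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted_for: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable sum of y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Fit a Bernoulli GLM with logit link by IRLS.

    Parameters
    ----------
    X
        Design matrix, one row per observation, including the intercept
        column if one is wanted.
    y
        Binary response vector.
    columns
        Optional column labels, used in error messages and results.

    The Newton step is halved until the log-likelihood does not decrease, so
    the likelihood is nondecreasing across iterations.  Convergence is
    declared when the maximum absolute score falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise GlmError("design matrix must be 2-dimensional")
    n, p = X.shape
    if columns is None:
        columns = [f"x{j}" for j in range(p)]
    if len(columns) != p:
        raise GlmError("columns must match the design matrix width")
    if y.shape != (n,):
        raise GlmError("response length must match the design matrix")
    if not np.isin(y, (0.0, 1.0)).all():
        raise GlmError("response must be binary (0/1)")
    if n < p:
        raise GlmError("more parameters than observations")
    if y.sum() == 0 or y.sum() == n:
        raise SeparationError("degenerate response: outcome is constant")
    if np.linalg.matrix_rank(X) < p:
        raise GlmError("design matrix is rank deficient")

    col_sd = X.std(axis=0)  # 0 for the intercept column
    beta = np.zeros(p)
    eta = X @ beta
    ll = _log_likelihood(eta, y)
    ll_trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "information matrix is singular (separation or collinearity)"
            ) from None
        # step-halving: never let the log-likelihood decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            cand_ll = _log_likelihood(X @ cand, y)
            if cand_ll >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        eta = X @ beta
        ll = cand_ll
        ll_trace.append(ll)

        scaled = np.abs(beta) * np.where(col_sd > 0, col_sd, 0.0)
        # intercept-only models are judged on the raw coefficient instead
        if col_sd.max() == 0:
            scaled = np.abs(beta)
        if scaled.max() > _SEPARATION_NORM:
            culprit = columns[int(np.argmax(scaled))]
            raise SeparationError(
                f"separation detected: coefficient for {culprit!r} is diverging"
            )

    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None])
    covariance = np.linalg.inv(info)
    covariance = (covariance + covariance.T) / 2.0
    return LogisticFit(
        coefficients=beta,
        covariance=covariance,
        log_likelihood=ll,
        converged=converged,
        iterations=it,
        columns=list(columns),
        ll_trace=ll_trace,
    )


def wald_or(
    fit: LogisticFit,
    index: int,
    level: float = 0.95,
    outcome: str = "",
) -> OddsRatioResult:
    """Odds ratio, Wald CI and two-sided Wald p-value for one coefficient."""
    if not 0 <= index < len(fit.coefficients):
        raise IndexError(f"coefficient index {index} out of range")
    if not fit.converged:
        raise GlmError("fit did not converge; Wald inference is not reliable")
    beta = float(fit.coefficients[index])
    se = fit.se(index)
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    if se == 0.0:
        p = 1.0 if beta == 0.0 else 0.0
    else:
        p = 2.0 * stats.norm.sf(abs(beta) / se)
    adjusted = tuple(
        c for j, c in enumerate(fit.columns) if j != index and c != "intercept"
    )
    return OddsRatioResult(
        exposure=fit.columns[index],
        outcome=outcome,
        odds_ratio=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p_value=float(p),
        adjusted_for=adjusted,
    )


#: covariates every class model adjusts for (coding: age in years, female=1,
#: duration as band midpoint in years)
ADJUSTERS = ("age_years", "female", "duration_mid")


def class_or_analysis(
    cohort: CohortTable, outcome: str
) -> tuple[list[OddsRatioResult], dict[str, str]]:
    """One-vs-rest adjusted odds ratios of an outcome for each therapy class.

    For each class a separate logistic model regresses the outcome on the
    class indicator (that class vs the other two pooled) plus age, sex and
    therapy-duration midpoint; the indicator's Wald odds ratio is reported.

    Returns the successful results and a map of class -> error message for
    models that could not be fitted (e.g. separation); at least one class
    must be estimable.
    """
    if outcome not in ("relapse", "progression", "mri_lesion", "composite"):
        raise GlmError(f"unknown outcome {outcome!r}")
    df = cohort.to_frame()
    present = set(df["treatment_class"])
    if present != set(CLASSES):
        raise GlmError(f"all three classes required, found {sorted(present)}")
    y = df[outcome].to_numpy(dtype=float)
    base = df[list(ADJUSTERS)].to_numpy(dtype=float)
    results: list[OddsRatioResult] = []
    failures: dict[str, str] = {}
    for cls in CLASSES:
        ind = (df["treatment_class"] == cls).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(df)), ind, base])
        cols = ["intercept", cls, *ADJUSTERS]
        try:
            fit = fit_logistic(X, y, columns=cols)
            results.append(wald_or(fit, 1, outcome=outcome))
        except GlmError as exc:
            failures[cls] = str(exc)
    if not results:
        raise GlmError(f"no class model estimable for {outcome}: {failures}")
    return results, failures


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the a-priori sample-size estimate for a target odds ratio."""

    target_or: float
    alpha: float = 0.05
    power: float = 0.95
    baseline_event_rate: float = 0.5
    exposure_prevalence: float = 0.5

    def __post_init__(self) -> None:
        if self.target_or <= 0:
            raise ValueError("target_or must be positive")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power < 1.0:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.power <= self.alpha:
            raise ValueError("power must exceed alpha")
        for name in ("baseline_event_rate", "exposure_prevalence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


def min_sample_size(spec: SampleSizeSpec) -> int:
    """Smallest n giving the requested power for a two-sided Wald test of the
    exposure log-odds ratio, by the two-group normal approximation.

    With exposure prevalence q, baseline (unexposed) event rate p0, and
    exposed rate p1 implied by the target OR, the variance of the estimated
    log-OR at total size n is ``V/n`` with
    ``V = 1/(q p1 (1-p1)) + 1/((1-q) p0 (1-p0))``; the requirement
    ``|log OR| / sqrt(V/n) >= z_{1-alpha/2} + z_{power}`` solves for n.
    The result is nonincreasing in |log OR| and in alpha.
    """
    if spec.target_or == 1.0:
        raise GlmError("target odds ratio of 1 is undetectable")
    p0 = spec.baseline_event_rate
    q = spec.exposure_prevalence
    odds1 = spec.target_or * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    log_or = math.log(spec.target_or)
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    v = 1.0 / (q * p1 * (1.0 - p1)) + 1.0 / ((1.0 - q) * p0 * (1.0 - p0))
    return int(math.ceil((z_a + z_b) ** 2 * v / log_or**2))
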