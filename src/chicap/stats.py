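"""Cohort-level statistics.

Exact (Clopper-Pearson) binomial confidence intervals for prevalence and
diagnostic yield, unadjusted 2x2 odds ratios with Woolf-logit intervals,
and covariate-adjusted odds ratios from maximum-likelihood logistic
regression (statsmodels GLM / binomial family, i.e. IRLS).

Percentages are displayed with round-half-up to the whole percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def round_half_up(x: float) -> int:
    """Round a non-negative value half-up (2.5 -> 3), the convention used
    for printed whole-percent figures."""
    if x < 0:
        raise ValueError("round_half_up expects non-negative input")
    return int(math.floor(x + 0.5))


def pct(x: int, n: int) -> int:
    """Whole-percent representation of a proportion."""
    return round_half_up(100.0 * x / n)


def binomial_ci(
    x: int, n: int, level: float = 0.95, method: str = "clopper-pearson"
) -> tuple[float, float]:
    """Two-sided exact binomial confidence interval.

    Clopper-Pearson via Beta quantiles: lower = Beta(x, n-x+1) quantile at
    alpha/2 (0 when x=0), upper = Beta(x+1, n-x) quantile at 1-alpha/2
    (1 when x=n). A Wilson score interval is available behind
    ``method="wilson"``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, n={n}]")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        lower = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
        upper = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
        return lower, upper
    if method == "wilson":
        z = sps.norm.ppf(1 - alpha / 2)
        p = x / n
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        return max(0.0, centre - half), min(1.0, centre + half)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class PatientRecord:
    """One child in the cohort."""

    id: str
    age_years: float
    sex: str  # female | male
    tumor_group: str  # CNS | extracranial
    chicap_diagnosis: bool
    known_at_inclusion: bool = False
    icc3_group: Optional[str] = None
    criteria: Optional[object] = None  # CriteriaScore

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.tumor_group not in ("CNS", "extracranial"):
            raise ValueError(f"unknown tumor_group {self.tumor_group!r}")
        if self.known_at_inclusion and not self.chicap_diagnosis:
            raise ValueError("known_at_inclusion implies chicap_diagnosis")


@dataclass
class CohortSummary:
    n_total: int
    n_chicap: int
    prevalence: float
    prevalence_ci: tuple[float, float]
    n_known_at_inclusion: int
    n_new_diagnoses: int
    yield_denominator: int
    diagnostic_yield: Optional[float]
    yield_ci: Optional[tuple[float, float]]
    share_unknown_at_inclusion: Optional[float]
    per_tumor_group: pd.DataFrame = field(repr=False, default=None)

    @property
    def prevalence_pct(self) -> int:
        return pct(self.n_chicap, self.n_total)

    @property
    def yield_pct(self) -> Optional[int]:
        if self.diagnostic_yield is None:
            return None
        return pct(self.n_new_diagnoses, self.yield_denominator)


def prevalence_and_yield(
    cohort: Sequence[PatientRecord], level: float = 0.95
) -> CohortSummary:
    """Prevalence over the whole cohort; diagnostic yield over patients
    without a known diagnosis at inclusion."""
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)
    n_pos = sum(p.chicap_diagnosis for p in cohort)
    n_known = sum(p.known_at_inclusion for p in cohort)
    n_new = n_pos - n_known
    denom = n - n_known
    per_group = (
        pd.DataFrame(
            [
                {"tumor_group": g,
                 "n": sum(1 for p in cohort if p.tumor_group == g),
                 "n_chicap": sum(1 for p in cohort
                                 if p.tumor_group == g and p.chicap_diagnosis)}
                for g in ("CNS", "extracranial")
            ]
        )
        .assign(prevalence=lambda d: d.n_chicap / d.n.where(d.n > 0))
    )
    if denom == 0:
        return CohortSummary(
            n_total=n, n_chicap=n_pos, prevalence=n_pos / n,
            prevalence_ci=binomial_ci(n_pos, n, level),
            n_known_at_inclusion=n_known, n_new_diagnoses=n_new,
            yield_denominator=0, diagnostic_yield=None, yield_ci=None,
            share_unknown_at_inclusion=(n_new / n_pos if n_pos else None),
            per_tumor_group=per_group,
        )
    return CohortSummary(
        n_total=n,
        n_chicap=n_pos,
        prevalence=n_pos / n,
        prevalence_ci=binomial_ci(n_pos, n, level),
        n_known_at_inclusion=n_known,
        n_new_diagnoses=n_new,
        yield_denominator=denom,
        diagnostic_yield=n_new / denom,
        yield_ci=binomial_ci(n_new, denom, level),
        share_unknown_at_inclusion=(n_new / n_pos if n_pos else None),
        per_tumor_group=per_group,
    )


def odds_ratio_2x2(
    a: float, b: float, c: float, d: float, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Unadjusted odds ratio (a*d)/(b*c) with a Woolf logit interval.

    Cells: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls. When any cell is zero, 0.5 is added to every
    cell (Haldane-Anscombe) so the estimate and interval stay finite.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("empty table margin")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, (math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se))


@dataclass
class AdjustedOrResult:
    odds_ratio: float
    ci: tuple[float, float]
    n_valid: int
    separation_flag: bool = False
    p_value: Optional[float] = None


def adjusted_or(
    df: pd.DataFrame,
    exposure: str,
    outcome: str = "chicap_diagnosis",
    covariates: Sequence[str] = ("age_years", "sex", "tumor_group"),
    level: float = 0.95,
) -> AdjustedOrResult:
    """Covariate-adjusted odds ratio for a binary exposure.

    Fits outcome ~ exposure + covariates by ML logistic regression (IRLS,
    tolerance 1e-8, up to 100 iterations). Rows with a missing exposure are
    dropped, reproducing per-criterion valid-N denominators. Categorical
    covariates (sex, tumor group) enter as two-level factors. Perfect or
    quasi-separation is flagged rather than raised; the CI is then reported
    as (0, inf).
    """
    import statsmodels.api as sm

    data = df[[outcome, exposure, *covariates]].dropna(subset=[exposure])
    n_valid = len(data)
    y = data[outcome].astype(float)
    X = pd.DataFrame(index=data.index)
    X["exposure"] = data[exposure].astype(float)
    for cov in covariates:
        col = data[cov]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.dropna().unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {cov} has >2 levels; recode upstream")
            X[cov] = (col == levels[-1]).astype(float)
        else:
            X[cov] = col.astype(float)
    X = sm.add_constant(X, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8
            )
        except Exception:
            return AdjustedOrResult(float("inf"), (0.0, float("inf")), n_valid, True)

    beta = fit.params["exposure"]
    se = fit.bse["exposure"]
    # diverging coefficient or exploding standard error => separation
    if not np.isfinite(se) or se > 50 or abs(beta) > 15:
        return AdjustedOrResult(
            math.exp(min(beta, 700)), (0.0, float("inf")), n_valid, True
        )
    z = sps.norm.ppf(1 - (1 - level) / 2)
    return AdjustedOrResult(
        odds_ratio=math.exp(beta),
        ci=(math.exp(beta - z * se), math.exp(beta + z * se)),
        n_valid=n_valid,
        separation_flag=False,
        p_value=float(fit.pvalues["exposure"]),
    )
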