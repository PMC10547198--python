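"""Per-class de novo mutation rates and case/control rate-ratio tests.

A cohort's mutation rate for a variant class is the number of observed de
novos divided by the cohort's summed haploid "callable" bases B (loci deep
and clean enough in all trio members to call a de novo).  Normalising by B
rather than by trio count guards against depth/quality differences between
sequencing batches.

Two Poisson rates x_case/B_case and x_ctrl/B_ctrl are compared with the exact
conditional test: given the total T = x_case + x_ctrl, the case count is
Binomial(T, p0) with p0 = B_case/(B_case+B_ctrl) under the null of equal
per-bp rates, and the one-sided p-value is the upper binomial tail.  The
default confidence interval for the rate ratio is the log-normal (Katz)
interval exp(ln RR +/- 1.96*sqrt(1/x_case + 1/x_ctrl)); an exact conditional
interval (inverted Clopper-Pearson on the binomial fraction) is available,
and is the reported interval when a zero cell makes the Katz interval
undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable
from .variants import DeNovoVariant, VariantClass, tabulate_counts

__all__ = [
    "ExomeConstants",
    "RateRatioResult",
    "BurdenRow",
    "mutation_rate",
    "per_individual_estimate",
    "rate_ratio_test",
    "burden_table",
    "TABLE_CLASSES",
]


@dataclass(frozen=True)
class ExomeConstants:
    """Reference coding-exome size used to scale per-bp rates to per-person.

    ``coding_exome_bp`` is the RefSeq hg19 coding exome; ``ploidy_factor`` 2
    converts the haploid per-bp rate to a diploid per-individual expectation.
    """

    coding_exome_bp: int = 33_828_798
    ploidy_factor: int = 2

    def __post_init__(self) -> None:
        if self.coding_exome_bp <= 0 or self.ploidy_factor <= 0:
            raise ValueError("exome constants must be positive")


@dataclass(frozen=True)
class RateRatioResult:
    rr: float
    ci_low: float
    ci_high: float
    p: float


def mutation_rate(x: float, B: float) -> float:
    """Per-bp de novo rate x/B; B is the summed haploid callable bases."""
    if B <= 0:
        raise ValueError(f"callable base total must be positive, got {B}")
    if x < 0:
        raise ValueError(f"count must be non-negative, got {x}")
    return x / B


def per_individual_estimate(rate: float, consts: ExomeConstants = ExomeConstants()) -> float:
    """Expected coding de novos per individual: rate x exome size x ploidy."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rate * consts.coding_exome_bp * consts.ploidy_factor


def _poisson_rate_ci(x: float, scale: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) CI for a Poisson mean x, returned on the x*scale scale."""
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else stats.chi2.ppf(alpha / 2, 2 * x) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (x + 1)) / 2
    return lo * scale, hi * scale


def rate_ci(x: float, B: float, level: float = 0.95) -> tuple[float, float]:
    """Exact 95% CI for the per-bp rate x/B."""
    return _poisson_rate_ci(x, 1.0 / B, level)


def _exact_conditional_ci(
    x_case: int, T: int, B_case: float, B_ctrl: float, level: float = 0.95
) -> tuple[float, float]:
    # Clopper-Pearson CI for the binomial fraction theta = x_case | T, then
    # invert theta = rr*B_case/(rr*B_case + B_ctrl) to the rate-ratio scale.
    alpha = 1.0 - level
    if x_case == 0:
        t_lo = 0.0
    else:
        t_lo = stats.beta.ppf(alpha / 2, x_case, T - x_case + 1)
    if x_case == T:
        t_hi = 1.0
    else:
        t_hi = stats.beta.ppf(1 - alpha / 2, x_case + 1, T - x_case)
    ratio = B_ctrl / B_case

    def to_rr(theta: float) -> float:
        if theta >= 1.0:
            return math.inf
        return theta / (1.0 - theta) * ratio

    return to_rr(t_lo), to_rr(t_hi)


def rate_ratio_test(
    x_case: int,
    B_case: float,
    x_ctrl: int,
    B_ctrl: float,
    alternative: str = "greater",
    ci_method: str = "log_normal",
    level: float = 0.95,
) -> RateRatioResult:
    """Exact conditional test of two Poisson rates.

    ``alternative='greater'`` tests for a higher case rate (the one-tailed
    direction of a case/control burden comparison).  With ``x_ctrl == 0`` the
    rate ratio is reported as ``inf`` and the exact conditional CI is used
    regardless of *ci_method*; division by zero never occurs.
    """
    if B_case <= 0 or B_ctrl <= 0:
        raise ValueError("callable base totals must be positive")
    if x_case < 0 or x_ctrl < 0:
        raise ValueError("counts must be non-negative")
    T = x_case + x_ctrl
    if T == 0:
        raise ValueError("x_case + x_ctrl must be positive")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if ci_method not in ("log_normal", "exact_conditional"):
        raise ValueError(f"unknown ci_method {ci_method!r}")

    p0 = B_case / (B_case + B_ctrl)
    if alternative == "greater":
        p = float(stats.binom.sf(x_case - 1, T, p0))
    elif alternative == "less":
        p = float(stats.binom.cdf(x_case, T, p0))
    else:
        lo = stats.binom.cdf(x_case, T, p0)
        hi = stats.binom.sf(x_case - 1, T, p0)
        p = float(min(1.0, 2.0 * min(lo, hi)))

    rate_case = x_case / B_case
    rate_ctrl = x_ctrl / B_ctrl
    rr = math.inf if x_ctrl == 0 else (rate_case / rate_ctrl if rate_ctrl > 0 else 0.0)

    if ci_method == "log_normal" and x_case > 0 and x_ctrl > 0:
        z = stats.norm.ppf(0.5 + level / 2)
        se = math.sqrt(1.0 / x_case + 1.0 / x_ctrl)
        ci_low = rr * math.exp(-z * se)
        ci_high = rr * math.exp(z * se)
    else:
        ci_low, ci_high = _exact_conditional_ci(x_case, T, B_case, B_ctrl, level)
    return RateRatioResult(rr=rr, ci_low=ci_low, ci_high=ci_high, p=p)


@dataclass(frozen=True)
class BurdenRow:
    variant_class: VariantClass
    x_case: int
    x_ctrl: int
    B_case: float
    B_ctrl: float
    rate_case: float
    rate_ctrl: float
    per_ind_case: float
    per_ind_ctrl: float
    rr: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool


#: Row order of a full burden table.
TABLE_CLASSES: tuple[VariantClass, ...] = (
    VariantClass.ALL,
    VariantClass.CODING,
    VariantClass.SYNONYMOUS,
    VariantClass.NONSYNONYMOUS,
    VariantClass.MISSENSE_ALL,
    VariantClass.MIS_D,
    VariantClass.MIS_P,
    VariantClass.MIS_B,
    VariantClass.LGD,
    VariantClass.DAMAGING,
    VariantClass.LGD_SNV,
    VariantClass.LGD_STOPGAIN,
    VariantClass.LGD_SPLICE,
    VariantClass.LGD_FRAMESHIFT,
    VariantClass.NONFRAMESHIFT,
    VariantClass.UNKNOWN,
)


def burden_table(
    case_vs: Sequence[DeNovoVariant],
    ctrl_vs: Sequence[DeNovoVariant],
    cohorts: CohortTable,
    consts: ExomeConstants = ExomeConstants(),
    alpha: float = 0.05,
    ci_method: str = "log_normal",
) -> list[BurdenRow]:
    """One burden row per variant class, cases vs controls.

    The "all" row uses the whole-capture callable totals; every coding class
    uses the coding callable totals.  Rows with one-sided p < *alpha* are
    flagged significant.
    """
    counts_case = tabulate_counts(case_vs)
    counts_ctrl = tabulate_counts(ctrl_vs)
    B = {
        "coding": (cohorts.callable_total("case", "coding"), cohorts.callable_total("control", "coding")),
        "all": (cohorts.callable_total("case", "all"), cohorts.callable_total("control", "all")),
    }
    for territory, (bc, bt) in B.items():
        if bc <= 0 or bt <= 0:
            raise ValueError(f"missing {territory} callable denominators in cohort table")

    rows: list[BurdenRow] = []
    for vc in TABLE_CLASSES:
        x_case, x_ctrl = counts_case[vc], counts_ctrl[vc]
        B_case, B_ctrl = B["all"] if vc is VariantClass.ALL else B["coding"]
        rate_case = mutation_rate(x_case, B_case)
        rate_ctrl = mutation_rate(x_ctrl, B_ctrl)
        if x_case + x_ctrl == 0:
            rr, ci_low, ci_high, p = (math.nan, math.nan, math.nan, 1.0)
        else:
            res = rate_ratio_test(x_case, B_case, x_ctrl, B_ctrl, ci_method=ci_method)
            rr, ci_low, ci_high, p = res.rr, res.ci_low, res.ci_high, res.p
        rows.append(
            BurdenRow(
                variant_class=vc,
                x_case=x_case,
                x_ctrl=x_ctrl,
                B_case=B_case,
                B_ctrl=B_ctrl,
                rate_case=rate_case,
                rate_ctrl=rate_ctrl,
                per_ind_case=per_individual_estimate(rate_case, consts),
                per_ind_ctrl=per_individual_estimate(rate_ctrl, consts),
                rr=rr,
                ci_low=ci_low,
                ci_high=ci_high,
                p=p,
                significant=bool(p < alpha),
            )
        )
    return rows


def burden_frame(rows: Sequence[BurdenRow]) -> pd.DataFrame:
    """Burden rows as a DataFrame (TSV/JSON-ready)."""
    return pd.DataFrame(
        [
            {
                "variant_class": r.variant_class.value,
                "x_case": r.x_case,
                "x_ctrl": r.x_ctrl,
                "rate_case": r.rate_case,
                "rate_ctrl": r.rate_ctrl,
                "per_ind_case": r.per_ind_case,
                "per_ind_ctrl": r.per_ind_ctrl,
                "rr": r.rr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
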