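"""Rates, per-individual estimates and the exact conditional rate-ratio test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from denovostat.burden import (
    ExomeConstants,
    burden_frame,
    burden_table,
    mutation_rate,
    per_individual_estimate,
    rate_ratio_test,
)
from denovostat.io import CohortTable
from denovostat.variants import DeNovoVariant, Effect, VariantClass

import pandas as pd

# callable exposures recovered from the coding row of the observed study
# table: count / printed per-bp rate
B_CASE = 128 / 2.02e-8
B_CTRL = 628 / 1.74e-8


class TestMutationRate:
    def test_observed_study_rates(self):
        assert mutation_rate(12, B_CASE) == pytest.approx(0.19e-8, rel=0.02)
        assert mutation_rate(628, B_CTRL) == pytest.approx(1.74e-8, rel=1e-12)
        assert mutation_rate(0, 1e9) == 0.0

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            mutation_rate(1, 0)


class TestPerIndividual:
    def test_observed_study_values(self):
        assert per_individual_estimate(2.02e-8) == pytest.approx(1.37, abs=0.005)
        assert per_individual_estimate(1.91e-8) == pytest.approx(1.29, abs=0.005)
        assert per_individual_estimate(0.0) == 0.0

    def test_ploidy_factor_configurable(self):
        haploid = ExomeConstants(ploidy_factor=1)
        assert per_individual_estimate(2.02e-8, haploid) == pytest.approx(1.37 / 2, abs=0.005)


def exact_upper_tail(x_case: int, T: int, B_case: float, B_ctrl: float) -> float:
    """Independent oracle: exact-rational conditional binomial tail."""
    p0 = Fraction(B_case) / Fraction(B_case + B_ctrl)
    total = sum(
        Fraction(math.comb(T, k)) * p0**k * (1 - p0) ** (T - k) for k in range(x_case, T + 1)
    )
    return float(total)


class TestRateRatioTest:
    def test_reproduces_observed_lgd_and_damaging(self):
        r = rate_ratio_test(12, B_CASE, 35, B_CTRL)
        assert r.rr == pytest.approx(1.95, abs=0.005)
        assert round(r.p, 2) == 0.04
        r = rate_ratio_test(54, B_CASE, 225, B_CTRL)
        assert r.rr == pytest.approx(1.37, abs=0.005)
        assert round(r.p, 2) == 0.03

    def test_symmetric_counts_give_p_0588(self):
        # P(X >= 10), X ~ Bin(20, 1/2) = (1 + C(20,10)/2^20)/2
        r = rate_ratio_test(10, 1e9, 10, 1e9)
        expected = float((1 + Fraction(math.comb(20, 10), 2**20)) / 2)
        assert r.rr == 1.0
        assert r.p == pytest.approx(expected, rel=1e-12)
        assert round(r.p, 3) == 0.588

    def test_zero_case_count(self):
        r = rate_ratio_test(0, 1e9, 5, 1e9)
        assert r.rr == 0.0 and r.p == 1.0

    def test_zero_control_count_reports_inf_with_exact_ci(self):
        r = rate_ratio_test(4, 1e9, 0, 1e9)
        assert math.isinf(r.rr)
        assert r.ci_low > 0 and math.isfinite(r.ci_low)

    @pytest.mark.parametrize("x_case,x_ctrl,ratio", [(3, 7, 2.0), (0, 5, 1.0), (9, 2, 0.5), (15, 15, 1.0)])
    def test_matches_exact_enumeration(self, x_case, x_ctrl, ratio):
        B_case, B_ctrl = 1e9, ratio * 1e9
        r = rate_ratio_test(x_case, B_case, x_ctrl, B_ctrl)
        assert r.p == pytest.approx(exact_upper_tail(x_case, x_case + x_ctrl, B_case, B_ctrl), rel=1e-10)

    def test_scale_invariance(self):
        a = rate_ratio_test(12, B_CASE, 35, B_CTRL)
        b = rate_ratio_test(12, 7.5 * B_CASE, 35, 7.5 * B_CTRL)
        assert b.rr == pytest.approx(a.rr, rel=1e-12)
        assert b.p == pytest.approx(a.p, rel=1e-12)

    def test_null_pvalues_are_uniform_after_discreteness_adjustment(self):
        """Randomised (discrete-adjusted) p-values under H0 pass a KS test."""
        rng = np.random.default_rng(5)
        B = 1e9
        lam = 20.0
        n = 1500
        x_case = rng.poisson(lam, n)
        x_ctrl = rng.poisson(lam, n)
        keep = (x_case + x_ctrl) > 0
        x_case, x_ctrl = x_case[keep], x_ctrl[keep]
        T = x_case + x_ctrl
        # randomised version of the exact tail: strictly-greater tail + U * P(X = x)
        p_hi = stats.binom.sf(x_case, T, 0.5)
        pmf = stats.binom.pmf(x_case, T, 0.5)
        u = rng.random(len(T))
        p_rand = p_hi + u * pmf
        assert stats.kstest(p_rand, "uniform").pvalue > 0.01
        # and the reported (conservative) p-values are super-uniform
        p_rep = stats.binom.sf(x_case - 1, T, 0.5)
        for alpha in (0.05, 0.2, 0.5):
            assert (p_rep <= alpha).mean() <= alpha + 0.02


def _trio_frame(n_case, n_ctrl, b_case, b_ctrl):
    rows = [
        {"trio_id": f"ca{i}", "phenotype": "case", "callable_bp": b_case} for i in range(n_case)
    ] + [
        {"trio_id": f"co{i}", "phenotype": "control", "callable_bp": b_ctrl} for i in range(n_ctrl)
    ]
    return CohortTable(pd.DataFrame(rows))


def test_burden_table_symmetry_and_shape():
    """Identical case/control streams with equal exposure give RR 1 everywhere."""
    def stream(cohort):
        return [
            DeNovoVariant(f"{cohort}{i}", cohort, f"G{i}", e, s, None)
            for i, (e, s) in enumerate(
                [(Effect.STOPGAIN, None), (Effect.MISSENSE_SNV, 0.99), (Effect.SYNONYMOUS_SNV, None)]
            )
        ]

    cohorts = _trio_frame(10, 10, 10**7, 10**7)
    rows = burden_table(stream("case"), stream("control"), cohorts)
    assert len(rows) == 16
    df = burden_frame(rows)
    occupied = df[df.x_case > 0]
    assert (occupied.rr == 1.0).all()
    # identical data cannot be significant
    assert not df.significant.any()
    lgd_row = df.set_index("variant_class").loc["lgd"]
    assert lgd_row.x_case == 1 and lgd_row.x_ctrl == 1
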