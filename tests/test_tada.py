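"""Bayes factors, direct-posterior FDR and the gene-level test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from denovostat.io import MutationRateTable
from denovostat.tada import (
    TadaParams,
    class_bayes_factor,
    direct_posterior_fdr,
    estimate_gamma_from_burden,
    gene_bayes_factor,
    null_pvalues,
    results_frame,
    run_tada,
)
from denovostat.variants import DeNovoVariant, Effect


def quadrature_bf(x: int, q0: float, gamma_bar: float, beta: float) -> float:
    """Oracle: marginal Poisson-Gamma likelihood by numerical integration."""
    shape = gamma_bar * beta

    def integrand(g):
        return stats.poisson.pmf(x, q0 * g) * stats.gamma.pdf(g, a=shape, scale=1.0 / beta)

    upper = stats.gamma.ppf(1 - 1e-12, a=shape, scale=1.0 / beta)
    marginal, _ = integrate.quad(integrand, 0, upper, limit=400, epsabs=0, epsrel=1e-10)
    return marginal / stats.poisson.pmf(x, q0)


class TestClassBayesFactor:
    def test_worked_example(self):
        # x=2, q0=0.01 (N=1, mu=0.005), gamma_bar=20, beta=1
        assert class_bayes_factor(2, 1, 0.005, 20, 1) == pytest.approx(340.8, abs=0.1)

    @pytest.mark.parametrize("x", range(6))
    @pytest.mark.parametrize("q0", [1e-4, 1e-3, 1e-2, 1e-1])
    @pytest.mark.parametrize("gamma_bar,beta", [(1, 1), (5, 0.5), (20, 1), (50, 2)])
    def test_matches_quadrature_oracle(self, x, q0, gamma_bar, beta):
        got = class_bayes_factor(x, 1, q0 / 2, gamma_bar, beta)
        assert got == pytest.approx(quadrature_bf(x, q0, gamma_bar, beta), rel=1e-6)

    def test_degenerate_prior_gives_bf_one(self):
        # gamma_bar = 1 with large beta concentrates the prior at relative risk 1
        assert class_bayes_factor(3, 100, 1e-5, 1.0, 1e6) == pytest.approx(1.0, abs=1e-4)

    def test_no_data_limit(self):
        bf = class_bayes_factor(0, 100, 1e-6, 20, 1)
        assert bf < 1.0
        tiny = class_bayes_factor(0, 100, 1e-12, 20, 1)
        assert tiny == pytest.approx(1.0, abs=1e-6)

    def test_monotone_increasing_in_x(self):
        bfs = [class_bayes_factor(x, 118, 2e-6, 20, 1) for x in range(8)]
        assert all(b > a for a, b in zip(bfs, bfs[1:]))

    def test_zero_rate_with_hits_is_error(self):
        with pytest.raises(ValueError, match="rate table"):
            class_bayes_factor(1, 118, 0.0, 20, 1)


def test_gene_bayes_factor_is_product():
    params = TadaParams(n_trios=118, gamma_bar_lgd=20, gamma_bar_misd=5)
    bf_l, bf_m, bf_t = gene_bayes_factor(2, 1, 2e-6, 5e-6, params)
    assert bf_t == pytest.approx(bf_l * bf_m, rel=1e-12)
    # both observations empty at tiny rates: uninformative
    _, _, bf0 = gene_bayes_factor(0, 0, 1e-12, 1e-12, params)
    assert bf0 == pytest.approx(1.0, abs=1e-6)


class TestDirectPosteriorFdr:
    def test_hand_worked_example(self):
        # pi=0.5, BFs {9, 1} -> posteriors {0.9, 0.5} -> q {0.1, 0.3}
        post, q = direct_posterior_fdr([9.0, 1.0], pi=0.5)
        np.testing.assert_allclose(post, [0.9, 0.5])
        np.testing.assert_allclose(q, [0.1, 0.3])

    def test_all_equal_bfs_share_q(self):
        _, q = direct_posterior_fdr([2.0, 2.0, 2.0], pi=0.1)
        assert len(set(np.round(q, 12))) == 1

    def test_rank1_q_is_one_minus_max_posterior(self):
        rng = np.random.default_rng(0)
        bfs = rng.lognormal(0, 2, 50)
        post, q = direct_posterior_fdr(bfs, pi=0.05)
        assert q[np.argmax(bfs)] == pytest.approx(1 - post.max(), rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1e6), min_size=1, max_size=40), st.floats(0.001, 0.5))
    def test_q_nondecreasing_along_ranking_and_order_invariant(self, bfs, pi):
        bfs = np.asarray(bfs)
        _, q = direct_posterior_fdr(bfs, pi)
        order = np.argsort(-bfs, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = np.random.default_rng(1).permutation(len(bfs))
        _, q2 = direct_posterior_fdr(bfs[perm], pi)
        np.testing.assert_allclose(q2, q[perm], rtol=1e-12)


class TestGammaFromBurden:
    def test_no_excess_floors_at_one(self):
        assert estimate_gamma_from_burden(5.0, 5.0, 100, 10000) == 1.0
        assert estimate_gamma_from_burden(2.0, 5.0, 100, 10000) == 1.0

    def test_plugin_arithmetic(self):
        # doubling the expectation across 1% of genes: 1 + E0*G/(E0*k) = 101
        assert estimate_gamma_from_burden(10.0, 5.0, 100, 10000) == pytest.approx(101.0)

    def test_study_scale_value(self):
        got = estimate_gamma_from_burden(12, 6.15, 184, 18665)
        assert got == pytest.approx(97, abs=1.0)

    def test_zero_k_rejected(self):
        with pytest.raises(ValueError):
            estimate_gamma_from_burden(10, 5, 0, 100)


def _mini_rates(G=400, mu_lgd=2e-6, mu_misd=5e-6, seed=0):
    rng = np.random.default_rng(seed)
    scale = rng.lognormal(0, 0.5, G)
    return MutationRateTable(
        genes=np.array([f"G{i:04d}" for i in range(G)], dtype=object),
        mu_total=10 * (mu_lgd + mu_misd) * scale,
        mu_lgd=mu_lgd * scale,
        mu_misd=mu_misd * scale,
    )


class TestNullPvalues:
    def test_all_zero_counts_give_p_near_one(self):
        rates = _mini_rates()
        params = TadaParams(n_trios=50, gamma_bar_lgd=20, gamma_bar_misd=5, n_null_sims=200, seed=3)
        from denovostat.tada import log_class_bayes_factor

        lb = log_class_bayes_factor(np.zeros(rates.n_genes), 2 * 50 * rates.mu_lgd, 20, 1)
        lb = lb + log_class_bayes_factor(np.zeros(rates.n_genes), 2 * 50 * rates.mu_misd, 5, 1)
        # per-gene null: a zero-count gene can never beat its own null draws
        p = null_pvalues(lb, rates, params, pooled=False)
        assert (p == 1.0).all()

    def test_planted_two_hit_gene_has_tiny_p(self):
        rates = _mini_rates()
        params = TadaParams(n_trios=50, gamma_bar_lgd=20, gamma_bar_misd=5, n_null_sims=300, seed=4)
        from denovostat.tada import log_class_bayes_factor

        x = np.zeros(rates.n_genes)
        x[7] = 2  # two LGD hits at q0 ~ 1e-3: null tail ~ Poisson P(X>=2) ~ 5e-7
        lb = log_class_bayes_factor(x, 2 * 50 * rates.mu_lgd, 20, 1)
        lb = lb + log_class_bayes_factor(np.zeros(rates.n_genes), 2 * 50 * rates.mu_misd, 5, 1)
        p = null_pvalues(lb, rates, params)
        assert p[7] < 1e-3  # pooled null: far below 1/(n_sims+1) per-gene resolution


def _variant(gene, effect, score=None, proband="p1"):
    return DeNovoVariant(proband, "case", gene, effect, score, None)


class TestRunTada:
    def test_doubly_hit_gene_is_unique_high_confidence(self, pcms_rates, pcms_config):
        """A two-LGD-hit gene (the KDM5B pattern) is the only q<0.1 gene."""
        target = str(pcms_rates.genes[1000])
        variants = [
            _variant(target, Effect.STOPGAIN, proband="p1"),
            _variant(target, Effect.STOPGAIN, proband="p2"),
        ]
        # 50 scattered singleton damaging hits
        for i in range(50):
            variants.append(_variant(str(pcms_rates.genes[2000 + 37 * i]), Effect.MISSENSE_SNV, 0.99, f"s{i}"))
        params = TadaParams(
            n_trios=118,
            gamma_bar_lgd=pcms_config.gamma_bar_lgd,
            gamma_bar_misd=pcms_config.gamma_bar_misd,
            pi=184 / pcms_rates.n_genes,
        )
        results, skipped = run_tada(variants, pcms_rates, params)
        assert skipped == []
        df = results_frame(results)
        hc = df.loc[df.qval < 0.1, "gene"].tolist()
        assert hc == [target]

    def test_no_variants_flags_nothing(self, small_rates):
        params = TadaParams(n_trios=10, gamma_bar_lgd=20, gamma_bar_misd=5, pi=0.1)
        results, _ = run_tada([], small_rates, params)
        df = results_frame(results)
        assert not df.high_confidence.any()

    def test_unknown_gene_goes_to_skip_report(self, small_rates):
        params = TadaParams(n_trios=10, gamma_bar_lgd=20, gamma_bar_misd=5, pi=0.1)
        _, skipped = run_tada([_variant("NOT_A_GENE", Effect.STOPGAIN)], small_rates, params)
        assert skipped == ["NOT_A_GENE"]

    def test_larger_pi_weakly_decreases_every_q(self, small_rates):
        variants = [_variant("A", Effect.STOPGAIN), _variant("B", Effect.MISSENSE_SNV, 0.99)]
        qs = {}
        for pi in (0.05, 0.1):
            params = TadaParams(n_trios=10, gamma_bar_lgd=20, gamma_bar_misd=5, pi=pi)
            results, _ = run_tada(variants, small_rates, params)
            qs[pi] = np.array([r.q for r in results])
        assert (qs[0.1] <= qs[0.05] + 1e-12).all()
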