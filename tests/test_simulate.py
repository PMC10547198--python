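"""The synthetic cohort generator: calibration, determinism, planted signal."""

import numpy as np
import pytest

from denovostat.burden import ExomeConstants, burden_frame, burden_table
from denovostat.simulate import (
    ScenarioConfig,
    make_disorder_like_set,
    make_gene_sets,
    make_rate_table,
    pcms_like_config,
    simulate_trio_cohort,
)
from denovostat.variants import VariantClass, frequency_filter, is_damaging, tabulate_counts


class TestMakeRateTable:
    def test_calibration_to_per_individual_targets(self):
        cfg = ScenarioConfig(seed=3)
        t = make_rate_table(cfg)
        assert 2 * t.mu_total.sum() == pytest.approx(1.18, rel=1e-9)
        assert 2 * t.mu_damaging.sum() == pytest.approx(0.42, rel=0.02)

    def test_deterministic_given_seed(self):
        a = make_rate_table(ScenarioConfig(seed=5))
        b = make_rate_table(ScenarioConfig(seed=5))
        np.testing.assert_array_equal(a.mu_total, b.mu_total)

    def test_target_rescaling(self):
        # doubling the per-individual target doubles the summed rates
        lo = make_rate_table(ScenarioConfig(seed=5))
        hi = make_rate_table(ScenarioConfig(seed=5, coding_per_individual=2.36))
        assert hi.mu_total.sum() == pytest.approx(2 * lo.mu_total.sum(), rel=1e-9)


class TestSimulateTrioCohort:
    def test_null_cohort_recovers_calibrated_per_individual_rate(self):
        """Control coding per-individual estimate lands on the 1.18 target."""
        cfg = ScenarioConfig(seed=7, N_case=5, N_ctrl=750)
        rng = np.random.default_rng(7)
        rates = make_rate_table(cfg, rng)
        sim = simulate_trio_cohort(cfg, rates, rng)
        vs = frequency_filter(sim.variants)
        counts = tabulate_counts(vs, cohort="control")
        B = sim.cohorts.callable_total("control")
        per_ind = counts[VariantClass.CODING] / B * ExomeConstants().coding_exome_bp * 2
        lam = 750 * 1.18 * cfg.exposure_ctrl()  # expected raw count
        se_scale = 3 * np.sqrt(lam) / lam  # 3 SE on the Poisson total, relative
        assert per_ind == pytest.approx(1.18, rel=se_scale)

    def test_null_scenario_burden_is_flat(self):
        cfg = ScenarioConfig(seed=11, N_case=300, N_ctrl=300,
                             callable_mean_case=4.8e7, callable_mean_ctrl=4.8e7)
        rng = np.random.default_rng(11)
        rates = make_rate_table(cfg, rng)
        sim = simulate_trio_cohort(cfg, rates, rng)
        vs = frequency_filter(sim.variants)
        case = [v for v in vs if v.cohort == "case"]
        ctrl = [v for v in vs if v.cohort == "control"]
        df = burden_frame(burden_table(case, ctrl, sim.cohorts))
        coding_rr = df.set_index("variant_class").loc["coding", "rr"]
        assert coding_rr == pytest.approx(1.0, abs=0.2)

    def test_pcms_preset_damaging_burden_and_recurrence(self):
        """The case-cohort preset yields ~54 damaging hits and recurrent genes."""
        n_dmg, n_with_recurrence = [], 0
        for seed in range(6):
            cfg = pcms_like_config(seed)
            rng = np.random.default_rng(seed)
            rates = make_rate_table(cfg, rng)
            sim = simulate_trio_cohort(cfg, rates, rng)
            case_dmg = [v for v in frequency_filter(sim.variants)
                        if v.cohort == "case" and is_damaging(v)]
            n_dmg.append(len(case_dmg))
            genes = [v.gene for v in case_dmg]
            if len(genes) != len(set(genes)):
                n_with_recurrence += 1
        assert abs(np.mean(n_dmg) - 54) < 3 * np.sqrt(54 / len(n_dmg))
        assert n_with_recurrence >= len(n_dmg) / 2  # majority of seeds

    def test_common_variant_fraction_exercises_filter(self):
        cfg = ScenarioConfig(seed=13, N_case=50, N_ctrl=50, freq_common_fraction=0.2)
        rng = np.random.default_rng(13)
        rates = make_rate_table(cfg, rng)
        sim = simulate_trio_cohort(cfg, rates, rng)
        kept = frequency_filter(sim.variants)
        frac_removed = 1 - len(kept) / len(sim.variants)
        assert frac_removed == pytest.approx(0.2, abs=0.08)

    def test_all_randomness_flows_from_seed(self):
        def build(seed):
            cfg = pcms_like_config(seed)
            rng = np.random.default_rng(seed)
            rates = make_rate_table(cfg, rng)
            return simulate_trio_cohort(cfg, rates, rng)

        a, b = build(21), build(21)
        assert a.variants == b.variants
        assert a.risk_genes.genes == b.risk_genes.genes


class TestGeneSets:
    def test_sizes_and_overlap_control(self, pcms_config, pcms_rates, pcms_cohort):
        rng = np.random.default_rng(0)
        sets = make_gene_sets(pcms_config, pcms_rates, pcms_cohort.risk_genes,
                              sizes=[50, 120], overlap_with_risk=0.4, rng=rng)
        assert [len(s) for s in sets] == [50, 120]
        risk = pcms_cohort.risk_genes.genes
        for s, size in zip(sets, (50, 120)):
            assert len(s.genes & risk) == round(0.4 * size)

    def test_zero_and_full_overlap(self, pcms_config, pcms_rates, pcms_cohort):
        rng = np.random.default_rng(1)
        (none,) = make_gene_sets(pcms_config, pcms_rates, pcms_cohort.risk_genes,
                                 sizes=[80], overlap_with_risk=0.0, rng=rng)
        (full,) = make_gene_sets(pcms_config, pcms_rates, pcms_cohort.risk_genes,
                                 sizes=[80], overlap_with_risk=1.0, rng=rng)
        risk = pcms_cohort.risk_genes.genes
        assert not none.genes & risk
        assert full.genes <= risk

    def test_disorder_like_set_hits_target_share(self, pcms_rates):
        rng = np.random.default_rng(2)
        weights = {str(g): float(w) for g, w in zip(pcms_rates.genes, pcms_rates.mu_damaging)}
        hit = [str(g) for g in pcms_rates.genes[:4]]
        gs = make_disorder_like_set("td_like", hit, weights, target_fold=4.5,
                                    n_mutations=54, rng=rng)
        total = sum(weights.values())
        share = sum(weights[g] for g in gs.genes) / total
        assert share == pytest.approx(4 / (4.5 * 54), rel=0.02)
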