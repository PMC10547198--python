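"""Synthetic trio cohorts, rate tables and gene sets for the full pipeline.

The generator produces every input the analysis consumes, with the
statistical structure the analysis assumes:

* a per-gene mutation-rate table with lognormal rate heterogeneity,
  calibrated so the cohort-level expected coding de novos per individual
  matches a target (default 1.18, a typical control-trio value);
* trio cohorts in which each trio's callable territory enters as an exposure
  multiplier on the per-gene rates, per-gene class counts are Poisson, and a
  planted set of k risk genes carries elevated relative risks for the LGD and
  damaging-missense classes;
* ANNOVAR-style variant rows (effect strings, PolyPhen2-HDIV scores drawn to
  match the missense sub-class proportions, a configurable fraction of
  common-population variants to exercise the frequency filter);
* gene sets with controlled overlap against the planted risk genes, for
  enrichment power experiments.

A ``pcms_like`` preset reproduces the study conditions of a small
stereotypy case cohort against a large control cohort: 118 case and 750
control trios, ~54 damaging case de novos, and typically at least one
recurrently hit gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .burden import ExomeConstants
from .io import CohortTable, MutationRateTable
from .tada import estimate_gamma_from_burden
from .variants import DeNovoVariant, Effect, GeneSet

__all__ = [
    "ScenarioConfig",
    "SimulatedCohort",
    "make_rate_table",
    "simulate_trio_cohort",
    "make_gene_sets",
    "make_disorder_like_set",
    "pcms_like_config",
]

_EXOME = ExomeConstants()

# class composition of coding de novos outside the LGD / Mis-D classes,
# as fractions of the coding total (anchored to large control-cohort data)
_FRAC_SYNONYMOUS = 171 / 628
_FRAC_MIS_P = 79 / 628
_FRAC_MIS_B = 137 / 628
_FRAC_MIS_NOSCORE = 5 / 628
_FRAC_NONFRAMESHIFT = 3 / 628
_FRAC_UNKNOWN = 8 / 628
# noncoding de novos on the capture, relative to the coding total
_FRAC_NONCODING_EXTRA = (666 - 628) / 628
# split of LGD variants into stopgain / splice / frameshift
_LGD_SPLIT = (16 / 35, 3 / 35, 16 / 35)


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of one synthetic study scenario.

    Rates: per-gene total coding rates are lognormal with spread
    ``rate_log_sd`` (in natural-log units), rescaled so the expected coding
    de novos per fully-callable individual is ``coding_per_individual``;
    ``f_lgd`` / ``f_misd`` are the LGD and damaging-missense fractions of
    each gene's coding rate.  Cohorts: per-trio haploid callable coding bases
    are Normal(mean, sd) and act as exposure multipliers
    callable/(2 * coding exome).  Signal: ``k_true`` risk genes drawn
    uniformly carry relative risks ``gamma_bar_lgd`` / ``gamma_bar_misd`` in
    case trios.  ``freq_common_fraction`` of generated variants are given a
    population frequency above the 0.001 filter.
    """

    G: int = 18_665
    N_case: int = 118
    N_ctrl: int = 750
    k_true: int = 184
    gamma_bar_lgd: float = 1.0
    gamma_bar_misd: float = 1.0
    rate_log_sd: float = 1.0
    coding_per_individual: float = 1.18
    f_lgd: float = 0.06
    f_misd: float = 0.30
    callable_mean_case: float = 5.370e7
    callable_mean_ctrl: float = 4.812e7
    callable_sd: float = 3.0e6
    freq_common_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.k_true <= self.G):
            raise ValueError("need 0 < k_true <= G")
        if self.gamma_bar_lgd < 1 or self.gamma_bar_misd < 1:
            raise ValueError("relative risks must be >= 1")
        if self.f_lgd + self.f_misd > 1:
            raise ValueError("class split fractions must sum to <= 1")
        if not (0 <= self.freq_common_fraction < 1):
            raise ValueError("freq_common_fraction must be in [0, 1)")
        for v in (self.N_case, self.N_ctrl, self.callable_mean_case, self.callable_mean_ctrl):
            if v <= 0:
                raise ValueError("cohort sizes and callable means must be positive")

    def exposure_case(self) -> float:
        return self.callable_mean_case / (self.exome_haploid_pair())

    def exposure_ctrl(self) -> float:
        return self.callable_mean_ctrl / (self.exome_haploid_pair())

    @staticmethod
    def exome_haploid_pair() -> float:
        return float(_EXOME.coding_exome_bp * _EXOME.ploidy_factor)


def make_rate_table(config: ScenarioConfig, rng: Optional[np.random.Generator] = None) -> MutationRateTable:
    """Lognormal per-gene rate table calibrated to the scenario's coding burden."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    raw = rng.lognormal(mean=0.0, sigma=config.rate_log_sd, size=config.G)
    target_sum = config.coding_per_individual / 2.0  # sum of haploid per-gene rates
    mu_total = raw * (target_sum / raw.sum())
    genes = np.array([f"G{i:05d}" for i in range(config.G)], dtype=object)
    return MutationRateTable(
        genes=genes,
        mu_total=mu_total,
        mu_lgd=config.f_lgd * mu_total,
        mu_misd=config.f_misd * mu_total,
    )


@dataclass
class SimulatedCohort:
    """Output of one cohort simulation: variants, trios and the planted truth."""

    variants: list[DeNovoVariant]
    cohorts: CohortTable
    risk_genes: GeneSet


def _materialize(
    rng: np.random.Generator,
    cohort: str,
    trio_ids: np.ndarray,
    gene_names: np.ndarray,
    counts_per_trio: np.ndarray,
    gene_p: np.ndarray,
    effect_kind: str,
    common: bool,
    out: list,
) -> None:
    total = int(counts_per_trio.sum())
    if total == 0:
        return
    trios = np.repeat(trio_ids, counts_per_trio)
    gidx = rng.choice(len(gene_p), size=total, p=gene_p)
    for t, gi in zip(trios, gidx):
        if effect_kind == "lgd":
            u = rng.random()
            if u < _LGD_SPLIT[0]:
                effect, score = Effect.STOPGAIN, None
            elif u < _LGD_SPLIT[0] + _LGD_SPLIT[1]:
                effect, score = Effect.SPLICE_SITE, None
            else:
                effect, score = Effect.FRAMESHIFT_INDEL, None
        elif effect_kind == "misd":
            effect, score = Effect.MISSENSE_SNV, rng.uniform(0.957, 1.0)
        elif effect_kind == "misp":
            effect, score = Effect.MISSENSE_SNV, rng.uniform(0.453, 0.957)
        elif effect_kind == "misb":
            effect, score = Effect.MISSENSE_SNV, rng.uniform(0.0, 0.453)
        elif effect_kind == "mis_noscore":
            effect, score = Effect.MISSENSE_SNV, None
        elif effect_kind == "synonymous":
            effect, score = Effect.SYNONYMOUS_SNV, None
        elif effect_kind == "nonframeshift":
            effect, score = Effect.NONFRAMESHIFT_INDEL, None
        elif effect_kind == "unknown":
            effect, score = Effect.UNKNOWN, None
        else:
            effect, score = Effect.NONCODING, None
        if common:
            freq = float(rng.uniform(0.001, 0.05))
        else:
            # most confirmed de novos are absent from population databases
            freq = None if rng.random() < 0.9 else float(rng.uniform(0.0, 0.0009))
        out.append(
            DeNovoVariant(
                proband_id=f"{t}-03",
                cohort=cohort,
                gene=str(gene_names[gi]),
                effect=effect,
                polyphen_hdiv=None if score is None else float(score),
                pop_freq=freq,
            )
        )


def simulate_trio_cohort(
    config: ScenarioConfig,
    rates: Optional[MutationRateTable] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCohort:
    """Simulate case and control trio cohorts under the scenario.

    Per trio, callable bases come from the callable model and scale all
    per-gene rates via the exposure multiplier callable/(2 * coding exome).
    Class counts are Poisson; in case trios the planted risk genes carry the
    configured relative risks for the LGD and damaging-missense classes.
    On top of the rare (calibrated) variants, extra common-population
    variants are added so that a ``freq_common_fraction`` share of all rows
    fails the 0.001 frequency filter.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if rates is None:
        rates = make_rate_table(config, rng)
    if rates.n_genes != config.G:
        raise ValueError("rate table size does not match config.G")

    risk_idx = rng.choice(config.G, size=config.k_true, replace=False)
    risk_mask = np.zeros(config.G, dtype=bool)
    risk_mask[risk_idx] = True

    mu_total = rates.mu_total
    sum_total = mu_total.sum()
    class_plan = [
        # (kind, per-gene base weights, summed class rate)
        ("synonymous", mu_total, _FRAC_SYNONYMOUS * sum_total),
        ("misp", mu_total, _FRAC_MIS_P * sum_total),
        ("misb", mu_total, _FRAC_MIS_B * sum_total),
        ("mis_noscore", mu_total, _FRAC_MIS_NOSCORE * sum_total),
        ("nonframeshift", mu_total, _FRAC_NONFRAMESHIFT * sum_total),
        ("unknown", mu_total, _FRAC_UNKNOWN * sum_total),
        ("noncoding", mu_total, _FRAC_NONCODING_EXTRA * sum_total),
    ]

    variants: list[DeNovoVariant] = []
    trio_rows = []
    fcf = config.freq_common_fraction
    common_factor = fcf / (1.0 - fcf) if fcf > 0 else 0.0

    for cohort, N, cmean in (
        ("case", config.N_case, config.callable_mean_case),
        ("control", config.N_ctrl, config.callable_mean_ctrl),
    ):
        callable_bp = np.maximum(
            rng.normal(cmean, config.callable_sd, size=N), 0.1 * cmean
        ).round()
        exposure = callable_bp / config.exome_haploid_pair()
        trio_ids = np.array([f"{cohort[:4]}{i:04d}" for i in range(N)], dtype=object)
        for tid, cb in zip(trio_ids, callable_bp):
            trio_rows.append(
                {"trio_id": tid, "phenotype": cohort, "callable_bp": int(cb)}
            )

        # class-specific per-gene rates, gamma-elevated in case risk genes
        g_l = config.gamma_bar_lgd if cohort == "case" else 1.0
        g_m = config.gamma_bar_misd if cohort == "case" else 1.0
        w_lgd = rates.mu_lgd * np.where(risk_mask, g_l, 1.0)
        w_misd = rates.mu_misd * np.where(risk_mask, g_m, 1.0)
        plan = class_plan + [("lgd", w_lgd, w_lgd.sum()), ("misd", w_misd, w_misd.sum())]

        for kind, w, S in plan:
            lam = 2.0 * exposure * S
            counts = rng.poisson(lam)
            _materialize(
                rng, cohort, trio_ids, rates.genes, counts, w / w.sum(), kind, False, variants
            )
            if common_factor > 0:
                counts_c = rng.poisson(lam * common_factor)
                _materialize(
                    rng, cohort, trio_ids, rates.genes, counts_c, w / w.sum(), kind, True, variants
                )

    cohorts = CohortTable(pd.DataFrame(trio_rows))
    risk_genes = GeneSet(name="planted_risk", genes=frozenset(rates.genes[risk_idx]))
    return SimulatedCohort(variants=variants, cohorts=cohorts, risk_genes=risk_genes)


def make_gene_sets(
    config: ScenarioConfig,
    rates: MutationRateTable,
    risk_genes: GeneSet,
    sizes: Sequence[int],
    overlap_with_risk: float,
    rng: Optional[np.random.Generator] = None,
) -> list[GeneSet]:
    """Gene sets of the requested sizes with controlled risk-gene overlap.

    Each set draws ``round(size * overlap_with_risk)`` members from the
    planted risk genes and the remainder from the non-risk universe.
    """
    if not (0.0 <= overlap_with_risk <= 1.0):
        raise ValueError("overlap_with_risk must be in [0, 1]")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    risk = np.asarray(sorted(risk_genes.genes), dtype=object)
    non_risk = np.asarray(sorted(set(map(str, rates.genes)) - set(risk)), dtype=object)
    out = []
    for j, size in enumerate(sizes):
        n_risk = min(int(round(size * overlap_with_risk)), len(risk))
        n_other = size - n_risk
        members = np.concatenate(
            [
                rng.choice(risk, size=n_risk, replace=False),
                rng.choice(non_risk, size=n_other, replace=False),
            ]
        )
        out.append(GeneSet(name=f"set{j}_ov{overlap_with_risk:g}", genes=frozenset(members)))
    return out


def make_disorder_like_set(
    name: str,
    hit_genes: Sequence[str],
    weights: dict,
    target_fold: float,
    n_mutations: int,
    rng: np.random.Generator,
    observed: Optional[int] = None,
    exclude: Optional[Sequence[str]] = None,
) -> GeneSet:
    """Synthetic stand-in for a curated disorder gene list.

    Builds a set containing the given mutated genes (the overlap actually
    observed) padded with unmutated genes until the set's mutability-weight
    share implies expected overlap ~= observed/target_fold, so a permutation
    test on the set reports approximately ``target_fold`` enrichment.  This
    emulates the study condition of a literature-curated list whose overlap
    with the observed mutations is known; it is not a real disorder list.

    *exclude* lists genes that must not be used as padding (typically every
    mutated gene, so the realised overlap stays exactly ``hit_genes``).
    """
    if target_fold <= 0:
        raise ValueError("target_fold must be positive")
    hit_genes = list(dict.fromkeys(hit_genes))
    total_w = float(sum(weights.values()))
    obs = float(observed if observed is not None else len(hit_genes))
    target_share = obs / (target_fold * n_mutations)
    share = sum(weights[g] for g in hit_genes) / total_w
    if share > target_share:
        raise ValueError(
            f"hit genes alone already exceed the target weight share "
            f"({share:.3g} > {target_share:.3g}); use fewer/lighter hit genes"
        )
    members = list(hit_genes)
    banned = set(hit_genes) | set(exclude or ())
    candidates = list(
        rng.permutation(np.asarray([g for g in weights if g not in banned], dtype=object))
    )
    deficit = target_share - share
    for g in candidates:
        wg = weights[g] / total_w
        if wg <= deficit:
            members.append(g)
            deficit -= wg
            if deficit <= 1e-4 * target_share:
                break
    return GeneSet(name=name, genes=frozenset(members))


def pcms_like_config(seed: int = 0) -> ScenarioConfig:
    """Scenario preset emulating the stereotypy case/control study.

    118 case and 750 control trios, 184 planted risk genes, and per-class
    relative risks chosen so the expected case burden matches the observed
    one (12 LGD and 42 damaging-missense case de novos against the cohort's
    callable-scaled null expectation), which yields ~54 damaging case de
    novos and usually at least one recurrently hit gene.
    """
    base = ScenarioConfig(seed=seed)
    sum_mu = base.coding_per_individual / 2.0
    e_case = base.exposure_case()
    E0_lgd = 2.0 * base.N_case * base.f_lgd * sum_mu * e_case
    E0_misd = 2.0 * base.N_case * base.f_misd * sum_mu * e_case
    g_lgd = estimate_gamma_from_burden(12.0, E0_lgd, base.k_true, base.G)
    g_misd = estimate_gamma_from_burden(42.0, E0_misd, base.k_true, base.G)
    return replace(base, gamma_bar_lgd=g_lgd, gamma_bar_misd=g_misd)
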