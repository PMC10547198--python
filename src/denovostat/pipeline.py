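"""End-to-end orchestration: filter -> burden -> gene test -> MLE -> projection -> enrichment.

The pipeline is a pure function of (inputs, config, seed).  A single master
seed is fanned out to the stochastic stages through ``numpy``'s
``SeedSequence`` spawning, so stage randomness is independent but fully
reproducible.  Each stage writes its table under the output directory and the
run closes with a machine-readable JSON report; logs are line-delimited JSON.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import burden as burden_mod
from . import enrichment as enrich_mod
from . import mle as mle_mod
from . import projection as proj_mod
from . import tada as tada_mod
from .io import (
    CohortTable,
    MutationRateTable,
    read_cohort_table,
    read_denovo_table,
    read_gene_sets_tsv,
    read_rate_table,
)
from .variants import (
    DeNovoVariant,
    VariantClass,
    case_exclusive_damaging_genes,
    frequency_filter,
    is_damaging,
    tabulate_counts,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

_KNOWN_KEYS = {
    "variants",
    "trios",
    "rates",
    "gene_sets",
    "out_dir",
    "seed",
    "freq_threshold",
    "q_high_confidence",
    "q_probable",
    "p_significant",
    "mle",
    "projection",
    "enrichment",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Thresholds: ``freq_threshold`` for the population-frequency filter,
    ``q_high_confidence`` / ``q_probable`` FDR cuts, ``p_significant`` for
    burden rows.  ``mle``, ``projection`` and ``enrichment`` hold per-stage
    parameter blocks; a stage with block None is skipped.
    """

    variants: str
    trios: str
    rates: str
    out_dir: str
    seed: int
    gene_sets: Optional[str] = None
    freq_threshold: float = 0.001
    q_high_confidence: float = 0.1
    q_probable: float = 0.3
    p_significant: float = 0.05
    mle: Optional[dict] = field(default_factory=dict)
    projection: Optional[dict] = None
    enrichment: Optional[dict] = None


def validate_config(raw: dict) -> RunConfig:
    """Normalise a parsed config mapping, rejecting contradictions."""
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("variants", "trios", "rates", "out_dir"):
        if key not in raw:
            raise ValueError(f"config missing required key {key!r}")
    cfg = RunConfig(**raw) if "seed" in raw else None
    if cfg is None:
        # Monte-Carlo stages (MLE is on by default) need an explicit seed
        raise ValueError("config missing required key 'seed'")
    for name in ("freq_threshold", "q_high_confidence", "q_probable", "p_significant"):
        v = getattr(cfg, name)
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must be in (0, 1), got {v}")
    if cfg.q_high_confidence > cfg.q_probable:
        raise ValueError("q_high_confidence must not exceed q_probable")
    return cfg


def _log(stage: str, t0: float, **fields) -> None:
    rec = {"stage": stage, "elapsed_s": round(time.monotonic() - t0, 3), **fields}
    print(json.dumps(rec), file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and return the JSON-ready report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    master = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(("tada", "mle", "projection", "enrichment"), master.spawn(4))
    }

    t0 = time.monotonic()
    variants = read_denovo_table(config.variants)
    cohorts = read_cohort_table(config.trios)
    rates = read_rate_table(config.rates)
    variants = frequency_filter(variants, config.freq_threshold)
    case_vs = [v for v in variants if v.cohort == "case"]
    ctrl_vs = [v for v in variants if v.cohort == "control"]
    _log("load", t0, n_case_variants=len(case_vs), n_ctrl_variants=len(ctrl_vs))

    # burden
    rows = burden_mod.burden_table(case_vs, ctrl_vs, cohorts, alpha=config.p_significant)
    bframe = burden_mod.burden_frame(rows)
    bframe.to_csv(out / "burden.tsv", sep="\t", index=False)
    report["burden"] = bframe.to_dict(orient="records")
    _log("burden", t0, n_significant=int(bframe["significant"].sum()))

    # case-exclusive damaging gene list
    exclusive = case_exclusive_damaging_genes(case_vs, ctrl_vs)
    (out / "case_exclusive_genes.txt").write_text("\n".join(sorted(exclusive.genes)) + "\n")
    report["case_exclusive_damaging_genes"] = len(exclusive)

    # gene-level Bayesian test, hyperparameters derived from the burden
    N_case = cohorts.n_trios("case")
    exposure = cohorts.callable_total("case") / (
        N_case * burden_mod.ExomeConstants().coding_exome_bp * 2
    )
    counts = tabulate_counts(case_vs)
    E0_lgd = 2.0 * N_case * float(rates.mu_lgd.sum()) * exposure
    E0_misd = 2.0 * N_case * float(rates.mu_misd.sum()) * exposure
    mle_block = config.mle if config.mle is not None else {}
    k_prior = int(mle_block.get("k_prior", 184))
    params = tada_mod.TadaParams(
        n_trios=N_case,
        gamma_bar_lgd=tada_mod.estimate_gamma_from_burden(
            counts[VariantClass.LGD], E0_lgd, k_prior, rates.n_genes
        ),
        gamma_bar_misd=tada_mod.estimate_gamma_from_burden(
            counts[VariantClass.MIS_D], E0_misd, k_prior, rates.n_genes
        ),
        pi=k_prior / rates.n_genes,
        seed=seeds["tada"],
    )
    results, skipped = tada_mod.run_tada(case_vs, rates, params)
    tframe = tada_mod.results_frame(results)
    tframe.to_csv(out / "tada.tsv", sep="\t", index=False)
    hc = tframe.loc[tframe["qval"] < config.q_high_confidence, "gene"].tolist()
    probable = tframe.loc[tframe["qval"] < config.q_probable, "gene"].tolist()
    report["tada"] = {
        "params": {
            "gamma_bar_lgd": params.gamma_bar_lgd,
            "gamma_bar_misd": params.gamma_bar_misd,
            "pi": params.pi,
            "seed": params.seed,
        },
        "high_confidence": hc,
        "probable": probable,
        "skipped_genes": skipped,
    }
    _log("tada", t0, n_high_confidence=len(hc), n_probable=len(probable))

    # risk-gene count MLE
    if config.mle is not None:
        M_obs = counts[VariantClass.DAMAGING]
        damaging_gene_counts: dict = {}
        for v in case_vs:
            if is_damaging(v):
                damaging_gene_counts[v.gene] = damaging_gene_counts.get(v.gene, 0) + 1
        R_obs = sum(1 for c in damaging_gene_counts.values() if c >= 2)
        max_mult = max(damaging_gene_counts.values(), default=0)
        E0 = mle_mod.expected_null_damaging(rates, N_case, exposure=exposure)
        mcfg = mle_mod.MleConfig(
            M_obs=M_obs,
            R_obs=R_obs,
            n_trios=N_case,
            E0=E0,
            max_multiplicity=max_mult if max_mult >= 2 else None,
            n_sims_per_k=int(mle_block.get("n_sims_per_k", 2000)),
            k_max=int(mle_block.get("k_max", 2500)),
            seed=seeds["mle"],
        )
        mres = mle_mod.mle_risk_genes(mcfg, rates)
        mres.curve().to_csv(out / "mle_curve.tsv", sep="\t", index=False)
        report["mle"] = {
            "M_obs": M_obs,
            "R_obs": R_obs,
            "E0": E0,
            "k_hat": mres.k_hat,
            "support": [mres.support_low, mres.support_high],
            "identifiable": mres.identifiable,
            "seed": mcfg.seed,
        }
        _log("mle", t0, k_hat=mres.k_hat)

    # discovery projection
    if config.projection is not None:
        pblock = dict(config.projection)
        k_proj = int(pblock.get("k", report.get("mle", {}).get("k_hat", k_prior)))
        # relative risks re-derived for the k actually projected: the same
        # observed excess spread over more genes means a weaker per-gene risk
        pcfg = proj_mod.ProjectionConfig(
            trio_grid=pblock.get("trio_grid", [100, 250, 500, 1000]),
            k=k_proj,
            gamma_bar_lgd=tada_mod.estimate_gamma_from_burden(
                counts[VariantClass.LGD], E0_lgd, k_proj, rates.n_genes
            ),
            gamma_bar_misd=tada_mod.estimate_gamma_from_burden(
                counts[VariantClass.MIS_D], E0_misd, k_proj, rates.n_genes
            ),
            exposure=float(pblock.get("exposure", exposure)),
            n_sims=int(pblock.get("n_sims", 200)),
            seed=seeds["projection"],
        )
        pframe = proj_mod.project_discovery(pcfg, rates)
        pframe.to_csv(out / "projection.tsv", sep="\t", index=False)
        report["projection"] = {
            "table": pframe.to_dict(orient="records"),
            "seed": pcfg.seed,
        }
        _log("projection", t0, grid=list(pcfg.trio_grid))

    # gene-set enrichment
    if config.enrichment is not None and config.gene_sets:
        sets = read_gene_sets_tsv(config.gene_sets)
        weights = {str(g): float(m) for g, m in zip(rates.genes, rates.mu_damaging)}
        mutations = [(v.gene, None) for v in case_vs if is_damaging(v) and v.gene in weights]
        eres = enrich_mod.cross_disorder_scan(
            mutations,
            sets,
            weights,
            n_perm=int(config.enrichment.get("n_perm", 10_000)),
            seed=seeds["enrichment"],
        )
        eframe = enrich_mod.enrichment_frame(eres)
        eframe.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["enrichment"] = {
            "table": eframe.to_dict(orient="records"),
            "seed": seeds["enrichment"],
        }
        _log("enrichment", t0, n_sets=len(sets))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    _log("done", t0)
    return report


def load_config(path) -> RunConfig:
    """Read and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    return validate_config(raw)
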