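"""Gene-level Bayesian test for de novo recurrence (TADA-Denovo).

For each gene g and variant class c (LGD, Mis-D) the observed de novo count
x is modelled as Poisson.  Under the null the mean is q0 = 2*N*mu_{g,c},
with mu the per-gene, per-generation haploid mutation rate and N the number
of trios.  Under the alternative the rate is inflated by a relative risk
gamma with a Gamma(gamma_bar*beta, beta) prior (mean gamma_bar), giving a
negative-binomial marginal likelihood and a closed-form class Bayes factor

    BF = [Gamma(x + gb)/(x! Gamma(gb)) * (b/(b+q0))^gb * (q0/(b+q0))^x]
         / [exp(-q0) q0^x / x!],        gb = gamma_bar*beta, b = beta.

Class Bayes factors multiply into a gene Bayes factor.  With prior risk-gene
fraction pi the posterior is pi*BF/(pi*BF + 1 - pi), and q-values follow the
Bayesian direct posterior approach: rank genes by BF and take the running
mean of (1 - posterior), so q at rank i is the expected false-discovery
proportion if the top i genes are declared risk genes.  Genes with q < 0.1
are called high-confidence and q < 0.3 probable risk genes.

Empirical p-values come from simulating null cohorts from the rate table
(per-gene Poisson counts at q0) and comparing observed Bayes factors against
the simulated null BF distribution, pooled across genes by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MutationRateTable
from .variants import DeNovoVariant, VariantClass, classify_variant

__all__ = [
    "TadaParams",
    "TadaGeneResult",
    "class_bayes_factor",
    "log_class_bayes_factor",
    "gene_bayes_factor",
    "direct_posterior_fdr",
    "null_pvalues",
    "estimate_gamma_from_burden",
    "count_class_hits",
    "run_tada",
    "results_frame",
]

#: per-gene class counts beyond this are treated as input errors
MAX_COUNT = 50

Q_HIGH_CONFIDENCE = 0.1
Q_PROBABLE = 0.3


@dataclass(frozen=True)
class TadaParams:
    """Hyperparameters of the de novo Bayesian test.

    gamma_bar_* are prior mean relative risks in risk genes (>= 1); beta_* are
    the Gamma prior rate parameters (the prior is Gamma(gamma_bar*beta, beta));
    pi is the prior fraction of risk genes k/G.
    """

    n_trios: int
    gamma_bar_lgd: float
    gamma_bar_misd: float
    beta_lgd: float = 1.0
    beta_misd: float = 1.0
    pi: float = 0.01
    n_null_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trios <= 0:
            raise ValueError("n_trios must be positive")
        if self.gamma_bar_lgd < 1 or self.gamma_bar_misd < 1:
            raise ValueError("prior mean relative risks must be >= 1")
        if self.beta_lgd <= 0 or self.beta_misd <= 0:
            raise ValueError("beta parameters must be positive")
        if not (0.0 < self.pi < 1.0):
            raise ValueError("pi must be in (0, 1)")


@dataclass(frozen=True)
class TadaGeneResult:
    gene: str
    x_lgd: int
    x_misd: int
    bf_lgd: float
    bf_misd: float
    bf_total: float
    posterior: float
    q: float
    p_empirical: Optional[float] = None


def log_class_bayes_factor(x, q0, gamma_bar: float, beta: float):
    """log BF of one variant class; vectorised over x and q0.

    ``q0`` is the null Poisson mean 2*N*mu.  Genes with q0 == 0 and x == 0
    are uninformative (log BF 0); q0 == 0 with x > 0 is a rate-table
    inconsistency and raises.
    """
    x = np.asarray(x, dtype=float)
    q0 = np.asarray(q0, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if (x > MAX_COUNT).any():
        raise ValueError(f"per-gene class count exceeds sanity cap {MAX_COUNT}")
    bad = (q0 <= 0) & (x > 0)
    if bad.any():
        raise ValueError(
            "zero mutation rate with observed variants (rate table inconsistency)"
        )
    gb = gamma_bar * beta
    with np.errstate(divide="ignore", invalid="ignore"):
        safe_q0 = np.where(q0 > 0, q0, 1.0)
        logbf = (
            gammaln(x + gb)
            - gammaln(gb)
            + gb * (np.log(beta) - np.log(beta + safe_q0))
            - x * np.log(beta + safe_q0)
            + safe_q0
        )
    return np.where(q0 > 0, logbf, 0.0)


def class_bayes_factor(x: int, N: int, mu: float, gamma_bar: float, beta: float) -> float:
    """Bayes factor for one gene-class observation (x counts in N trios)."""
    q0 = 2.0 * N * mu
    return float(np.exp(log_class_bayes_factor(x, q0, gamma_bar, beta)))


def gene_bayes_factor(
    x_lgd: int,
    x_misd: int,
    mu_lgd: float,
    mu_misd: float,
    params: TadaParams,
) -> tuple[float, float, float]:
    """(bf_lgd, bf_misd, bf_total) for one gene; bf_total is the product."""
    bf_l = class_bayes_factor(x_lgd, params.n_trios, mu_lgd, params.gamma_bar_lgd, params.beta_lgd)
    bf_m = class_bayes_factor(x_misd, params.n_trios, mu_misd, params.gamma_bar_misd, params.beta_misd)
    return bf_l, bf_m, bf_l * bf_m


def _log_bf_matrix(
    x_lgd: np.ndarray, x_misd: np.ndarray, rates: MutationRateTable, params: TadaParams
) -> tuple[np.ndarray, np.ndarray]:
    N = params.n_trios
    lb_l = log_class_bayes_factor(x_lgd, 2.0 * N * rates.mu_lgd, params.gamma_bar_lgd, params.beta_lgd)
    lb_m = log_class_bayes_factor(x_misd, 2.0 * N * rates.mu_misd, params.gamma_bar_misd, params.beta_misd)
    return lb_l, lb_m


def direct_posterior_fdr(
    bfs: Sequence[float], pi: float, genes: Optional[Sequence[str]] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probabilities and direct-posterior q-values.

    Genes are ranked by BF descending (stable; ties broken by gene symbol
    ascending when symbols are supplied) and q at rank i is the running mean
    of (1 - posterior) over the top i genes.  Tied BFs share the largest
    q of their tie block, so declaring "everything at least this strong"
    has a well-defined expected false-discovery proportion.  Results are
    returned in input order.
    """
    bfs = np.asarray(bfs, dtype=float)
    if bfs.size == 0:
        raise ValueError("need at least one gene")
    if not (0.0 < pi < 1.0):
        raise ValueError("pi must be in (0, 1)")
    posterior = pi * bfs / (pi * bfs + (1.0 - pi))
    posterior = np.where(np.isinf(bfs), 1.0, posterior)

    if genes is not None:
        order = np.lexsort((np.asarray(genes, dtype=object), -bfs))
    else:
        order = np.argsort(-bfs, kind="stable")
    q_sorted = np.cumsum(1.0 - posterior[order]) / np.arange(1, bfs.size + 1)
    # tied BFs share the q of the worst (last) tied rank
    sorted_bf = bfs[order]
    i = bfs.size - 2
    while i >= 0:
        if sorted_bf[i] == sorted_bf[i + 1]:
            q_sorted[i] = q_sorted[i + 1]
        i -= 1
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return posterior, q


def estimate_gamma_from_burden(x_case: float, E0: float, k: int, G: int) -> float:
    """Prior mean relative risk implied by an observed class burden.

    The excess count (x_case - E0) over the null expectation E0 = 2N*sum(mu)
    is attributed uniformly to k risk genes out of G, giving
    gamma_bar = 1 + (x_case - E0)*G/(E0*k), floored at 1.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if G < k:
        raise ValueError("k cannot exceed G")
    if E0 <= 0:
        raise ValueError("null expectation E0 must be positive")
    return max(1.0, 1.0 + (x_case - E0) * G / (E0 * k))


def null_pvalues(
    observed_log_bf: np.ndarray,
    rates: MutationRateTable,
    params: TadaParams,
    pooled: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Empirical p-values of observed gene Bayes factors under the null.

    Null cohorts are simulated from the rate table (per-gene class counts
    Poisson at 2*N*mu) and gene log-BFs recomputed.  With ``pooled=True``
    (default) all simulated gene BFs form one null distribution and
    p = (1 + #{null BF >= observed})/(n_null + 1); otherwise each gene is
    compared only against its own simulated BFs.
    """
    if params.n_null_sims < 100:
        raise ValueError("n_null_sims must be >= 100")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    G = rates.n_genes
    n = params.n_null_sims
    q0_l = 2.0 * params.n_trios * rates.mu_lgd
    q0_m = 2.0 * params.n_trios * rates.mu_misd
    obs = np.asarray(observed_log_bf, dtype=float)

    if pooled:
        exceed = np.zeros(G, dtype=np.int64)
        total = 0
        for _ in range(n):
            x_l = rng.poisson(q0_l)
            x_m = rng.poisson(q0_m)
            np.minimum(x_l, MAX_COUNT, out=x_l)
            np.minimum(x_m, MAX_COUNT, out=x_m)
            lb = log_class_bayes_factor(x_l, q0_l, params.gamma_bar_lgd, params.beta_lgd)
            lb += log_class_bayes_factor(x_m, q0_m, params.gamma_bar_misd, params.beta_misd)
            lb.sort()
            exceed += G - np.searchsorted(lb, obs, side="left")
            total += G
        return (1.0 + exceed) / (total + 1.0)

    exceed = np.zeros(G, dtype=np.int64)
    for _ in range(n):
        x_l = rng.poisson(q0_l)
        x_m = rng.poisson(q0_m)
        np.minimum(x_l, MAX_COUNT, out=x_l)
        np.minimum(x_m, MAX_COUNT, out=x_m)
        lb = log_class_bayes_factor(x_l, q0_l, params.gamma_bar_lgd, params.beta_lgd)
        lb += log_class_bayes_factor(x_m, q0_m, params.gamma_bar_misd, params.beta_misd)
        exceed += lb >= obs
    return (1.0 + exceed) / (n + 1.0)


def count_class_hits(
    variants: Iterable[DeNovoVariant], rates: MutationRateTable
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-gene (x_lgd, x_misd) count vectors aligned to the rate table.

    Genes carrying variants but absent from the rate table are returned as a
    skip report (third element) rather than silently dropped.
    """
    x_lgd = np.zeros(rates.n_genes, dtype=np.int64)
    x_misd = np.zeros(rates.n_genes, dtype=np.int64)
    skipped: list[str] = []
    lgd_classes = (
        VariantClass.LGD_STOPGAIN,
        VariantClass.LGD_SPLICE,
        VariantClass.LGD_FRAMESHIFT,
    )
    for v in variants:
        c = classify_variant(v)
        if c in lgd_classes or c is VariantClass.MIS_D:
            gene = v.gene.strip()
            if gene not in rates:
                skipped.append(gene)
                continue
            i = rates.gene_index([gene])[0]
            if c is VariantClass.MIS_D:
                x_misd[i] += 1
            else:
                x_lgd[i] += 1
    return x_lgd, x_misd, sorted(set(skipped))


def run_tada(
    case_variants: Sequence[DeNovoVariant],
    rates: MutationRateTable,
    params: TadaParams,
    compute_pvalues: bool = False,
) -> tuple[list[TadaGeneResult], list[str]]:
    """Full TADA-Denovo pass over the rate table's gene universe.

    Returns per-gene results (every gene in the rate table, input order) and
    the skip report of variant genes absent from the rate table.
    """
    x_lgd, x_misd, skipped = count_class_hits(case_variants, rates)
    lb_l, lb_m = _log_bf_matrix(x_lgd, x_misd, rates, params)
    lb_total = lb_l + lb_m
    posterior, q = direct_posterior_fdr(np.exp(lb_total), params.pi, genes=rates.genes)
    p_emp = (
        null_pvalues(lb_total, rates, params) if compute_pvalues else None
    )
    results = [
        TadaGeneResult(
            gene=str(rates.genes[i]),
            x_lgd=int(x_lgd[i]),
            x_misd=int(x_misd[i]),
            bf_lgd=float(np.exp(lb_l[i])),
            bf_misd=float(np.exp(lb_m[i])),
            bf_total=float(np.exp(lb_total[i])),
            posterior=float(posterior[i]),
            q=float(q[i]),
            p_empirical=(float(p_emp[i]) if p_emp is not None else None),
        )
        for i in range(rates.n_genes)
    ]
    return results, skipped


def results_frame(results: Sequence[TadaGeneResult]) -> pd.DataFrame:
    """Result table with TADA-style column names, sorted by evidence."""
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "dn.cls1": r.x_lgd,
                "dn.cls2": r.x_misd,
                "BF.cls1": r.bf_lgd,
                "BF.cls2": r.bf_misd,
                "BF": r.bf_total,
                "posterior": r.posterior,
                "pval": r.p_empirical,
                "qval": r.q,
            }
            for r in results
        ]
    )
    df["high_confidence"] = df["qval"] < Q_HIGH_CONFIDENCE
    df["probable"] = df["qval"] < Q_PROBABLE
    return df.sort_values(["BF", "gene"], ascending=[False, True], kind="stable").reset_index(drop=True)
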