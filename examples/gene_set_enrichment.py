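"""Mutability-weighted permutation test of gene-set overlap.

Asks whether the genes damaged de novo in a case cohort overlap a curated
gene set more than expected, where expectation respects per-gene damaging
mutation rates (long, mutable genes are hit more often by chance).
"""

import numpy as np

import denovostat as ds
from denovostat.enrichment import cross_disorder_scan
from denovostat.variants import frequency_filter, is_damaging

cfg = ds.pcms_like_config(seed=7)
rng = np.random.default_rng(7)
rates = ds.make_rate_table(cfg, rng)
sim = ds.simulate_trio_cohort(cfg, rates, rng)

mutations = [(v.gene, None) for v in frequency_filter(sim.variants)
             if v.cohort == "case" and is_damaging(v)]
weights = {str(g): float(w) for g, w in zip(rates.genes, rates.mu_damaging)}

# one set enriched for the planted risk genes, one random control set
sets = ds.make_gene_sets(cfg, rates, sim.risk_genes, sizes=[150], overlap_with_risk=0.6, rng=rng)
sets += ds.make_gene_sets(cfg, rates, sim.risk_genes, sizes=[150], overlap_with_risk=0.0, rng=rng)

for r in cross_disorder_scan(mutations, sets, weights, n_perm=10_000, seed=3):
    print(f"{r.set_name:14s} observed {r.observed:4.0f}  expected {r.expected:5.2f}  "
          f"fold {r.fold:5.2f}  p {r.p:.4f}")
# fold = observed/expected overlap; p is the one-sided add-one permutation
# p-value. The risk-overlapping set shows fold >> 1, the random set fold ~ 1.
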