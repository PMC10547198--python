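# Methods

This note records the models behind `denovostat`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
places where the design was genuinely open.

## Variant classification

Variants are classified from ANNOVAR-style annotations into a strict
hierarchy. The finest classes partition the coding variants: synonymous,
Mis-D/Mis-P/Mis-B (PolyPhen2-HDIV ≥ 0.957 / [0.453, 0.957) / < 0.453),
missense-without-prediction, stopgain+stoploss, canonical splice,
frameshift, nonframeshift, unknown. Aggregates are sums, so identities such
as nonsynonymous = all-missense + LGD hold exactly on every tabulation.
Decisions worth recording:

- **Stoploss counts as LGD** (it alters a stop codon, like stopgain).
- **Missense without a PolyPhen2 prediction** counts in "all missense" and
  everything above it, but in no Mis-D/P/B sub-class.
- **Missing population frequency passes the < 0.001 rarity filter**: a
  confirmed de novo absent from the aggregation database is novel.
- Gene symbols are compared case-sensitively after whitespace trimming; no
  alias resolution is attempted, since inputs come from a single annotation
  source.

## Burden testing

Rates are x/B with B the cohort's summed haploid callable bases; the "all"
row uses whole-capture callable totals and coding rows coding totals.
Per-individual estimates multiply the per-bp rate by the RefSeq hg19 coding
exome (33,828,798 bp) **and by a ploidy factor of 2**: the haploid callable
denominator makes the per-bp rate haploid, so the diploid per-person
expectation needs the factor (it is configurable via `ExomeConstants`).

The test is the exact conditional comparison of two Poisson rates:
conditional on T = x_case + x_ctrl, the case count is Binomial(T, p₀) with
p₀ = B_case/(B_case+B_ctrl); one-sided p-values are exact binomial tails
(direction: case > control). The default CI is the log-normal (Katz)
interval exp(ln RR ± z√(1/x_case + 1/x_ctrl)); an exact conditional
interval (Clopper–Pearson on the binomial fraction, transformed to the RR
scale) is available and is substituted automatically when a zero cell makes
the Katz interval undefined. Exact CIs for small counts are wide; no
procedure here reproduces any published interval bit-exactly, and none is
attempted — intervals are validated at 10% relative tolerance against
published anchors.

## Gene-level Bayesian test

Per gene and class, x ~ Poisson(q₀γ) with q₀ = 2Nμ; γ = 1 under the null
and γ ~ Gamma(γ̄β, β) under the alternative, giving

    BF = NB(x; γ̄β, β/(β+q₀)) / Poisson(x; q₀)

computed in log space (`scipy.special.gammaln`); class BFs multiply into the
gene BF. Posterior and q-values follow the direct posterior approach:
posterior = πBF/(πBF + 1 − π); rank genes by BF (stable sort, ties broken
by symbol; tied BFs share the worst q of the tie block); q at rank i is the
running mean of (1 − posterior), the expected false-discovery proportion of
declaring the top i genes.

Defaults: **β = 1**; **γ̄ per class from the observed burden** via
γ̄ = 1 + (x − E0)·G/(E0·k), i.e. the observed excess concentrated uniformly
in k risk genes (floored at 1); **π = k/G**. With 118 trios, 12 LGD and 42
Mis-D case variants, k = 184 and G = 18,665 this gives γ̄ ≈ 83 (LGD) and
≈ 28 (Mis-D). Per-gene class counts above 50 are rejected as input errors.
Empirical p-values simulate null cohorts from the rate table and compare
observed BFs against the simulated BF distribution pooled across genes
(add-one estimator); a per-gene null option exists. Pooling is cheap and
gives fine-grained p-values, but for zero-count genes it can rank
low-mutability genes above high-mutability ones; q-values, not p-values,
drive all discovery thresholds here.

## Null expectations and callable exposure

Per-gene mutation-rate tables are calibrated to per-individual expectations
on a fully callable exome. Real cohorts call de novos on only their
callable fraction (~70–80% of the coding exome), so expected *observed*
counts are E0 = 2NΣμ × exposure, with exposure = mean per-trio callable bp
divided by twice the coding exome. This is not optional bookkeeping: with
2Σμ_damaging = 0.42 per individual, a 750-trio control cohort at callable
fraction 0.74 is expected to show ≈ 233 damaging de novos — matching
observation — whereas the unscaled expectation (315) does not.
`expected_null_damaging` therefore takes an `exposure` argument (default
1.0 for tables that already reflect the sequenced territory).

## Risk-gene count MLE

Model for one replicate at candidate k: draw the excess count
C ~ Binomial(M, C̄/M) with C̄ = max(0, M − E0) (stochastic rounding avoids
bias); choose k risk genes uniformly from the universe; place C mutations
within the risk set weighted by μ_damaging (uniform placement is an
option); place the remaining M − C mutations over all G genes weighted by
μ_damaging; record the per-gene multiplicities.

The likelihood L(k) is the fraction of replicates whose recurrence agrees
with the data, where agreement means: the number of genes with ≥ 2
mutations equals R_obs **and** no gene exceeds the observed maximum
multiplicity. The second clause matters. Matching the scalar R alone is
degenerate: at k = 1 the whole excess lands in one gene, which yields
"exactly one recurrent gene" with high probability regardless of the data,
so the scalar likelihood always peaks at k = 1. Requiring the maximum
multiplicity to match (2, when the one recurrent gene carries exactly a
pair) restores a unimodal likelihood whose peak moves with the data. The
scalar statistic remains available (`max_multiplicity=None`), and the
estimator's self-consistency is verified by parameter recovery on synthetic
cohorts with known k.

Estimation scans a coarse logarithmic grid over [1, 2500] and refines
around the argmax (smallest k on ties), default 2,000 simulations per k;
the support interval collects every k with L(k) ≥ L(k̂)/e². At pilot scale
the curve is flat near its peak — the support interval spans an order of
magnitude, which is the honest precision of a ~50-mutation summary. A
cohort with no expected excess and no recurrence is flagged
non-identifiable.

## Discovery projection

At each cohort size n, replicates draw k risk genes uniformly, generate
class counts Poisson(2nμ_c γ_c · exposure) with γ_c = γ̄_c in risk genes
and 1 otherwise, and run the Bayesian test (π = k/G, same γ̄ — signal model
and analysis prior deliberately coherent). Reported: mean probable and
high-confidence counts with Monte-Carlo SEs, and the realised true-positive
fraction among flagged genes. The `exposure` knob generates cohorts
sequenced like the pilot (callable fraction ≈ 0.79) while the analysis
keeps full-exome rates — the same asymmetry the real analysis experiences.
Desk-scale default is 200 replicates per grid point; grids and replicate
counts are explicit config.

Because γ̄, β and π behind any published projection of this kind are rarely
printed, projected counts are expected to agree with published curves only
to tens of percent. Under the burden-derived calibration here, projections
at 1000 trios and probable-gene counts at 500 trios land within ±30% of the
published anchor values; the high-confidence count at 500 trios runs ~45%
high, which we attribute to hyperparameter differences we cannot recover
from the published record and have not tuned toward.

## Permutation enrichment

Placement weights default to per-gene damaging mutation rates — an
approximation to alignment-aware, trinucleotide-context placement that
subsumes gene length and sequence context; the weight column is pluggable,
and class-specific weight vectors are supported. Each permutation
reassigns every mutation independently; the statistic is the number of
mutations in the set (a distinct-genes option exists, since "genes
harbouring mutations enriched among genes" phrasing is ambiguous in the
field); fold = observed / permutation mean; p is the add-one estimator.
Multiple sets share one permutation stream; nominal p-values are reported
without multiplicity correction.

## Synthetic data generator

What it emulates: per-gene rate heterogeneity (lognormal, log-sd 1.0 —
about the spread of published per-gene rate tables); class composition of
coding de novos (fractions anchored to a large published control cohort:
synonymous 27%, Mis-P 13%, Mis-B 22%, LGD 6%, Mis-D 30%, small
nonframeshift/unknown/no-prediction remnants, ~6% extra noncoding);
per-trio callable heterogeneity (Normal callable bp entering as an exposure
multiplier); planted risk genes with per-class relative risks; PolyPhen
scores drawn uniformly within each sub-class band; a configurable fraction
of common-population variants to exercise the frequency filter.

Calibration: summed rates are scaled so a fully callable individual expects
1.18 coding de novos (hence 0.42 damaging); the `pcms_like` preset (118
case / 750 control trios, k = 184, per-trio callable means 5.37e7/4.81e7)
derives its relative risks from the 12-LGD / 42-Mis-D case anchors, so the
expected case damaging count is ~54 and at least one recurrently hit gene
appears in most seeds.

What it does not emulate: sequence context (no trinucleotide model, no
per-gene length/GC structure beyond the rate), annotation error, mosaicism,
relatedness, sex chromosomes, or correlated callable profiles between
family members. Passing tests on synthetic data therefore validate the
statistical machinery and its calibration identities, not robustness to
annotation noise in real tables.

## Numerical choices

- All likelihoods in log space; BF = exp(logBF) only at the edges.
- Zero rates with zero counts are uninformative (BF 1); zero rates with
  observed counts raise (rate-table inconsistency).
- x_ctrl = 0 in the rate-ratio test reports RR = ∞ with the exact CI; no
  division by zero anywhere.
- Add-one estimators for all empirical p-values, so p ∈ (0, 1].
- Every Monte-Carlo entry point takes an explicit seed or Generator; the
  pipeline fans one master seed out through `SeedSequence.spawn`, so stage
  randomness is independent but reproducible, and reruns with the same
  seed produce byte-identical report payloads.

## Problem sizes

Defaults are desk-scale by design: 2,000 MLE simulations per k on a
coarse-to-fine grid, 200 projection replicates per cohort size, 10–20k
permutations per enrichment scan. These reproduce the anchors above with
Monte-Carlo error small relative to the stated tolerances; all are plain
config fields for larger runs.

## Known limitations

- The gene-list count ambiguity: a published 52-entry case-exclusive gene
  table lists one gene twice, and 54 damaging variants with one recurrent
  pair minus two control-overlap genes gives 51 unique symbols, not 52; the
  published arithmetic cannot be reconciled exactly. The operation returns
  unique symbols, and the synthetic fixture used in testing is constructed
  to be internally consistent (53 distinct damaged genes, one exclusion,
  52 remaining).
- The MLE treats (M, R, max multiplicity) as the whole data summary;
  likelihood based on the full recurrence vector or per-gene identities
  would be sharper.
- The enrichment null is rate-weighted placement, not alignment-aware
  placement; folds against tools using sequence-context nulls agree only
  approximately.
- π, γ̄ and β interact; the burden-derived defaults are one defensible
  calibration, not an estimate with uncertainty.
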