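"""Mutability-weighted permutation test of gene-set overlap.

Tests whether an observed list of de novo damaging mutations hits a curated
gene set more often than chance, where "chance" respects gene mutability:
each permutation independently reassigns every mutation to a gene with
probability proportional to a per-gene weight (by default the gene's damaging
mutation rate, which subsumes gene length and sequence context).  The
statistic is the number of mutations landing in the set (or, optionally, the
number of distinct set genes hit); fold enrichment is observed over the
permutation mean and the one-sided p-value uses the add-one estimator
p = (1 + #{perm >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variants import GeneSet

__all__ = [
    "EnrichmentResult",
    "expected_overlap",
    "permutation_enrichment",
    "cross_disorder_scan",
]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    n_mutations: int
    observed: float
    expected: float
    fold: float
    p: float
    n_perm: int
    seed: Optional[int] = None


def _weight_arrays(weights: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray, dict]:
    genes = np.asarray(list(weights.keys()), dtype=object)
    w = np.asarray([weights[g] for g in genes], dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must have positive total")
    return genes, w, {g: i for i, g in enumerate(genes)}


def expected_overlap(
    weights: Mapping[str, float], gene_set: GeneSet, n_mutations: int
) -> float:
    """Closed-form permutation mean: n_mutations * (set weight share)."""
    genes, w, _ = _weight_arrays(weights)
    in_set = np.asarray([g in gene_set for g in genes])
    if not in_set.any():
        warnings.warn(
            f"gene set {gene_set.name!r} shares no genes with the weighted universe",
            stacklevel=2,
        )
        return 0.0
    return n_mutations * float(w[in_set].sum() / w.sum())


def _observed_stat(
    mut_idx: np.ndarray, in_set: np.ndarray, statistic: str
) -> float:
    hits = in_set[mut_idx]
    if statistic == "mutations":
        return float(hits.sum())
    return float(np.unique(mut_idx[hits]).size)


def _perm_stats(
    draws: np.ndarray, in_set: np.ndarray, statistic: str
) -> np.ndarray:
    if statistic == "mutations":
        return in_set[draws].sum(axis=1)
    out = np.empty(draws.shape[0], dtype=np.int64)
    for r in range(draws.shape[0]):
        row = draws[r]
        out[r] = np.unique(row[in_set[row]]).size
    return out


def permutation_enrichment(
    mutations: Sequence[tuple],
    gene_set: GeneSet,
    weights: Mapping[str, float],
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    statistic: str = "mutations",
    class_weights: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> EnrichmentResult:
    """Permutation enrichment of one gene set.

    *mutations* is a sequence of ``(gene, class)`` pairs (class may be None).
    With *class_weights* given, mutations of a class listed there are
    permuted under that class's weight vector; others fall back to *weights*.
    Every mutation's gene must be present in its weight universe.
    """
    if statistic not in ("mutations", "genes"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    genes, w, index = _weight_arrays(weights)
    in_set = np.asarray([g in gene_set for g in genes])

    mut_genes = [m[0] for m in mutations]
    missing = sorted({g for g in mut_genes if g not in index})
    if missing:
        raise ValueError(f"mutation genes absent from the weighted universe: {missing}")
    mut_idx = np.asarray([index[g] for g in mut_genes], dtype=int)
    n_mut = len(mutations)
    observed = _observed_stat(mut_idx, in_set, statistic)

    draws = np.empty((n_perm, n_mut), dtype=int)
    if class_weights:
        groups: dict[str, list[int]] = {}
        for j, m in enumerate(mutations):
            groups.setdefault(m[1] if m[1] in class_weights else None, []).append(j)
        for cls, cols in groups.items():
            if cls is None:
                p = w / w.sum()
            else:
                _, wc, idx_c = _weight_arrays(class_weights[cls])
                if list(idx_c) != list(index):
                    raise ValueError("class weight universes must match the base universe")
                p = wc / wc.sum()
            draws[:, cols] = rng.choice(len(genes), size=(n_perm, len(cols)), p=p)
    else:
        draws[:] = rng.choice(len(genes), size=(n_perm, n_mut), p=w / w.sum())

    perm = _perm_stats(draws, in_set, statistic)
    expected = float(perm.mean())
    fold = observed / expected if expected > 0 else (np.inf if observed > 0 else np.nan)
    p = float((1 + (perm >= observed).sum()) / (n_perm + 1))
    return EnrichmentResult(
        set_name=gene_set.name,
        n_mutations=n_mut,
        observed=observed,
        expected=expected,
        fold=fold,
        p=p,
        n_perm=n_perm,
        seed=seed,
    )


def cross_disorder_scan(
    mutations: Sequence[tuple],
    sets: Sequence[GeneSet],
    weights: Mapping[str, float],
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "mutations",
) -> list[EnrichmentResult]:
    """Enrichment of several gene sets against one shared permutation stream.

    All sets are scored against the same random placements, so results for a
    duplicated set are identical.  Nominal p-values are reported with no
    multiplicity correction.
    """
    if not sets:
        return []
    genes, w, index = _weight_arrays(weights)
    mut_genes = [m[0] for m in mutations]
    missing = sorted({g for g in mut_genes if g not in index})
    if missing:
        raise ValueError(f"mutation genes absent from the weighted universe: {missing}")
    mut_idx = np.asarray([index[g] for g in mut_genes], dtype=int)
    n_mut = len(mutations)
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(genes), size=(n_perm, n_mut), p=w / w.sum())

    results = []
    for gs in sets:
        in_set = np.asarray([g in gs for g in genes])
        observed = _observed_stat(mut_idx, in_set, statistic)
        perm = _perm_stats(draws, in_set, statistic)
        expected = float(perm.mean())
        fold = observed / expected if expected > 0 else (np.inf if observed > 0 else np.nan)
        p = float((1 + (perm >= observed).sum()) / (n_perm + 1))
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                n_mutations=n_mut,
                observed=observed,
                expected=expected,
                fold=fold,
                p=p,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "n_mutations": r.n_mutations,
                "observed": r.observed,
                "expected": r.expected,
                "fold": r.fold,
                "p": r.p,
                "n_perm": r.n_perm,
            }
            for r in results
        ]
    )
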