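"""Domain types and classification logic for annotated de novo variants.

A de novo variant is a germline mutation observed in a sequenced child but in
neither parent.  Variants arrive as rows of an ANNOVAR-style annotation table
(gene symbol, exonic function, PolyPhen2-HDIV score, population allele
frequency) and are organised into a hierarchy of functional classes:

* LGD ("likely gene disrupting"): stopgain/stoploss, canonical splice-site and
  frameshift variants;
* Mis-D / Mis-P / Mis-B: missense variants with PolyPhen2-HDIV score >= 0.957
  ("probably damaging"), in [0.453, 0.957) ("possibly damaging"), or < 0.453
  ("benign");
* damaging = LGD + Mis-D, the class carrying most of the association signal in
  trio studies of neurodevelopmental phenotypes.

All counting identities (e.g. nonsynonymous = all-missense + LGD) are exposed
as class-hierarchy invariants and enforced by :func:`tabulate_counts`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Effect",
    "VariantClass",
    "DeNovoVariant",
    "GeneSet",
    "MIS_D_MIN_SCORE",
    "MIS_P_MIN_SCORE",
    "classify_variant",
    "frequency_filter",
    "tabulate_counts",
    "case_exclusive_damaging_genes",
]

#: PolyPhen2-HDIV score thresholds for the missense sub-classes.
MIS_D_MIN_SCORE = 0.957
MIS_P_MIN_SCORE = 0.453


class Effect(str, Enum):
    """Normalised exonic-function annotation of a single variant."""

    SYNONYMOUS_SNV = "synonymous_snv"
    MISSENSE_SNV = "missense_snv"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    SPLICE_SITE = "splice_site"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    UNKNOWN = "unknown"
    NONCODING = "noncoding"


class VariantClass(str, Enum):
    """Variant classes tabulated in a burden analysis.

    The classes form a hierarchy; on any tabulation the identities

    * nonsynonymous = missense_all + lgd
    * damaging      = lgd + mis_d
    * lgd           = lgd_snv + lgd_frameshift
    * lgd_snv       = lgd_stopgain + lgd_splice
    * coding        = synonymous + nonsynonymous + nonframeshift + unknown
    * all           = coding + noncoding

    hold exactly.  Missense variants without a PolyPhen2 prediction count in
    ``missense_all`` (and everything above it) but in no Mis-D/P/B sub-class.
    """

    ALL = "all"
    CODING = "coding"
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    MISSENSE_ALL = "missense_all"
    MIS_D = "mis_d"
    MIS_P = "mis_p"
    MIS_B = "mis_b"
    LGD = "lgd"
    DAMAGING = "damaging"
    LGD_SNV = "lgd_snv"
    LGD_STOPGAIN = "lgd_stopgain"
    LGD_SPLICE = "lgd_splice"
    LGD_FRAMESHIFT = "lgd_frameshift"
    NONFRAMESHIFT = "nonframeshift"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class DeNovoVariant:
    """One annotated de novo call.

    ``polyphen_hdiv`` is only meaningful for missense variants; ``pop_freq``
    (population allele frequency, e.g. ExAC) may be missing, which is read as
    "not seen in the reference population".  ``locus`` is an optional
    ``(chrom, pos, ref, alt)`` tuple with a 1-based position.
    """

    proband_id: str
    cohort: str  # "case" | "control"
    gene: str
    effect: Effect
    polyphen_hdiv: Optional[float] = None
    pop_freq: Optional[float] = None
    locus: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.cohort not in ("case", "control"):
            raise ValueError(f"cohort must be 'case' or 'control', got {self.cohort!r}")
        if self.polyphen_hdiv is not None and not (0.0 <= self.polyphen_hdiv <= 1.0):
            raise ValueError(f"polyphen_hdiv out of [0,1]: {self.polyphen_hdiv}")
        if self.pop_freq is not None and not (0.0 <= self.pop_freq <= 1.0):
            raise ValueError(f"pop_freq out of [0,1]: {self.pop_freq}")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (case-sensitive, whitespace-trimmed)."""

    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(g.strip() for g in self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def classify_variant(v: DeNovoVariant) -> Optional[VariantClass]:
    """Return the finest variant class for *v*.

    Missense variants lacking a PolyPhen2 score classify as ``MISSENSE_ALL``
    (no damaging/possibly/benign sub-class).  Noncoding variants return
    ``None``: they contribute only to the "all" row of a tabulation.
    """
    e = v.effect
    if e is Effect.MISSENSE_SNV:
        s = v.polyphen_hdiv
        if s is None:
            return VariantClass.MISSENSE_ALL
        if s >= MIS_D_MIN_SCORE:
            return VariantClass.MIS_D
        if s >= MIS_P_MIN_SCORE:
            return VariantClass.MIS_P
        return VariantClass.MIS_B
    if e in (Effect.STOPGAIN, Effect.STOPLOSS):
        return VariantClass.LGD_STOPGAIN
    if e is Effect.SPLICE_SITE:
        return VariantClass.LGD_SPLICE
    if e is Effect.FRAMESHIFT_INDEL:
        return VariantClass.LGD_FRAMESHIFT
    if e is Effect.SYNONYMOUS_SNV:
        return VariantClass.SYNONYMOUS
    if e is Effect.NONFRAMESHIFT_INDEL:
        return VariantClass.NONFRAMESHIFT
    if e is Effect.NONCODING:
        return None
    return VariantClass.UNKNOWN


def is_damaging(v: DeNovoVariant) -> bool:
    """True for LGD or Mis-D variants (the "damaging" class)."""
    c = classify_variant(v)
    return c in (
        VariantClass.LGD_STOPGAIN,
        VariantClass.LGD_SPLICE,
        VariantClass.LGD_FRAMESHIFT,
        VariantClass.MIS_D,
    )


def frequency_filter(
    vs: Sequence[DeNovoVariant], threshold: float = 0.001
) -> list[DeNovoVariant]:
    """Keep variants rarer than *threshold* in the reference population.

    A missing ``pop_freq`` is treated as novel (kept): a confirmed de novo
    call absent from the aggregation database has frequency ~0.  Order is
    preserved and the operation is idempotent.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return [v for v in vs if v.pop_freq is None or v.pop_freq < threshold]


# finest classes contributing to each aggregate, in tabulation order
_FINEST = (
    VariantClass.SYNONYMOUS,
    VariantClass.MIS_D,
    VariantClass.MIS_P,
    VariantClass.MIS_B,
    VariantClass.LGD_STOPGAIN,
    VariantClass.LGD_SPLICE,
    VariantClass.LGD_FRAMESHIFT,
    VariantClass.NONFRAMESHIFT,
    VariantClass.UNKNOWN,
)


def tabulate_counts(
    vs: Iterable[DeNovoVariant], cohort: Optional[str] = None
) -> dict[VariantClass, int]:
    """Count variants in every class of the hierarchy.

    If *cohort* is given only variants with that cohort label are counted.
    The returned mapping covers all 16 classes and satisfies the hierarchy
    identities exactly by construction.
    """
    fine: Counter = Counter()
    n_noncoding = 0
    n_missense_noscore = 0
    for v in vs:
        if cohort is not None and v.cohort != cohort:
            continue
        c = classify_variant(v)
        if c is None:
            n_noncoding += 1
        elif c is VariantClass.MISSENSE_ALL:
            n_missense_noscore += 1
        else:
            fine[c] += 1

    out = {c: fine.get(c, 0) for c in _FINEST}
    out[VariantClass.MISSENSE_ALL] = (
        out[VariantClass.MIS_D]
        + out[VariantClass.MIS_P]
        + out[VariantClass.MIS_B]
        + n_missense_noscore
    )
    out[VariantClass.LGD_SNV] = out[VariantClass.LGD_STOPGAIN] + out[VariantClass.LGD_SPLICE]
    out[VariantClass.LGD] = out[VariantClass.LGD_SNV] + out[VariantClass.LGD_FRAMESHIFT]
    out[VariantClass.NONSYNONYMOUS] = out[VariantClass.MISSENSE_ALL] + out[VariantClass.LGD]
    out[VariantClass.DAMAGING] = out[VariantClass.LGD] + out[VariantClass.MIS_D]
    out[VariantClass.CODING] = (
        out[VariantClass.SYNONYMOUS]
        + out[VariantClass.NONSYNONYMOUS]
        + out[VariantClass.NONFRAMESHIFT]
        + out[VariantClass.UNKNOWN]
    )
    out[VariantClass.ALL] = out[VariantClass.CODING] + n_noncoding
    return out


def damaging_genes(vs: Iterable[DeNovoVariant]) -> set[str]:
    """Unique symbols of genes carrying at least one damaging variant."""
    return {v.gene.strip() for v in vs if is_damaging(v)}


def case_exclusive_damaging_genes(
    case_vs: Iterable[DeNovoVariant],
    control_vs: Iterable[DeNovoVariant],
    name: str = "case_exclusive_damaging",
) -> GeneSet:
    """Genes damaged de novo in cases but in no control.

    Returns the *unique* gene symbols with >= 1 damaging (LGD or Mis-D) case
    variant, minus any symbol with >= 1 damaging control variant.  Symbols are
    compared case-sensitively after whitespace trimming.
    """
    genes = damaging_genes(case_vs) - damaging_genes(control_vs)
    return GeneSet(name=name, genes=frozenset(genes))
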