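"""Readers and writers for the tab-separated tables the pipeline consumes.

Four file kinds are supported, all TSV with a header row (UTF-8):

* **variant tables** — one annotated de novo call per row (ANNOVAR-style
  columns; coordinates, when present, are 1-based);
* **trio tables** — one trio per row with phenotype label and per-trio
  haploid callable base counts (the denominators for mutation rates);
* **rate tables** — per-gene expected de novo mutation rates per generation
  (haploid) for the total coding, LGD and damaging-missense classes;
* **gene sets** — one symbol per line, or a two-column (set, gene) TSV.

Column names for variant tables are configurable through a *dialect* mapping
so tables exported from different annotation workflows can be read without
rewriting headers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variants import DeNovoVariant, Effect, GeneSet

__all__ = [
    "TableSchemaError",
    "RowParseError",
    "CohortTable",
    "MutationRateTable",
    "DEFAULT_DIALECT",
    "read_denovo_table",
    "write_denovo_table",
    "read_cohort_table",
    "write_cohort_table",
    "read_rate_table",
    "write_rate_table",
    "read_gene_set",
    "read_gene_sets_tsv",
    "write_gene_sets_tsv",
]


class TableSchemaError(ValueError):
    """A required column is missing or a table-level invariant is violated."""


class RowParseError(ValueError):
    """A row holds an unparsable value; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


#: Logical field -> column header used when reading/writing variant tables.
DEFAULT_DIALECT: dict[str, str] = {
    "proband": "proband_id",
    "cohort": "cohort",
    "gene": "gene",
    "effect": "exonic_function",
    "polyphen": "polyphen2_hdiv",
    "pop_freq": "exac_freq",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
}

# ANNOVAR-style exonic-function strings -> normalised Effect.
_EFFECT_ALIASES: dict[str, Effect] = {
    "synonymous_snv": Effect.SYNONYMOUS_SNV,
    "synonymous snv": Effect.SYNONYMOUS_SNV,
    "missense_snv": Effect.MISSENSE_SNV,
    "nonsynonymous_snv": Effect.MISSENSE_SNV,
    "nonsynonymous snv": Effect.MISSENSE_SNV,
    "stopgain": Effect.STOPGAIN,
    "stopgain_snv": Effect.STOPGAIN,
    "stopgain snv": Effect.STOPGAIN,
    "stoploss": Effect.STOPLOSS,
    "stoploss_snv": Effect.STOPLOSS,
    "stoploss snv": Effect.STOPLOSS,
    "splice_site": Effect.SPLICE_SITE,
    "splicing": Effect.SPLICE_SITE,
    "frameshift_indel": Effect.FRAMESHIFT_INDEL,
    "frameshift insertion": Effect.FRAMESHIFT_INDEL,
    "frameshift deletion": Effect.FRAMESHIFT_INDEL,
    "frameshift substitution": Effect.FRAMESHIFT_INDEL,
    "nonframeshift_indel": Effect.NONFRAMESHIFT_INDEL,
    "nonframeshift insertion": Effect.NONFRAMESHIFT_INDEL,
    "nonframeshift deletion": Effect.NONFRAMESHIFT_INDEL,
    "nonframeshift substitution": Effect.NONFRAMESHIFT_INDEL,
    "unknown": Effect.UNKNOWN,
    "noncoding": Effect.NONCODING,
    "intronic": Effect.NONCODING,
    "intergenic": Effect.NONCODING,
    "utr3": Effect.NONCODING,
    "utr5": Effect.NONCODING,
    "ncrna_exonic": Effect.NONCODING,
    "ncrna_intronic": Effect.NONCODING,
    "upstream": Effect.NONCODING,
    "downstream": Effect.NONCODING,
}


def _normalise_effect(raw: str) -> Effect:
    return _EFFECT_ALIASES.get(str(raw).strip().lower(), Effect.UNKNOWN)


def _opt_float(value, row: int, column: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", ".", "NA", "nan", "None"):
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise RowParseError(row, f"unparsable numeric in column {column!r}: {s!r}") from exc


@dataclass
class CohortTable:
    """Per-trio phenotype labels and haploid callable base counts.

    ``callable_bp`` is the per-trio coding callable total (the denominator
    used for coding variant classes); ``callable_bp_all`` optionally holds a
    whole-capture callable total for the "all" row and defaults to the coding
    column when absent.
    """

    df: pd.DataFrame

    REQUIRED = ("trio_id", "phenotype", "callable_bp")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise TableSchemaError(f"cohort table missing required column {col!r}")
        if self.df["trio_id"].duplicated().any():
            dupes = sorted(self.df.loc[self.df["trio_id"].duplicated(), "trio_id"])
            raise TableSchemaError(f"duplicate trio_ids: {dupes}")
        bad = set(self.df["phenotype"]) - {"case", "control"}
        if bad:
            raise TableSchemaError(f"unknown phenotype labels: {sorted(bad)}")
        if (self.df["callable_bp"] <= 0).any():
            raise TableSchemaError("callable_bp must be positive for every trio")
        if "callable_bp_all" not in self.df.columns:
            self.df = self.df.assign(callable_bp_all=self.df["callable_bp"])

    def n_trios(self, phenotype: str) -> int:
        return int((self.df["phenotype"] == phenotype).sum())

    def callable_total(self, phenotype: str, territory: str = "coding") -> float:
        """Summed haploid callable bases over the cohort's trios."""
        col = "callable_bp" if territory == "coding" else "callable_bp_all"
        return float(self.df.loc[self.df["phenotype"] == phenotype, col].sum())


@dataclass
class MutationRateTable:
    """Per-gene expected de novo mutation rates by variant class.

    Rates are per gene per generation on the haploid scale, so the expected
    count of class-c de novos in N trios is ``2 * N * mu_c`` summed over
    genes.  ``mu_damaging`` is derived as ``mu_lgd + mu_misd``.
    """

    genes: np.ndarray
    mu_total: np.ndarray
    mu_lgd: np.ndarray
    mu_misd: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.mu_total = np.asarray(self.mu_total, dtype=float)
        self.mu_lgd = np.asarray(self.mu_lgd, dtype=float)
        self.mu_misd = np.asarray(self.mu_misd, dtype=float)
        n = len(self.genes)
        if not (len(self.mu_total) == len(self.mu_lgd) == len(self.mu_misd) == n):
            raise TableSchemaError("rate table columns have unequal lengths")
        if n == 0:
            raise TableSchemaError("rate table is empty")
        uniq, counts = np.unique(self.genes, return_counts=True)
        if (counts > 1).any():
            raise TableSchemaError(f"duplicate gene symbols: {sorted(uniq[counts > 1])}")
        for name, col in (("mu_total", self.mu_total), ("mu_lgd", self.mu_lgd), ("mu_misd", self.mu_misd)):
            if (col < 0).any():
                raise TableSchemaError(f"negative rates in column {name!r}")
        # tiny slack for rates read back from text
        if (self.mu_lgd + self.mu_misd > self.mu_total * (1 + 1e-9) + 1e-15).any():
            raise TableSchemaError("mu_lgd + mu_misd exceeds mu_total for some gene")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def mu_damaging(self) -> np.ndarray:
        return self.mu_lgd + self.mu_misd

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of *genes*; raises KeyError listing unknown symbols."""
        idx, missing = [], []
        for g in genes:
            i = self._index.get(g)
            (idx if i is not None else missing).append(i if i is not None else g)
        if missing:
            raise KeyError(f"genes absent from rate table: {sorted(set(missing))}")
        return np.asarray(idx, dtype=int)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "mu_total": self.mu_total,
                "mu_lgd": self.mu_lgd,
                "mu_misd": self.mu_misd,
                "mu_damaging": self.mu_damaging,
            }
        )


def read_denovo_table(
    path, dialect: Optional[Mapping[str, str]] = None
) -> list[DeNovoVariant]:
    """Read an annotated de novo variant TSV into records, preserving order.

    *dialect* maps logical field names (see :data:`DEFAULT_DIALECT`) to the
    file's column headers.  Unrecognised effect strings map to ``unknown``.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical in ("proband", "cohort", "gene", "effect"):
        if d[logical] not in df.columns:
            raise TableSchemaError(
                f"variant table missing required column {d[logical]!r} (field {logical!r})"
            )
    has_locus = all(d[k] in df.columns for k in ("chrom", "pos", "ref", "alt"))
    out: list[DeNovoVariant] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        locus = None
        if has_locus and str(rec[d["chrom"]]).strip():
            try:
                pos = int(str(rec[d["pos"]]).strip())
            except ValueError as exc:
                raise RowParseError(i, f"unparsable position {rec[d['pos']]!r}") from exc
            locus = (str(rec[d["chrom"]]).strip(), pos, str(rec[d["ref"]]).strip(), str(rec[d["alt"]]).strip())
        out.append(
            DeNovoVariant(
                proband_id=str(rec[d["proband"]]).strip(),
                cohort=str(rec[d["cohort"]]).strip().lower(),
                gene=str(rec[d["gene"]]).strip(),
                effect=_normalise_effect(rec[d["effect"]]),
                polyphen_hdiv=_opt_float(rec.get(d["polyphen"]), i, d["polyphen"]),
                pop_freq=_opt_float(rec.get(d["pop_freq"]), i, d["pop_freq"]),
                locus=locus,
            )
        )
    return out


def write_denovo_table(vs: Sequence[DeNovoVariant], path) -> None:
    """Write records as a TSV readable by :func:`read_denovo_table`."""
    d = DEFAULT_DIALECT

    def fmt(x):
        return "" if x is None else repr(x) if isinstance(x, float) else str(x)

    rows = []
    for v in vs:
        chrom, pos, ref, alt = v.locus if v.locus else ("", "", "", "")
        rows.append(
            {
                d["proband"]: v.proband_id,
                d["cohort"]: v.cohort,
                d["gene"]: v.gene,
                d["effect"]: v.effect.value,
                d["polyphen"]: fmt(v.polyphen_hdiv),
                d["pop_freq"]: fmt(v.pop_freq),
                d["chrom"]: chrom,
                d["pos"]: pos,
                d["ref"]: ref,
                d["alt"]: alt,
            }
        )
    pd.DataFrame(rows, columns=list(d.values())).to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> CohortTable:
    df = pd.read_csv(path, sep="\t")
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_rate_table(path) -> MutationRateTable:
    """Read a per-gene rate TSV with columns gene, mu_total, mu_lgd, mu_misd."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "mu_total", "mu_lgd", "mu_misd"):
        if col not in df.columns:
            raise TableSchemaError(f"rate table missing required column {col!r}")
    return MutationRateTable(
        genes=df["gene"].astype(str).str.strip().to_numpy(),
        mu_total=df["mu_total"].to_numpy(float),
        mu_lgd=df["mu_lgd"].to_numpy(float),
        mu_misd=df["mu_misd"].to_numpy(float),
    )


def write_rate_table(rates: MutationRateTable, path) -> None:
    rates.to_frame().drop(columns="mu_damaging").to_csv(path, sep="\t", index=False)


def read_gene_set(path, name: Optional[str] = None) -> GeneSet:
    """Read a one-symbol-per-line gene list (blank lines and '#' comments skipped)."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            symbols.append(s)
    dupes = [g for g, c in pd.Series(symbols).value_counts().items() if c > 1]
    if dupes:
        raise TableSchemaError(f"duplicate gene symbols in {path}: {sorted(dupes)}")
    return GeneSet(name=name or Path(path).stem, genes=frozenset(symbols))


def read_gene_sets_tsv(path) -> list[GeneSet]:
    """Read a two-column (set_name, gene) TSV into a list of gene sets."""
    df = pd.read_csv(path, sep="\t")
    for col in ("set_name", "gene"):
        if col not in df.columns:
            raise TableSchemaError(f"gene-set table missing required column {col!r}")
    out = []
    for name, grp in df.groupby("set_name", sort=True):
        out.append(GeneSet(name=str(name), genes=frozenset(grp["gene"].astype(str).str.strip())))
    return out


def write_gene_sets_tsv(sets: Sequence[GeneSet], path) -> None:
    rows = [
        {"set_name": gs.name, "gene": g} for gs in sets for g in sorted(gs.genes)
    ]
    pd.DataFrame(rows, columns=["set_name", "gene"]).to_csv(path, sep="\t", index=False)
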