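"""Reading, validating and writing GWAS summary-statistic tables.

The canonical in-memory container is :class:`GwasTable`, a thin wrapper
around a pandas DataFrame with one row per variant and the columns
``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
Files are tab-separated text (optionally gzipped) with one header row;
missing values are written as ``NA``.  Rows that violate the row-level
invariants (se <= 0, p outside (0,1], eaf outside [0,1], identical
alleles) are dropped on read and counted in an audit log.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = [
    "snp",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_NUCLEOTIDES = set("ACGT")

# smallest positive double; p-values of exactly 0 are clamped here
TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class VariantAssoc:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele estimate (linear or log-odds scale),
    ``se`` its standard error (> 0), ``pval`` in (0, 1], ``eaf`` the
    effect-allele frequency in [0, 1] or NaN when unknown.
    """

    snp: str
    chr: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def is_indel(self) -> bool:
        return len(self.effect_allele) > 1 or len(self.other_allele) > 1


@dataclass
class GwasTable:
    """A validated summary-statistic table for one trait."""

    trait_name: str
    df: pd.DataFrame
    trait_type: str = "continuous"  # "binary" | "continuous"
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"GwasTable missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[VariantAssoc]:
        return [VariantAssoc(**row) for row in self.df[CANONICAL_COLUMNS].to_dict("records")]

    def with_df(self, df: pd.DataFrame) -> "GwasTable":
        """Copy of this table with a replacement DataFrame (metadata kept)."""
        return GwasTable(
            trait_name=self.trait_name,
            df=df.reset_index(drop=True),
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Row-level validation; returns (kept rows, audit dict)."""
    n_in = len(df)
    audit: dict = {"input_rows": n_in, "dropped": {}, "flagged": {}}

    se_bad = ~(df["se"] > 0)
    p_bad = ~((df["pval"] > 0) & (df["pval"] <= 1))
    # p == 0 exactly is clamped rather than dropped (documented convention)
    p_zero = df["pval"] == 0
    p_bad &= ~p_zero
    eaf_bad = df["eaf"].notna() & ~((df["eaf"] >= 0) & (df["eaf"] <= 1))
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    allele_same = ea == oa
    allele_empty = (ea.str.len() == 0) | (oa.str.len() == 0)
    beta_bad = ~np.isfinite(df["beta"]) | ~np.isfinite(df["se"])

    bad = se_bad | p_bad | eaf_bad | allele_same | allele_empty | beta_bad
    for name, mask in [
        ("se_nonpositive", se_bad),
        ("pval_out_of_range", p_bad),
        ("eaf_out_of_range", eaf_bad),
        ("identical_alleles", allele_same | allele_empty),
        ("nonfinite_beta_or_se", beta_bad),
    ]:
        k = int(mask.sum())
        if k:
            audit["dropped"][name] = k

    kept = df.loc[~bad].copy()
    kept["effect_allele"] = ea.loc[~bad]
    kept["other_allele"] = oa.loc[~bad]

    # flags: kept but noteworthy
    nz = kept["pval"] == 0
    if nz.any():
        kept.loc[nz, "pval"] = TINY_P
        audit["flagged"]["pval_zero_clamped"] = int(nz.sum())
    odd = ~kept["effect_allele"].map(lambda a: set(a) <= _NUCLEOTIDES) | ~kept[
        "other_allele"
    ].map(lambda a: set(a) <= _NUCLEOTIDES)
    if odd.any():
        audit["flagged"]["nonstandard_alleles"] = int(odd.sum())
    indel = (kept["effect_allele"].str.len() > 1) | (kept["other_allele"].str.len() > 1)
    if indel.any():
        audit["flagged"]["indel_alleles"] = int(indel.sum())

    audit["kept_rows"] = len(kept)
    audit["dropped_rows"] = n_in - len(kept)
    return kept.reset_index(drop=True), audit


def read_gwas_table(
    path: str | Path,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    dialect: Mapping[str, str] | None = None,
    audit_path: str | Path | None = None,
) -> tuple[GwasTable, dict]:
    """Read a tab-separated summary-statistic file into a :class:`GwasTable`.

    ``dialect`` maps file column names to canonical ones, e.g.
    ``{"effect_allele.exposure": "effect_allele"}``.  Invalid rows are
    dropped and counted in the returned audit dict (also written as JSON
    to ``audit_path`` when given).  Zero valid rows is fatal.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", na_values=["NA", ""], dtype={"snp": str},
        float_precision="round_trip",
    )
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (dialect mapping?)")
    df = df[CANONICAL_COLUMNS].copy()
    df["snp"] = df["snp"].astype(str)
    df["chr"] = df["chr"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for c in ("eaf", "beta", "se", "pval", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)

    kept, audit = _validate_rows(df)
    audit["path"] = str(path)
    if len(kept) == 0:
        raise ValueError(f"{path}: no valid rows after validation ({audit})")
    if audit_path is not None:
        Path(audit_path).write_text(json.dumps(audit, indent=2))
    table = GwasTable(
        trait_name=trait_name or path.stem, df=kept, trait_type=trait_type
    )
    return table, audit


def write_gwas_table(table: GwasTable, path: str | Path) -> Path:
    """Write a table as tab-separated text; NaN fields become ``NA``.

    Floats are serialized with ``repr`` round-trip precision so that
    read(write(t)) reproduces every finite field bit-exactly.
    """
    path = Path(path)
    out = table.df[CANONICAL_COLUMNS].copy()
    with open(path, "wt") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fields = []
            for col, val in zip(CANONICAL_COLUMNS, row):
                if isinstance(val, float) and math.isnan(val):
                    fields.append("NA")
                elif isinstance(val, float):
                    fields.append(repr(val))
                else:
                    fields.append(str(val))
            fh.write("\t".join(fields) + "\n")
    return path
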