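"""Genetic-instrument selection.

Selection proceeds as in standard two-sample MR practice: keep variants
below a p-value threshold, greedily clump by LD (keep the most significant
variant, discard linked neighbours within a physical window), drop
duplicate rsIDs, and require per-variant F statistics F = beta^2/se^2 to
clear a weak-instrument bar (conventionally 10, boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mrsuite.gwas_io import GwasTable


@dataclass
class LdMatrix:
    """Pairwise squared-correlation (r^2) matrix over named SNPs."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("LdMatrix diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("LdMatrix must be symmetric")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float | None:
        """r^2 between two SNPs, or None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_square_tsv(cls, path: str | Path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=list(df.index.astype(str)), r2=df.to_numpy(dtype=float))

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "LdMatrix":
        """Long format: columns snp_a, snp_b, r2; absent pairs default to 0."""
        df = pd.read_csv(path, sep="\t")
        ids = sorted(set(df["snp_a"].astype(str)) | set(df["snp_b"].astype(str)))
        idx = {s: i for i, s in enumerate(ids)}
        r2 = np.eye(len(ids))
        for a, b, v in zip(df["snp_a"].astype(str), df["snp_b"].astype(str), df["r2"]):
            r2[idx[a], idx[b]] = v
            r2[idx[b], idx[a]] = v
        return cls(snp_ids=ids, r2=r2)

    def to_square_tsv(self, path: str | Path) -> Path:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t"
        )
        return Path(path)


@dataclass
class InstrumentSet:
    """Final instrument table with per-SNP F statistics and a selection log."""

    table: GwasTable
    f_stats: pd.Series
    selection_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def select_by_pvalue(table: GwasTable, threshold: float) -> GwasTable:
    """Keep exactly the records with pval <= threshold, order preserved."""
    if not (0 < threshold < 1 or threshold == 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    return table.with_df(table.df.loc[table.df["pval"] <= threshold])


def drop_duplicates(table: GwasTable) -> GwasTable:
    """For repeated snp ids keep smallest p, then smallest se, then first."""
    df = table.df.copy()
    df["_order"] = np.arange(len(df))
    df = df.sort_values(["snp", "pval", "se", "_order"], kind="stable")
    df = df.drop_duplicates("snp", keep="first")
    df = df.sort_values("_order", kind="stable").drop(columns="_order")
    return table.with_df(df)


def greedy_clump(
    table: GwasTable,
    ld: LdMatrix | None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> GwasTable:
    """Greedy LD clumping by ascending p-value.

    Repeatedly keep the remaining variant with the smallest p (ties: smaller
    se, then lexicographic snp id) and remove every other variant on the
    same chromosome within ``window_kb`` kilobases (inclusive) whose r^2
    with it is >= ``r2_max``.  Variants missing from ``ld`` (or ``ld=None``)
    are treated as unlinked (r^2 = 0).  Output is sorted by p ascending.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    df = table.df.copy()
    if len(df) == 0:
        return table.with_df(df)
    order = df.sort_values(
        ["pval", "se", "snp"], kind="stable"
    ).index.to_numpy()
    window_bp = window_kb * 1000.0
    alive = {int(i) for i in order}
    kept_rows: list[int] = []
    for i in order:
        i = int(i)
        if i not in alive:
            continue
        kept_rows.append(i)
        alive.discard(i)
        snp_i = df.at[i, "snp"]
        chr_i = df.at[i, "chr"]
        pos_i = df.at[i, "pos"]
        for j in list(alive):
            if df.at[j, "chr"] != chr_i:
                continue
            if abs(df.at[j, "pos"] - pos_i) > window_bp:
                continue
            r2 = ld.lookup(snp_i, df.at[j, "snp"]) if ld is not None else None
            if r2 is None:
                r2 = 0.0  # absent from the reference: treated as unlinked
            if r2 >= r2_max:
                alive.discard(j)
    return table.with_df(df.loc[kept_rows])


def f_statistic(beta: float | np.ndarray, se: float | np.ndarray) -> float | np.ndarray:
    """Single-variant instrument strength F = beta^2 / se^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("se must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def filter_by_f(table: GwasTable, min_f: float = 10.0) -> InstrumentSet:
    """Retain records with F >= min_f (boundary inclusive)."""
    f = pd.Series(
        f_statistic(table.df["beta"].to_numpy(), table.df["se"].to_numpy()),
        index=table.df["snp"].to_numpy(),
        name="F",
    )
    keep = f.to_numpy() >= min_f
    out = table.with_df(table.df.loc[keep])
    return InstrumentSet(
        table=out,
        f_stats=f[keep],
        selection_log={
            "input": len(table),
            "min_f": min_f,
            "retained": int(keep.sum()),
            "removed_weak": int((~keep).sum()),
        },
    )
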