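"""Allele harmonization of exposure and outcome summary statistics.

Produces the per-variant effect pairs (gamma_i, Gamma_i) — the exposure
and outcome associations expressed on the same effect allele — that every
estimator consumes.  Palindromic variants (A/T, C/G) are removed outright
because their strand cannot be resolved from alleles alone; swapped
alleles flip the outcome beta's sign; strand flips (complement alleles)
are rescued once before declaring a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mrsuite.gwas_io import GwasTable

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G}; indels are never palindromic."""
    a, b = effect_allele.upper(), other_allele.upper()
    if len(a) != 1 or len(b) != 1:
        return False
    return {a, b} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str:
    return allele.upper().translate(_COMPLEMENT)


@dataclass
class HarmonizedSet:
    """Aligned per-variant effect pairs ready for estimation.

    ``beta_exp``/``se_exp`` are the exposure associations gamma_i,
    ``beta_out``/``se_out`` the outcome associations Gamma_i on the same
    effect allele.  ``drop_log`` maps excluded snp ids to reason codes.
    """

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    drop_log: dict[str, str] = field(default_factory=dict)
    flip_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.snp_ids)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if (self.se_exp <= 0).any() or (self.se_out <= 0).any():
            raise ValueError("all standard errors must be positive")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta_exp=self.beta_exp[idx],
            se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx],
            se_out=self.se_out[idx],
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
        )

    def to_tsv(self, path: str | Path) -> Path:
        pd.DataFrame(
            {
                "snp": self.snp_ids,
                "beta_exp": self.beta_exp,
                "se_exp": self.se_exp,
                "beta_out": self.beta_out,
                "se_out": self.se_out,
            }
        ).to_csv(path, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "HarmonizedSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            snp_ids=list(df["snp"].astype(str)),
            beta_exp=df["beta_exp"].to_numpy(),
            se_exp=df["se_exp"].to_numpy(),
            beta_out=df["beta_out"].to_numpy(),
            se_out=df["se_out"].to_numpy(),
            **kw,
        )


def harmonize(exposure: GwasTable, outcome: GwasTable) -> HarmonizedSet:
    """Intersect on snp id and align outcome effects to the exposure's
    effect allele.

    Per shared variant: identical alleles pass through; swapped alleles
    negate the outcome beta; complement (strand-flipped) alleles are
    complemented once and re-tested; anything else is dropped with reason
    ``allele_mismatch``.  Palindromic variants are dropped with reason
    ``palindromic``.  Order follows the exposure table.
    """
    exp = exposure.df.set_index("snp", drop=False)
    out = outcome.df.set_index("snp", drop=False)
    shared = [s for s in exposure.df["snp"] if s in out.index]
    if not shared:
        raise ValueError(
            f"no shared variants between exposure '{exposure.trait_name}' "
            f"and outcome '{outcome.trait_name}'"
        )

    ids: list[str] = []
    be, se_e, bo, se_o = [], [], [], []
    drop_log: dict[str, str] = {}
    flip_log: dict[str, str] = {}
    for s in shared:
        e = exp.loc[s]
        o = out.loc[s]
        if isinstance(e, pd.DataFrame) or isinstance(o, pd.DataFrame):
            drop_log[s] = "duplicate_id"
            continue
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        if is_palindromic(ea_e, oa_e):
            drop_log[s] = "palindromic"
            continue
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        beta_o = float(o["beta"])
        action = None
        if (ea_o, oa_o) == (ea_e, oa_e):
            action = "same"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            action = "swap"
        else:
            # strand-flip rescue: complement outcome alleles once, re-test
            ca, cb = _complement(ea_o), _complement(oa_o)
            if (ca, cb) == (ea_e, oa_e):
                action = "flip"
            elif (ca, cb) == (oa_e, ea_e):
                action = "flip_swap"
        if action is None:
            drop_log[s] = "allele_mismatch"
            continue
        if action in ("swap", "flip_swap"):
            beta_o = -beta_o
        if action != "same":
            flip_log[s] = action
        ids.append(s)
        be.append(float(e["beta"]))
        se_e.append(float(e["se"]))
        bo.append(beta_o)
        se_o.append(float(o["se"]))

    if not ids:
        raise ValueError(
            f"harmonization of '{exposure.trait_name}' vs "
            f"'{outcome.trait_name}' left no variants ({drop_log})"
        )
    return HarmonizedSet(
        snp_ids=ids,
        beta_exp=np.array(be),
        se_exp=np.array(se_e),
        beta_out=np.array(bo),
        se_out=np.array(se_o),
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        drop_log=drop_log,
        flip_log=flip_log,
    )
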