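#!/usr/bin/env python
"""Generate the synthetic study inputs and verify their integrity.

Builds ground-truth-known stand-ins for the study's data layers:

* two plasma-protein exposure GWAS ("PD1_like" causal-protective on the
  disease outcomes, "PDL1_like" null), each instrumented by ~20 variants;
* five binary coronary-disease outcome GWAS on the linear-probability
  beta scale of large-biobank case/control traits (odds ratios near 1);
* a block-diagonal LD reference for clumping;
* a 3-vs-3 log2 expression matrix with a planted down-regulated
  immune-checkpoint-like gene set, plus decoy sets, in GMT form.

Writes everything under results/synthetic_data/ and prints the per-file
row counts and the read-back audit.
"""

from pathlib import Path

import numpy as np

from mrsuite import (
    MrSimConfig,
    ExprSimConfig,
    simulate_mr_summary,
    simulate_ld,
    simulate_expression,
    write_gwas_table,
    read_gwas_table,
)
from mrsuite.gsea import write_gmt

OUT = Path("results/synthetic_data")
OUT.mkdir(parents=True, exist_ok=True)

SEED = 2024
OUTCOMES = ["chd", "angina", "mi", "coronary_atherosclerosis",
            "unstable_angina"]
# true causal effects of the PD1-like protein on each outcome
# (log-odds per SD of protein; protective, near-null magnitude)
PD1_EFFECTS = {o: -0.003 for o in OUTCOMES}
PDL1_EFFECTS = {o: 0.0 for o in OUTCOMES}

print("== exposure/outcome summary statistics ==")
for label, effects, offset in [("PD1_like", PD1_EFFECTS, 0),
                               ("PDL1_like", PDL1_EFFECTS, 100)]:
    for i, (outcome, theta) in enumerate(effects.items()):
        exp, out, truth = simulate_mr_summary(MrSimConfig(
            n_snp=20, theta=theta, seed=SEED + offset + i,
            binary_outcome_scale=True))
        exp.trait_name, out.trait_name = label, outcome
        write_gwas_table(exp, OUT / f"{label}__{outcome}__exposure.tsv")
        write_gwas_table(out, OUT / f"{label}__{outcome}__outcome.tsv")
    print(f"  {label}: 20 instruments x {len(effects)} outcomes "
          f"(true theta {list(effects.values())[0]:+.3f})")

print("== LD reference (block-diagonal) ==")
ld = simulate_ld(20, [2, 3] + [1] * 15, 0.9, seed=SEED)
ld.to_square_tsv(OUT / "ld_reference.tsv")
print(f"  20 variants, blocks [2, 3, 1x15] at r2=0.9 within blocks")

print("== expression matrix with planted signal ==")
checkpoint_genes = [f"G{i+1:05d}" for i in range(40)]
mat, truth = simulate_expression(ExprSimConfig(
    n_genes=600, planted_sets={"PDL1_PD1_CHECKPOINT": (checkpoint_genes,
                                                       -2.0)},
    seed=SEED))
mat.to_tsv(OUT / "expression.tsv", OUT / "groups.tsv")
rng = np.random.default_rng(SEED)
sets = {"PDL1_PD1_CHECKPOINT": checkpoint_genes}
for j in range(9):
    sets[f"DECOY_{j}"] = sorted(rng.choice(mat.gene_ids[40:], 30,
                                           replace=False))
write_gmt(sets, OUT / "gene_sets.gmt")
print(f"  600 genes x 6 samples; planted 40-gene set shifted -2.0 log2 "
      f"in cases; 9 decoy sets")

print("== read-back audit ==")
t, audit = read_gwas_table(OUT / "PD1_like__chd__exposure.tsv")
print(f"  {audit['path']}: {audit['kept_rows']} rows kept, "
      f"{audit['dropped_rows']} dropped")
assert audit["dropped_rows"] == 0
print("done")
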